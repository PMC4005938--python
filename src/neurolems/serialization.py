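"""Readers and writers: NeuroML-XML, JSON (lossless), HDF5 and SWC (morphology).

Four on-disk formats with different contracts:

* **XML** -- the de-facto NeuroML serialization; lossless for the whole
  document subset.  Fixed dialect: UTF-8, 4-space indent, attributes in
  schema order, reals as ``%.6g``.
* **JSON** -- lossless; mirrors the object model, but morphologies are
  stored array-backed (numeric row lists, compact separators), which is
  what makes the format compact.  Canonical segment groups (``all`` and the
  SWC-type groups) are regenerated from the stored arrays on load; only
  non-canonical groups are stored, as run-length spans.
* **HDF5** -- morphology-only (lossy): group ``/morphology`` with datasets
  ``vertices`` (N×4 float64) and ``connectivity`` (N int64), attribute
  ``id``.  Arrays round-trip bit-exactly.
* **SWC** -- morphology-only (lossy): the 7-column node format; the radius
  column is half the stored diameter.  Type codes map to canonical segment
  groups (``soma_group``, ``axon_group``, ``dendrite_group``,
  ``apical_dendrite_group``) on load and are regenerated on write.

The numeric dialect is fixed on purpose: file sizes are then deterministic
functions of content, so the per-segment byte footprint of each format is a
meaningful, reproducible measurement.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
from lxml import etree

from .arraymorph import (
    ArrayMorphology,
    TYPE_GROUPS,
    _GROUP_TYPES,
    from_morphology,
    groups_from_types,
    to_morphology,
)
from .errors import (
    Issue,
    ParseError,
    StructureError,
    UnsupportedError,
    ValidationError,
    has_errors,
)
from .nml import (
    Connection,
    ExplicitInput,
    ExpTwoSynapse,
    IafCell,
    IzhikevichCell,
    Morphology,
    Network,
    NeuroMLDocument,
    Point3DWithDiam,
    Population,
    Projection,
    PulseGenerator,
    Segment,
    SegmentGroup,
    SegmentParent,
    validate_neuroml,
)

__all__ = [
    "write_neuroml_xml",
    "load_neuroml_xml",
    "write_json",
    "load_json",
    "write_hdf5",
    "load_hdf5",
    "write_swc",
    "load_swc",
    "measure",
    "SerializationReport",
    "SwcRecord",
]


def _fmt(value: float) -> str:
    return format(float(value), ".6g")


def _round6(value: float) -> float:
    return float(_fmt(value))


# ==========================================================================
# NeuroML XML


def write_neuroml_xml(doc: NeuroMLDocument, path) -> None:
    """Write a document in the fixed XML dialect (validates first)."""
    issues = validate_neuroml(doc)
    if has_errors(issues):
        raise ValidationError("document does not validate", issues)
    text = dumps_neuroml_xml(doc)
    Path(path).write_text(text, encoding="utf-8")


def dumps_neuroml_xml(doc: NeuroMLDocument) -> str:
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', f'<neuroml id="{doc.id}">']
    for cell in doc.izhikevich_cells:
        lines.append(
            f'    <izhikevichCell id="{cell.id}" a="{cell.a}" b="{cell.b}" '
            f'c="{cell.c}" d="{cell.d}" thresh="{cell.thresh}"/>'
        )
    for cell in doc.iaf_cells:
        lines.append(
            f'    <iafCell id="{cell.id}" leakReversal="{cell.leak_reversal}" '
            f'thresh="{cell.thresh}" reset="{cell.reset}" C="{cell.C}" '
            f'leakConductance="{cell.leak_conductance}"/>'
        )
    for syn in doc.synapses:
        lines.append(
            f'    <expTwoSynapse id="{syn.id}" gbase="{syn.gbase}" erev="{syn.erev}" '
            f'tauRise="{syn.tau_rise}" tauDecay="{syn.tau_decay}"/>'
        )
    for gen in doc.pulse_generators:
        lines.append(
            f'    <pulseGenerator id="{gen.id}" delay="{gen.delay}" '
            f'duration="{gen.duration}" amplitude="{gen.amplitude}"/>'
        )
    for morph in doc.morphologies:
        _morphology_xml_lines(morph, lines)
    for net in doc.networks:
        lines.append(f'    <network id="{net.id}">')
        for pop in net.populations:
            lines.append(
                f'        <population id="{pop.id}" component="{pop.component}" size="{pop.size}"/>'
            )
        for proj in net.projections:
            lines.append(
                f'        <projection id="{proj.id}" '
                f'presynapticPopulation="{proj.presynaptic_population}" '
                f'postsynapticPopulation="{proj.postsynaptic_population}" '
                f'synapse="{proj.synapse}">'
            )
            for conn in proj.connections:
                lines.append(
                    f'            <connection id="{conn.id}" '
                    f'preCellId="{conn.pre_cell_id}" postCellId="{conn.post_cell_id}"/>'
                )
            lines.append("        </projection>")
        for ei in net.explicit_inputs:
            lines.append(f'        <explicitInput target="{ei.target}" input="{ei.input}"/>')
        lines.append("    </network>")
    lines.append("</neuroml>")
    return "\n".join(lines) + "\n"


def _morphology_xml_lines(morph, lines) -> None:
    if isinstance(morph, ArrayMorphology):
        morph = to_morphology(morph)
    lines.append(f'    <morphology id="{morph.id}">')
    seg_map = morph.segment_map()
    for seg in morph.segments:
        name = seg.name if seg.name is not None else f"segment_{seg.id}"
        lines.append(f'        <segment id="{seg.id}" name="{name}">')
        if seg.parent is not None:
            fa = seg.parent.fraction_along
            fa_text = "1.0" if fa == 1.0 else ("0.0" if fa == 0.0 else _fmt(fa))
            lines.append(
                f'            <parent segment="{seg.parent.segment}" fractionAlong="{fa_text}"/>'
            )
        prox = morph.resolved_proximal(seg, seg_map)
        lines.append(
            f'            <proximal x="{_fmt(prox.x)}" y="{_fmt(prox.y)}" '
            f'z="{_fmt(prox.z)}" diameter="{_fmt(prox.diameter)}"/>'
        )
        d = seg.distal
        lines.append(
            f'            <distal x="{_fmt(d.x)}" y="{_fmt(d.y)}" '
            f'z="{_fmt(d.z)}" diameter="{_fmt(d.diameter)}"/>'
        )
        lines.append("        </segment>")
    for group in morph.groups:
        lines.append(f'        <segmentGroup id="{group.id}">')
        for member in group.members:
            lines.append(f'            <member segment="{member}"/>')
        for inc in group.includes:
            lines.append(f'            <include segmentGroup="{inc}"/>')
        lines.append("        </segmentGroup>")
    lines.append("    </morphology>")


def load_neuroml_xml(path) -> NeuroMLDocument:
    """Tolerant reader: unknown elements/attributes become issues, not errors."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from None
    root = tree.getroot()
    tag = etree.QName(root).localname if root.prefix or "}" in str(root.tag) else root.tag
    if tag != "neuroml":
        raise ParseError(f"root element must be <neuroml>, got <{root.tag}>")
    return _read_document(root)


def loads_neuroml_xml(text: str) -> NeuroMLDocument:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from None
    return _read_document(root)


def _local(el) -> str:
    tag = el.tag
    return tag.split("}", 1)[1] if isinstance(tag, str) and "}" in tag else tag


def _read_document(root) -> NeuroMLDocument:
    doc = NeuroMLDocument(id=root.get("id", "neuroml_document"))
    issues = doc.load_issues
    for el in root:
        if not isinstance(el.tag, str):
            continue
        tag = _local(el)
        if tag == "izhikevichCell":
            doc.izhikevich_cells.append(
                IzhikevichCell(
                    id=el.get("id", ""),
                    a=el.get("a", ""),
                    b=el.get("b", ""),
                    c=el.get("c", ""),
                    d=el.get("d", ""),
                    thresh=el.get("thresh", ""),
                )
            )
        elif tag == "iafCell":
            doc.iaf_cells.append(
                IafCell(
                    id=el.get("id", ""),
                    leak_reversal=el.get("leakReversal", ""),
                    thresh=el.get("thresh", ""),
                    reset=el.get("reset", ""),
                    C=el.get("C", ""),
                    leak_conductance=el.get("leakConductance", ""),
                )
            )
        elif tag == "expTwoSynapse":
            doc.synapses.append(
                ExpTwoSynapse(
                    id=el.get("id", ""),
                    gbase=el.get("gbase", ""),
                    erev=el.get("erev", ""),
                    tau_rise=el.get("tauRise", ""),
                    tau_decay=el.get("tauDecay", ""),
                )
            )
        elif tag == "pulseGenerator":
            doc.pulse_generators.append(
                PulseGenerator(
                    id=el.get("id", ""),
                    delay=el.get("delay", ""),
                    duration=el.get("duration", ""),
                    amplitude=el.get("amplitude", ""),
                )
            )
        elif tag == "morphology":
            doc.morphologies.append(_read_morphology(el, issues))
        elif tag == "network":
            doc.networks.append(_read_network(el, issues))
        else:
            issues.append(Issue("warning", f"unknown element <{tag}> skipped"))
    return doc


def _read_morphology(el, issues) -> Morphology:
    morph = Morphology(id=el.get("id", "morphology"))
    for child in el:
        if not isinstance(child.tag, str):
            continue
        tag = _local(child)
        if tag == "segment":
            try:
                seg_id = int(child.get("id"))
            except (TypeError, ValueError):
                raise ParseError("segment without a valid integer id") from None
            seg = Segment(
                id=seg_id,
                name=child.get("name"),
                distal=Point3DWithDiam(0.0, 0.0, 0.0, 0.0),
            )
            saw_distal = False
            for sub in child:
                if not isinstance(sub.tag, str):
                    continue
                stag = _local(sub)
                if stag == "parent":
                    seg.parent = SegmentParent(
                        segment=int(sub.get("segment")),
                        fraction_along=float(sub.get("fractionAlong", "1.0")),
                    )
                elif stag == "proximal":
                    seg.proximal = _read_point(sub)
                elif stag == "distal":
                    seg.distal = _read_point(sub)
                    saw_distal = True
                else:
                    issues.append(Issue("warning", f"unknown element <{stag}> in segment {seg_id}"))
            if not saw_distal:
                raise ParseError(f"segment {seg_id} lacks a distal point")
            morph.segments.append(seg)
        elif tag == "segmentGroup":
            group = SegmentGroup(id=child.get("id", ""))
            for sub in child:
                if not isinstance(sub.tag, str):
                    continue
                stag = _local(sub)
                if stag == "member":
                    group.members.append(int(sub.get("segment")))
                elif stag == "include":
                    group.includes.append(sub.get("segmentGroup"))
                else:
                    issues.append(Issue("warning", f"unknown element <{stag}> in segmentGroup"))
            morph.groups.append(group)
        else:
            issues.append(Issue("warning", f"unknown element <{tag}> in morphology skipped"))
    return morph


def _read_point(el) -> Point3DWithDiam:
    try:
        return Point3DWithDiam(
            x=float(el.get("x")),
            y=float(el.get("y")),
            z=float(el.get("z")),
            diameter=float(el.get("diameter")),
        )
    except (TypeError, ValueError):
        raise ParseError(f"malformed point element <{_local(el)}>") from None


def _read_network(el, issues) -> Network:
    net = Network(id=el.get("id", ""))
    for child in el:
        if not isinstance(child.tag, str):
            continue
        tag = _local(child)
        if tag == "population":
            net.populations.append(
                Population(
                    id=child.get("id", ""),
                    component=child.get("component", ""),
                    size=int(child.get("size", "0")),
                )
            )
        elif tag == "projection":
            proj = Projection(
                id=child.get("id", ""),
                presynaptic_population=child.get("presynapticPopulation", ""),
                postsynaptic_population=child.get("postsynapticPopulation", ""),
                synapse=child.get("synapse", ""),
            )
            for sub in child:
                if isinstance(sub.tag, str) and _local(sub) == "connection":
                    proj.connections.append(
                        Connection(
                            id=int(sub.get("id")),
                            pre_cell_id=int(sub.get("preCellId")),
                            post_cell_id=int(sub.get("postCellId")),
                        )
                    )
            net.projections.append(proj)
        elif tag == "explicitInput":
            net.explicit_inputs.append(
                ExplicitInput(target=child.get("target", ""), input=child.get("input", ""))
            )
        else:
            issues.append(Issue("warning", f"unknown element <{tag}> in network skipped"))
    return net


# ==========================================================================
# JSON


def write_json(doc: NeuroMLDocument, path=None) -> str:
    """Serialize a document to compact JSON; returns the text.

    If ``path`` is given the text is also written there.
    """
    issues = validate_neuroml(doc)
    if has_errors(issues):
        raise ValidationError("document does not validate", issues)
    payload = {"id": doc.id}
    if doc.izhikevich_cells:
        payload["izhikevich_cells"] = [
            {"id": c.id, "a": c.a, "b": c.b, "c": c.c, "d": c.d, "thresh": c.thresh}
            for c in doc.izhikevich_cells
        ]
    if doc.iaf_cells:
        payload["iaf_cells"] = [
            {
                "id": c.id,
                "leak_reversal": c.leak_reversal,
                "thresh": c.thresh,
                "reset": c.reset,
                "C": c.C,
                "leak_conductance": c.leak_conductance,
            }
            for c in doc.iaf_cells
        ]
    if doc.synapses:
        payload["synapses"] = [
            {"id": s.id, "gbase": s.gbase, "erev": s.erev, "tau_rise": s.tau_rise, "tau_decay": s.tau_decay}
            for s in doc.synapses
        ]
    if doc.pulse_generators:
        payload["pulse_generators"] = [
            {"id": g.id, "delay": g.delay, "duration": g.duration, "amplitude": g.amplitude}
            for g in doc.pulse_generators
        ]
    if doc.morphologies:
        payload["morphologies"] = [_morphology_payload(m) for m in doc.morphologies]
    if doc.networks:
        payload["networks"] = [
            {
                "id": n.id,
                "populations": [[p.id, p.component, p.size] for p in n.populations],
                "projections": [
                    {
                        "id": pr.id,
                        "pre": pr.presynaptic_population,
                        "post": pr.postsynaptic_population,
                        "synapse": pr.synapse,
                        "connections": [
                            [c.id, c.pre_cell_id, c.post_cell_id] for c in pr.connections
                        ],
                    }
                    for pr in n.projections
                ],
                "explicit_inputs": [[e.target, e.input] for e in n.explicit_inputs],
            }
            for n in doc.networks
        ]
    text = json.dumps(payload, separators=(",", ":")) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _spans(members: list[int]) -> list[list[int]]:
    """Run-length spans [first, last] over a sorted member list."""
    spans: list[list[int]] = []
    for m in sorted(members):
        if spans and m == spans[-1][1] + 1:
            spans[-1][1] = m
        else:
            spans.append([m, m])
    return spans


def _expand_spans(spans) -> list[int]:
    out: list[int] = []
    for first, last in spans:
        out.extend(range(int(first), int(last) + 1))
    return out


def _morphology_payload(morph) -> dict:
    am = morph if isinstance(morph, ArrayMorphology) else from_morphology(morph)
    extra_groups = []
    if not isinstance(morph, ArrayMorphology):
        canonical = {"all"} | set(TYPE_GROUPS.values())
        for group in morph.groups:
            if group.id in canonical:
                continue
            extra_groups.append(
                {"id": group.id, "spans": _spans(group.members), "includes": group.includes}
            )
    names = am.segment_names
    if names is None:
        names = [f"segment_{sid}" for sid in am.segment_ids.tolist()]
    payload = {
        "id": am.id,
        "vertices": [[_round6(v) for v in row] for row in am.vertices.tolist()],
        "connectivity": am.connectivity.tolist(),
        "segment_ids": am.segment_ids.tolist(),
        "segment_names": names,
        "segment_types": am.segment_types.tolist(),
    }
    if extra_groups:
        payload["groups"] = extra_groups
    return payload


def load_json(source) -> NeuroMLDocument:
    """Load a document from JSON text or a path."""
    if isinstance(source, Path) or (isinstance(source, str) and os.path.exists(source)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc}") from None
    if not isinstance(payload, dict) or "id" not in payload:
        raise ParseError("JSON document must be an object with an 'id'")
    doc = NeuroMLDocument(id=payload["id"])
    for entry in payload.get("izhikevich_cells", []):
        doc.izhikevich_cells.append(IzhikevichCell(**entry))
    for entry in payload.get("iaf_cells", []):
        doc.iaf_cells.append(IafCell(**entry))
    for entry in payload.get("synapses", []):
        doc.synapses.append(ExpTwoSynapse(**entry))
    for entry in payload.get("pulse_generators", []):
        doc.pulse_generators.append(PulseGenerator(**entry))
    for entry in payload.get("morphologies", []):
        doc.morphologies.append(_morphology_from_payload(entry))
    for entry in payload.get("networks", []):
        net = Network(id=entry["id"])
        for pid, comp, size in entry.get("populations", []):
            net.populations.append(Population(id=pid, component=comp, size=int(size)))
        for pr in entry.get("projections", []):
            proj = Projection(
                id=pr["id"],
                presynaptic_population=pr["pre"],
                postsynaptic_population=pr["post"],
                synapse=pr["synapse"],
            )
            for cid, pre, post in pr.get("connections", []):
                proj.connections.append(
                    Connection(id=int(cid), pre_cell_id=int(pre), post_cell_id=int(post))
                )
            net.projections.append(proj)
        for target, input_id in entry.get("explicit_inputs", []):
            net.explicit_inputs.append(ExplicitInput(target=target, input=input_id))
        doc.networks.append(net)
    return doc


def _morphology_from_payload(entry: dict) -> Morphology:
    try:
        vertices = np.asarray(entry["vertices"], dtype=np.float64)
        if vertices.ndim != 2 or vertices.shape[1] != 4:
            raise ParseError("morphology vertices must be rows of [x, y, z, diameter]")
        am = ArrayMorphology(
            vertices=vertices,
            connectivity=entry["connectivity"],
            segment_ids=entry.get("segment_ids"),
            segment_names=entry.get("segment_names"),
            segment_types=entry.get("segment_types"),
            id=entry["id"],
        )
    except (KeyError, ValueError, StructureError) as exc:
        raise ParseError(f"malformed morphology payload: {exc}") from None
    morph = to_morphology(am)
    for g in entry.get("groups", []):
        morph.groups.append(
            SegmentGroup(
                id=g["id"],
                members=_expand_spans(g.get("spans", [])),
                includes=list(g.get("includes", [])),
            )
        )
    return morph


# ==========================================================================
# HDF5 (morphology only)

_H5_OPTS = dict(libver="latest", meta_block_size=512)


def write_hdf5(morph, path) -> None:
    """Write one morphology's arrays; anything else is unsupported (lossy)."""
    if isinstance(morph, NeuroMLDocument):
        raise UnsupportedError(
            "HDF5 serialization is morphology-only; pass an ArrayMorphology"
        )
    if isinstance(morph, Morphology):
        morph = from_morphology(morph)
    if not isinstance(morph, ArrayMorphology):
        raise UnsupportedError(f"cannot serialize {type(morph).__name__} to HDF5")
    with h5py.File(path, "w", **_H5_OPTS) as fh:
        group = fh.create_group("morphology")
        group.attrs["id"] = morph.id
        group.create_dataset("vertices", data=morph.vertices, dtype=np.float64, track_times=False)
        group.create_dataset(
            "connectivity", data=morph.connectivity, dtype=np.int64, track_times=False
        )


def load_hdf5(path) -> ArrayMorphology:
    try:
        with h5py.File(path, "r") as fh:
            if "morphology" not in fh:
                raise ParseError(f"{path}: missing /morphology group")
            group = fh["morphology"]
            if "vertices" not in group or "connectivity" not in group:
                raise ParseError(f"{path}: missing vertices/connectivity datasets")
            return ArrayMorphology(
                vertices=group["vertices"][...],
                connectivity=group["connectivity"][...],
                id=str(group.attrs.get("id", "morphology")),
            )
    except OSError as exc:
        raise ParseError(f"cannot open {path}: {exc}") from None


# ==========================================================================
# SWC (morphology only)

from dataclasses import dataclass


@dataclass(frozen=True)
class SwcRecord:
    """One SWC node: 1-based id, type code, position, radius, parent id (-1 root)."""

    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


def load_swc(path) -> Morphology:
    """Read SWC text into a Morphology (radius column doubled to diameters)."""
    records: list[SwcRecord] = []
    text = Path(path).read_text(encoding="utf-8") if os.path.exists(str(path)) else str(path)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 7:
            raise ParseError(f"SWC line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            records.append(
                SwcRecord(
                    id=int(fields[0]),
                    type=int(fields[1]),
                    x=float(fields[2]),
                    y=float(fields[3]),
                    z=float(fields[4]),
                    radius=float(fields[5]),
                    parent=int(fields[6]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"SWC line {lineno}: {exc}") from None
    if not records:
        raise ParseError("SWC file contains no records")
    by_id = {}
    for rec in records:
        if rec.id in by_id:
            raise ParseError(f"duplicate SWC id {rec.id}")
        by_id[rec.id] = rec
    roots = [r for r in records if r.parent == -1]
    if len(roots) != 1:
        raise ParseError(f"expected exactly one SWC root, found {len(roots)}")
    for rec in records:
        if rec.parent != -1 and rec.parent not in by_id:
            raise ParseError(f"SWC record {rec.id} references missing parent {rec.parent}")

    index_of = {rec.id: k for k, rec in enumerate(records)}
    vertices = np.array([[r.x, r.y, r.z, 2.0 * r.radius] for r in records])
    connectivity = np.array(
        [-1 if r.parent == -1 else index_of[r.parent] for r in records], dtype=np.int64
    )
    root_index = index_of[roots[0].id]
    non_root = [r for k, r in enumerate(records) if k != root_index]
    am = ArrayMorphology(
        vertices=vertices,
        connectivity=connectivity,
        segment_ids=np.arange(len(records) - 1, dtype=np.int64),
        segment_types=np.array(
            [r.type if r.type in TYPE_GROUPS else 0 for r in non_root], dtype=np.int64
        ),
        id="swc_import",
    )
    return to_morphology(am)


def _fmt_full(value: float) -> str:
    """Shortest decimal that round-trips the float exactly (SWC is not part
    of the fixed-size dialect, so nothing is gained by truncating)."""
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


def write_swc(morph) -> str:
    """Emit SWC text: 1-based contiguous ids, parents before children."""
    am = morph if isinstance(morph, ArrayMorphology) else from_morphology(morph)
    n = len(am.vertices)
    # topological order: root first, then children breadth-first
    children: dict[int, list[int]] = {}
    idx = am._segment_vertex_indices()
    meta_of = {int(v): k for k, v in enumerate(idx)}
    for v in idx:
        children.setdefault(int(am.connectivity[v]), []).append(int(v))
    order = [am.root_index]
    cursor = 0
    while cursor < len(order):
        order.extend(children.get(order[cursor], []))
        cursor += 1
    swc_id = {v: k + 1 for k, v in enumerate(order)}
    lines = ["# Generated by neurolems", "# id type x y z radius parent"]
    for v in order:
        row = am.vertices[v]
        if v == am.root_index:
            type_code, parent = 1, -1  # root node conventionally tagged soma
        else:
            type_code = int(am.segment_types[meta_of[v]])
            parent = swc_id[int(am.connectivity[v])]
        lines.append(
            f"{swc_id[v]} {type_code} {_fmt_full(row[0])} {_fmt_full(row[1])} "
            f"{_fmt_full(row[2])} {_fmt_full(row[3] / 2.0)} {parent}"
        )
    return "\n".join(lines) + "\n"


# ==========================================================================
# Reports


@dataclass(frozen=True)
class SerializationReport:
    format: str
    byte_size: int
    segment_count: int
    lossless: bool


_LOSSLESS = {"xml": True, "json": True, "hdf5": False, "swc": False}


def sniff_format(path) -> str:
    ext = Path(path).suffix.lower()
    if ext in (".nml", ".xml"):
        return "xml"
    if ext == ".json":
        return "json"
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    if ext == ".swc":
        return "swc"
    raise UnsupportedError(f"cannot infer format from extension {ext!r}")


def _segment_count(doc: NeuroMLDocument) -> int:
    total = 0
    for morph in doc.morphologies:
        if isinstance(morph, ArrayMorphology):
            total += morph.n_segments
        else:
            total += len(morph.segments)
    return total


def measure(path) -> SerializationReport:
    """File size from the filesystem plus a segment count from a parse."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = sniff_format(path)
    size = path.stat().st_size
    if fmt == "xml":
        count = _segment_count(load_neuroml_xml(path))
    elif fmt == "json":
        count = _segment_count(load_json(path))
    elif fmt == "hdf5":
        count = load_hdf5(path).n_segments
    else:
        count = len(load_swc(path).segments)
    return SerializationReport(
        format=fmt, byte_size=size, segment_count=count, lossless=_LOSSLESS[fmt]
    )
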