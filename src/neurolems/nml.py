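"""Object model for the NeuroML v2 subset handled by this toolkit.

Covers neuronal morphologies (trees of conical-frustum segments between 3D
points with diameters), point-neuron cells (Izhikevich, integrate-and-fire),
the two-exponential synapse, square current pulses, and networks built from
populations, projections and explicit inputs.  Cell/synapse parameters are
stored as their NeuroML quantity text (``"-65mV"``) so documents round-trip
with the author's spelling; SI conversion happens through the unit registry
when values are needed numerically.

Geometry conventions: coordinates and diameters are micrometres.  A segment
without an explicit proximal point inherits its attachment point on the
parent: ``fraction_along=1`` (the default) attaches at the parent's distal
point, ``fraction_along=0`` at its proximal point, and intermediate values
interpolate linearly along the parent's axis with linearly interpolated
diameter -- the only continuous choice for frusta.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import Issue, StructureError
from .units import UnitRegistry, builtin_registry, check_dimension, parse_quantity
from .errors import ParseError, UnitError

__all__ = [
    "Point3DWithDiam",
    "SegmentParent",
    "Segment",
    "SegmentGroup",
    "Morphology",
    "IzhikevichCell",
    "IafCell",
    "ExpTwoSynapse",
    "PulseGenerator",
    "Population",
    "Connection",
    "Projection",
    "ExplicitInput",
    "Network",
    "NeuroMLDocument",
    "frustum_lateral_area",
    "frustum_volume",
    "cell_totals",
    "element_to_type_name",
    "attribute_to_field_name",
    "validate_neuroml",
]


# --------------------------------------------------------------------------
# Morphology types


@dataclass
class Point3DWithDiam:
    x: float
    y: float
    z: float
    diameter: float


@dataclass
class SegmentParent:
    segment: int
    fraction_along: float = 1.0


@dataclass
class Segment:
    id: int
    distal: Point3DWithDiam
    proximal: Point3DWithDiam | None = None
    parent: SegmentParent | None = None
    name: str | None = None


@dataclass
class SegmentGroup:
    id: str
    members: list[int] = field(default_factory=list)
    includes: list[str] = field(default_factory=list)


@dataclass
class Morphology:
    id: str
    segments: list[Segment] = field(default_factory=list)
    groups: list[SegmentGroup] = field(default_factory=list)

    def segment_map(self) -> dict[int, Segment]:
        return {s.id: s for s in self.segments}

    def root(self) -> Segment | None:
        roots = [s for s in self.segments if s.parent is None]
        return roots[0] if len(roots) == 1 else None

    def resolved_proximal(self, seg: Segment, seg_map=None) -> Point3DWithDiam:
        """The segment's effective proximal point (explicit or inherited)."""
        if seg.proximal is not None:
            return seg.proximal
        if seg.parent is None:
            raise StructureError(f"root segment {seg.id} must carry a proximal point")
        seg_map = seg_map or self.segment_map()
        parent = seg_map.get(seg.parent.segment)
        if parent is None:
            raise StructureError(
                f"segment {seg.id} references unknown parent {seg.parent.segment}"
            )
        fraction = seg.parent.fraction_along
        p_prox = self.resolved_proximal(parent, seg_map)
        p_dist = parent.distal
        return Point3DWithDiam(
            p_prox.x + fraction * (p_dist.x - p_prox.x),
            p_prox.y + fraction * (p_dist.y - p_prox.y),
            p_prox.z + fraction * (p_dist.z - p_prox.z),
            p_prox.diameter + fraction * (p_dist.diameter - p_prox.diameter),
        )


# --------------------------------------------------------------------------
# Cells, synapses, inputs, networks


@dataclass
class IzhikevichCell:
    """Two-variable spiking cell; a, b, d dimensionless, c and thresh voltages."""

    id: str
    a: str
    b: str
    c: str
    d: str
    thresh: str


@dataclass
class IafCell:
    id: str
    leak_reversal: str
    thresh: str
    reset: str
    C: str
    leak_conductance: str


@dataclass
class ExpTwoSynapse:
    id: str
    gbase: str
    erev: str
    tau_rise: str
    tau_decay: str


@dataclass
class PulseGenerator:
    id: str
    delay: str
    duration: str
    amplitude: str


@dataclass
class Population:
    id: str
    component: str
    size: int


@dataclass
class Connection:
    id: int
    pre_cell_id: int
    post_cell_id: int


@dataclass
class Projection:
    id: str
    presynaptic_population: str
    postsynaptic_population: str
    synapse: str
    connections: list[Connection] = field(default_factory=list)


@dataclass
class ExplicitInput:
    target: str  # "population[index]"
    input: str


@dataclass
class Network:
    id: str
    populations: list[Population] = field(default_factory=list)
    projections: list[Projection] = field(default_factory=list)
    explicit_inputs: list[ExplicitInput] = field(default_factory=list)


@dataclass
class NeuroMLDocument:
    id: str
    izhikevich_cells: list[IzhikevichCell] = field(default_factory=list)
    iaf_cells: list[IafCell] = field(default_factory=list)
    synapses: list[ExpTwoSynapse] = field(default_factory=list)
    pulse_generators: list[PulseGenerator] = field(default_factory=list)
    morphologies: list = field(default_factory=list)  # Morphology or ArrayMorphology
    networks: list[Network] = field(default_factory=list)
    load_issues: list[Issue] = field(default_factory=list)

    def all_component_ids(self):
        for group in (
            self.izhikevich_cells,
            self.iaf_cells,
            self.synapses,
            self.pulse_generators,
        ):
            for item in group:
                yield item.id


# --------------------------------------------------------------------------
# Geometry helpers


def _distance(p: Point3DWithDiam, d: Point3DWithDiam) -> float:
    return math.sqrt((p.x - d.x) ** 2 + (p.y - d.y) ** 2 + (p.z - d.z) ** 2)


def frustum_lateral_area(p: Point3DWithDiam, d: Point3DWithDiam) -> float:
    """Lateral surface of the conical frustum between two points, in µm².

    ``pi * (r1 + r2) * sqrt((r1 - r2)^2 + h^2)`` with radii from the point
    diameters and h the Euclidean distance.  Degenerate frusta (h = 0,
    equal radii) have zero lateral area.
    """
    r1 = p.diameter / 2.0
    r2 = d.diameter / 2.0
    h = _distance(p, d)
    return math.pi * (r1 + r2) * math.sqrt((r1 - r2) ** 2 + h ** 2)


def frustum_volume(p: Point3DWithDiam, d: Point3DWithDiam) -> float:
    """Volume of the conical frustum between two points, in µm³."""
    r1 = p.diameter / 2.0
    r2 = d.diameter / 2.0
    h = _distance(p, d)
    return (math.pi * h / 3.0) * (r1 * r1 + r1 * r2 + r2 * r2)


def cell_totals(m: Morphology) -> tuple[float, float]:
    """Total (lateral area µm², volume µm³) summed over all segments."""
    seg_map = m.segment_map()
    area = 0.0
    volume = 0.0
    for seg in m.segments:
        prox = m.resolved_proximal(seg, seg_map)
        area += frustum_lateral_area(prox, seg.distal)
        volume += frustum_volume(prox, seg.distal)
    return area, volume


# --------------------------------------------------------------------------
# Naming conversion (NeuroML camelCase <-> Python conventions)


def element_to_type_name(name: str) -> str:
    """XML element name -> Python class name: capitalize, keep camel humps."""
    if not name:
        return name
    return name[0].upper() + name[1:]


_CAMEL_SPLIT = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")


def attribute_to_field_name(name: str) -> str:
    """XML attribute name -> snake_case field name.

    Underscores go before interior capitals; digits stay with the run they
    follow (``q10Settings -> q10_settings``).  Idempotent on names that are
    already snake_case.
    """
    return _CAMEL_SPLIT.sub("_", name).lower()


# --------------------------------------------------------------------------
# Validation

# expected dimension per quantity-valued field
_CELL_DIMENSIONS = {
    IzhikevichCell: {"a": "none", "b": "none", "c": "voltage", "d": "none", "thresh": "voltage"},
    IafCell: {
        "leak_reversal": "voltage",
        "thresh": "voltage",
        "reset": "voltage",
        "C": "capacitance",
        "leak_conductance": "conductance",
    },
    ExpTwoSynapse: {
        "gbase": "conductance",
        "erev": "voltage",
        "tau_rise": "time",
        "tau_decay": "time",
    },
    PulseGenerator: {"delay": "time", "duration": "time", "amplitude": "current"},
}

_TARGET_RE = re.compile(r"^([A-Za-z_][A-Za-z_0-9]*)\[(\d+)\]$")


def validate_neuroml(doc: NeuroMLDocument, registry: UnitRegistry | None = None) -> list[Issue]:
    """Structural validation of a document; issues are data, never raised."""
    from .arraymorph import ArrayMorphology  # local import to avoid a cycle

    registry = registry or builtin_registry()
    issues: list[Issue] = []

    # unique ids per element class
    for label, items in [
        ("izhikevichCell", doc.izhikevich_cells),
        ("iafCell", doc.iaf_cells),
        ("expTwoSynapse", doc.synapses),
        ("pulseGenerator", doc.pulse_generators),
        ("morphology", doc.morphologies),
        ("network", doc.networks),
    ]:
        seen = set()
        for item in items:
            if item.id in seen:
                issues.append(Issue("error", f"duplicate {label} id {item.id!r}"))
            seen.add(item.id)

    # quantity dimension checks
    for group in (doc.izhikevich_cells, doc.iaf_cells, doc.synapses, doc.pulse_generators):
        for item in group:
            expected = _CELL_DIMENSIONS[type(item)]
            for fname, dim in expected.items():
                text = getattr(item, fname)
                loc = f"{type(item).__name__} {item.id}.{fname}"
                try:
                    q = parse_quantity(text, registry)
                except (ParseError, UnitError) as exc:
                    issues.append(Issue("error", str(exc), loc))
                    continue
                if not check_dimension(q, dim, registry):
                    issues.append(
                        Issue("error", f"{text!r} does not match dimension {dim!r}", loc)
                    )

    for morph in doc.morphologies:
        if isinstance(morph, ArrayMorphology):
            continue  # array invariants are enforced by the class itself
        issues.extend(_validate_morphology(morph))

    component_ids = set(doc.all_component_ids())
    input_ids = {p.id for p in doc.pulse_generators}
    synapse_ids = {s.id for s in doc.synapses}
    for net in doc.networks:
        pops = {p.id: p for p in net.populations}
        for pop in net.populations:
            if pop.component not in component_ids:
                issues.append(
                    Issue("error", f"population {pop.id!r} references unknown component {pop.component!r}")
                )
            if pop.size < 0:
                issues.append(Issue("error", f"population {pop.id!r} has negative size"))
        for proj in net.projections:
            for role, pop_id in (
                ("presynaptic", proj.presynaptic_population),
                ("postsynaptic", proj.postsynaptic_population),
            ):
                if pop_id not in pops:
                    issues.append(
                        Issue("error", f"projection {proj.id!r} references unknown {role} population {pop_id!r}")
                    )
            if proj.synapse not in synapse_ids:
                issues.append(
                    Issue("error", f"projection {proj.id!r} references unknown synapse {proj.synapse!r}")
                )
            pre = pops.get(proj.presynaptic_population)
            post = pops.get(proj.postsynaptic_population)
            for conn in proj.connections:
                if pre is not None and not (0 <= conn.pre_cell_id < pre.size):
                    issues.append(
                        Issue("error", f"connection {conn.id} pre index {conn.pre_cell_id} out of range")
                    )
                if post is not None and not (0 <= conn.post_cell_id < post.size):
                    issues.append(
                        Issue("error", f"connection {conn.id} post index {conn.post_cell_id} out of range")
                    )
        for ei in net.explicit_inputs:
            match = _TARGET_RE.match(ei.target)
            if match is None:
                issues.append(Issue("error", f"malformed explicitInput target {ei.target!r}"))
            else:
                pop = pops.get(match.group(1))
                if pop is None:
                    issues.append(
                        Issue("error", f"explicitInput targets unknown population {match.group(1)!r}")
                    )
                elif int(match.group(2)) >= pop.size:
                    issues.append(
                        Issue("error", f"explicitInput index {match.group(2)} out of range for {pop.id!r}")
                    )
            if ei.input not in input_ids:
                issues.append(Issue("error", f"explicitInput references unknown input {ei.input!r}"))
    return issues


def _validate_morphology(morph: Morphology) -> list[Issue]:
    issues: list[Issue] = []
    loc = f"morphology {morph.id}"
    seen = set()
    for seg in morph.segments:
        if seg.id in seen:
            issues.append(Issue("error", f"duplicate segment id {seg.id}", loc))
        seen.add(seg.id)
        if seg.id < 0:
            issues.append(Issue("error", f"negative segment id {seg.id}", loc))
        for point in (seg.proximal, seg.distal):
            if point is None:
                continue
            if point.diameter < 0:
                issues.append(Issue("error", f"segment {seg.id}: negative diameter", loc))
            if not all(math.isfinite(v) for v in (point.x, point.y, point.z)):
                issues.append(Issue("error", f"segment {seg.id}: non-finite coordinate", loc))
        if seg.parent is not None and not (0.0 <= seg.parent.fraction_along <= 1.0):
            issues.append(
                Issue("error", f"segment {seg.id}: fractionAlong outside [0,1]", loc)
            )
        if (
            seg.proximal is not None
            and seg.proximal.x == seg.distal.x
            and seg.proximal.y == seg.distal.y
            and seg.proximal.z == seg.distal.z
        ):
            issues.append(
                Issue(
                    "warning",
                    f"segment {seg.id} has zero length (spherical soma?); "
                    "consider modeling the soma as a cylinder",
                    loc,
                )
            )

    roots = [s for s in morph.segments if s.parent is None]
    if morph.segments and len(roots) != 1:
        issues.append(Issue("error", f"expected exactly one root segment, found {len(roots)}", loc))
    for root in roots:
        if root.proximal is None:
            issues.append(Issue("error", f"root segment {root.id} lacks a proximal point", loc))

    seg_map = {s.id: s for s in morph.segments}
    for seg in morph.segments:
        if seg.parent is not None and seg.parent.segment not in seg_map:
            issues.append(
                Issue("error", f"segment {seg.id} references unknown parent {seg.parent.segment}", loc)
            )
    # cycle check by walking parent chains with memoization
    status: dict[int, int] = {}
    for seg in morph.segments:
        chain = []
        current = seg
        while current is not None and status.get(current.id) is None:
            chain.append(current.id)
            status[current.id] = 0
            if current.parent is None:
                current = None
            else:
                nxt = seg_map.get(current.parent.segment)
                if nxt is not None and status.get(nxt.id) == 0:
                    issues.append(Issue("error", f"cycle in segment parentage at {nxt.id}", loc))
                    current = None
                else:
                    current = nxt
        for sid in chain:
            status[sid] = 1

    group_ids = {g.id for g in morph.groups}
    for group in morph.groups:
        for member in group.members:
            if member not in seg_map:
                issues.append(Issue("error", f"group {group.id!r} member {member} does not exist", loc))
        for inc in group.includes:
            if inc not in group_ids:
                issues.append(Issue("error", f"group {group.id!r} includes unknown group {inc!r}", loc))
    # include graph acyclic
    inc_map = {g.id: g.includes for g in morph.groups}
    state: dict[str, int] = {}

    def visit(gid):
        if state.get(gid) == 1:
            return
        if state.get(gid) == 0:
            issues.append(Issue("error", f"cyclic group includes through {gid!r}", loc))
            return
        state[gid] = 0
        for inc in inc_map.get(gid, []):
            if inc in inc_map:
                visit(inc)
        state[gid] = 1

    for gid in inc_map:
        visit(gid)
    return issues
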