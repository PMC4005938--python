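"""Flat-array morphology representation, interchangeable with ``Morphology``.

Storage is node-based in the SWC spirit: one row of ``vertices`` (x, y, z,
diameter; µm) per 3D point, and a ``connectivity`` array of parent vertex
indices with ``-1`` marking the single root.  A segment is the conical
frustum along the edge from a non-root vertex to its parent, so N vertices
encode N-1 segments.  Storage per vertex is exactly 4 reals + 1 integer,
independent of tree size -- the whole point of the representation.

Segment-level access stays available through :class:`SegmentView`, a
write-through proxy: mutations through a view land in the arrays and are
visible to the next :func:`totals` call, and low-level array edits are
visible through views.

Representable subset: branch points share their single parent vertex, so
per-child proximal overrides and intermediate ``fraction_along`` attachments
cannot be expressed; conversion rejects them with a clear error.  Children
attached to the root *segment* at ``fraction_along=0`` are representable
(they become siblings sharing the root vertex) and are how multi-neurite
somata round-trip.
"""

from __future__ import annotations

import numpy as np

from .errors import StructureError
from .nml import Morphology, Point3DWithDiam, Segment, SegmentGroup, SegmentParent

__all__ = ["ArrayMorphology", "SegmentView", "from_morphology", "to_morphology", "totals"]

_COORD_ATOL = 1e-9


class ArrayMorphology:
    """Vertex/connectivity arrays plus optional per-segment metadata."""

    def __init__(
        self,
        vertices,
        connectivity,
        segment_ids=None,
        segment_names=None,
        segment_types=None,
        id: str = "morphology",
    ):
        self.id = id
        self.vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 4)
        self.connectivity = np.asarray(connectivity, dtype=np.int64).reshape(-1)
        n = len(self.vertices)
        if n < 1:
            raise StructureError("an array morphology needs at least the root vertex")
        if len(self.connectivity) != n:
            raise StructureError("vertices and connectivity lengths differ")
        roots = np.flatnonzero(self.connectivity == -1)
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root (-1) entry, found {len(roots)}")
        self.root_index = int(roots[0])
        others = np.delete(np.arange(n), self.root_index)
        bad = (self.connectivity[others] < 0) | (self.connectivity[others] >= n)
        if np.any(bad) or np.any(self.connectivity[others] == others):
            raise StructureError("connectivity entries must index another existing vertex")
        self._check_single_tree()

        self.segment_ids = (
            np.asarray(segment_ids, dtype=np.int64)
            if segment_ids is not None
            else np.arange(n - 1, dtype=np.int64)
        )
        if len(self.segment_ids) != n - 1:
            raise StructureError("segment_ids must have one entry per non-root vertex")
        self.segment_names = list(segment_names) if segment_names is not None else None
        if self.segment_names is not None and len(self.segment_names) != n - 1:
            raise StructureError("segment_names must have one entry per non-root vertex")
        self.segment_types = (
            np.asarray(segment_types, dtype=np.int64)
            if segment_types is not None
            else np.zeros(n - 1, dtype=np.int64)
        )
        if len(self.segment_types) != n - 1:
            raise StructureError("segment_types must have one entry per non-root vertex")

    def _check_single_tree(self):
        n = len(self.vertices)
        # follow parents with path tracking; every vertex must reach the root
        state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 on path, 2 done
        state[self.root_index] = 2
        for start in range(n):
            path = []
            v = start
            while state[v] == 0:
                state[v] = 1
                path.append(v)
                v = int(self.connectivity[v])
            if state[v] == 1:
                raise StructureError("connectivity contains a cycle")
            for u in path:
                state[u] = 2

    # -- basic properties --------------------------------------------------

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_segments(self) -> int:
        return len(self.vertices) - 1

    def _segment_vertex_indices(self) -> np.ndarray:
        """Non-root vertex indices in ascending order (one per segment)."""
        return np.delete(np.arange(len(self.vertices)), self.root_index)

    # -- construction ------------------------------------------------------

    def append_child(self, parent_index: int, point: Point3DWithDiam) -> int:
        """Add a vertex under ``parent_index``; returns the new vertex index."""
        n = len(self.vertices)
        if not 0 <= parent_index < n:
            raise IndexError(f"parent index {parent_index} out of range [0, {n})")
        row = np.array([[point.x, point.y, point.z, point.diameter]])
        self.vertices = np.vstack([self.vertices, row])
        self.connectivity = np.append(self.connectivity, np.int64(parent_index))
        next_id = int(self.segment_ids.max()) + 1 if len(self.segment_ids) else 0
        self.segment_ids = np.append(self.segment_ids, np.int64(next_id))
        if self.segment_names is not None:
            self.segment_names.append(f"segment_{next_id}")
        self.segment_types = np.append(self.segment_types, np.int64(0))
        return n

    # -- segment-level access ---------------------------------------------

    @property
    def segments(self) -> list["SegmentView"]:
        return [SegmentView(self, int(v)) for v in self._segment_vertex_indices()]

    def segment_view(self, segment_id: int) -> "SegmentView":
        pos = np.flatnonzero(self.segment_ids == segment_id)
        if len(pos) != 1:
            raise StructureError(f"no unique segment with id {segment_id}")
        return SegmentView(self, int(self._segment_vertex_indices()[pos[0]]))

    # -- geometry ----------------------------------------------------------

    def totals(self) -> tuple[float, float]:
        """Vectorized (total lateral area µm², total volume µm³)."""
        idx = self._segment_vertex_indices()
        if len(idx) == 0:
            return 0.0, 0.0
        child = self.vertices[idx]
        parent = self.vertices[self.connectivity[idx]]
        r1 = parent[:, 3] / 2.0
        r2 = child[:, 3] / 2.0
        h = np.sqrt(np.sum((parent[:, :3] - child[:, :3]) ** 2, axis=1))
        area = np.pi * (r1 + r2) * np.sqrt((r1 - r2) ** 2 + h ** 2)
        volume = (np.pi * h / 3.0) * (r1 ** 2 + r1 * r2 + r2 ** 2)
        return float(area.sum()), float(volume.sum())


class SegmentView:
    """Write-through Segment facade over one non-root vertex."""

    __slots__ = ("morph", "vertex_index")

    def __init__(self, morph: ArrayMorphology, vertex_index: int):
        if vertex_index == morph.root_index:
            raise StructureError("the root vertex has no segment")
        self.morph = morph
        self.vertex_index = vertex_index

    def _meta_index(self) -> int:
        idx = self.morph._segment_vertex_indices()
        return int(np.flatnonzero(idx == self.vertex_index)[0])

    @property
    def id(self) -> int:
        return int(self.morph.segment_ids[self._meta_index()])

    @property
    def name(self) -> str:
        names = self.morph.segment_names
        return names[self._meta_index()] if names is not None else f"segment_{self.id}"

    @property
    def parent_vertex(self) -> int:
        return int(self.morph.connectivity[self.vertex_index])

    @property
    def proximal(self) -> Point3DWithDiam:
        row = self.morph.vertices[self.parent_vertex]
        return Point3DWithDiam(*map(float, row))

    @proximal.setter
    def proximal(self, point: Point3DWithDiam):
        self.morph.vertices[self.parent_vertex] = (point.x, point.y, point.z, point.diameter)

    @property
    def distal(self) -> Point3DWithDiam:
        row = self.morph.vertices[self.vertex_index]
        return Point3DWithDiam(*map(float, row))

    @distal.setter
    def distal(self, point: Point3DWithDiam):
        self.morph.vertices[self.vertex_index] = (point.x, point.y, point.z, point.diameter)

    @property
    def distal_diameter(self) -> float:
        return float(self.morph.vertices[self.vertex_index, 3])

    @distal_diameter.setter
    def distal_diameter(self, value: float):
        self.morph.vertices[self.vertex_index, 3] = value


# --------------------------------------------------------------------------
# Conversion


def _points_equal(a: Point3DWithDiam, b) -> bool:
    return (
        abs(a.x - b[0]) <= _COORD_ATOL
        and abs(a.y - b[1]) <= _COORD_ATOL
        and abs(a.z - b[2]) <= _COORD_ATOL
        and abs(a.diameter - b[3]) <= _COORD_ATOL
    )


def from_morphology(m: Morphology) -> ArrayMorphology:
    """Convert an object morphology to arrays.

    One vertex for the root's proximal point plus one per segment distal.
    Segments must attach at ``fraction_along`` 1 (parent distal) or 0
    (parent proximal); anything else, or an explicit proximal that differs
    from the attachment point, is not representable and raises
    :class:`StructureError`.
    """
    if not m.segments:
        return ArrayMorphology(
            vertices=np.zeros((1, 4)), connectivity=np.array([-1]), id=m.id
        )
    root = m.root()
    if root is None:
        raise StructureError("morphology must have exactly one root segment")
    if root.proximal is None:
        raise StructureError(f"root segment {root.id} lacks a proximal point")
    seg_map = m.segment_map()

    order: list[Segment] = []
    placed: set[int] = set()
    remaining = list(m.segments)
    while remaining:
        progressed = False
        still = []
        for seg in remaining:
            if seg.parent is None or seg.parent.segment in placed:
                order.append(seg)
                placed.add(seg.id)
                progressed = True
            else:
                still.append(seg)
        if not progressed:
            raise StructureError("segment parentage is not a tree (cycle or dangling parent)")
        remaining = still

    vertices = [[root.proximal.x, root.proximal.y, root.proximal.z, root.proximal.diameter]]
    connectivity = [-1]
    seg_vertex: dict[int, int] = {}  # segment id -> distal vertex index
    seg_ids, names, types = [], [], []
    type_by_segment = _types_from_groups(m)

    for seg in order:
        if seg.parent is None:
            parent_vertex = 0
            attach = root.proximal
        else:
            fraction = seg.parent.fraction_along
            parent_seg = seg_map[seg.parent.segment]
            if fraction == 1.0:
                parent_vertex = seg_vertex[parent_seg.id]
                attach = parent_seg.distal
            elif fraction == 0.0:
                parent_vertex = int(connectivity[seg_vertex[parent_seg.id]])
                attach = m.resolved_proximal(parent_seg, seg_map)
            else:
                raise StructureError(
                    f"segment {seg.id}: fractionAlong={fraction} is not representable "
                    "in array form (only 0 and 1 are)"
                )
        if seg.proximal is not None and not _points_equal(
            seg.proximal,
            (attach.x, attach.y, attach.z, attach.diameter),
        ):
            raise StructureError(
                f"segment {seg.id}: explicit proximal differs from the parent "
                "attachment point; per-child proximal overrides are not "
                "representable in array form"
            )
        vertices.append([seg.distal.x, seg.distal.y, seg.distal.z, seg.distal.diameter])
        connectivity.append(parent_vertex)
        seg_vertex[seg.id] = len(vertices) - 1
        seg_ids.append(seg.id)
        names.append(seg.name if seg.name is not None else f"segment_{seg.id}")
        types.append(type_by_segment.get(seg.id, 0))

    return ArrayMorphology(
        vertices=np.array(vertices),
        connectivity=np.array(connectivity),
        segment_ids=np.array(seg_ids),
        segment_names=names,
        segment_types=np.array(types),
        id=m.id,
    )


#: SWC type code <-> canonical segment-group tag
TYPE_GROUPS = {
    1: "soma_group",
    2: "axon_group",
    3: "dendrite_group",
    4: "apical_dendrite_group",
}
_GROUP_TYPES = {name: code for code, name in TYPE_GROUPS.items()}


def _types_from_groups(m: Morphology) -> dict[int, int]:
    out: dict[int, int] = {}
    for group in m.groups:
        code = _GROUP_TYPES.get(group.id)
        if code is not None:
            for member in group.members:
                out[member] = code
    return out


def groups_from_types(segment_ids, segment_types) -> list[SegmentGroup]:
    """Rebuild the canonical type groups plus an ``all`` group."""
    groups = [SegmentGroup(id="all", members=[int(s) for s in segment_ids])]
    for code, name in TYPE_GROUPS.items():
        members = [int(s) for s, t in zip(segment_ids, segment_types) if int(t) == code]
        if members:
            groups.append(SegmentGroup(id=name, members=members))
    return groups


def to_morphology(am: ArrayMorphology) -> Morphology:
    """Convert arrays back to an object morphology.

    Each non-root vertex becomes a segment with that vertex as distal point
    and an explicit proximal copied from its parent vertex.  Extra children
    of the root vertex attach to the first root-child segment at
    ``fraction_along=0`` so the result keeps exactly one root segment.
    """
    idx = am._segment_vertex_indices()
    meta_of_vertex = {int(v): meta for meta, v in enumerate(idx)}
    # breadth-first from the root so parents gain segment ids before children
    children: dict[int, list[int]] = {}
    for v in idx:
        children.setdefault(int(am.connectivity[v]), []).append(int(v))
    topo: list[int] = [am.root_index]
    cursor = 0
    while cursor < len(topo):
        topo.extend(children.get(topo[cursor], []))
        cursor += 1
    topo = topo[1:]  # drop the root; it owns no segment

    seg_of_vertex: dict[int, int] = {}  # vertex index -> segment id
    by_vertex: dict[int, Segment] = {}
    root_child_segment: int | None = None
    names = am.segment_names
    for v in topo:
        meta = meta_of_vertex[v]
        sid = int(am.segment_ids[meta])
        name = names[meta] if names is not None else f"segment_{sid}"
        parent_vertex = int(am.connectivity[v])
        proximal = Point3DWithDiam(*map(float, am.vertices[parent_vertex]))
        distal = Point3DWithDiam(*map(float, am.vertices[v]))
        if parent_vertex == am.root_index:
            if root_child_segment is None:
                parent = None
                root_child_segment = sid
            else:
                parent = SegmentParent(segment=root_child_segment, fraction_along=0.0)
        else:
            parent = SegmentParent(segment=seg_of_vertex[parent_vertex], fraction_along=1.0)
        seg_of_vertex[v] = sid
        by_vertex[v] = Segment(id=sid, distal=distal, proximal=proximal, parent=parent, name=name)
    # emit in the arrays' segment order so metadata alignment round-trips
    segments = [by_vertex[int(v)] for v in idx]

    groups = groups_from_types(am.segment_ids, am.segment_types)
    if not segments:
        groups = []
    return Morphology(id=am.id, segments=segments, groups=groups)


def totals(am: ArrayMorphology) -> tuple[float, float]:
    """Module-level alias for :meth:`ArrayMorphology.totals`."""
    return am.totals()
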