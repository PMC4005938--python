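import numpy as np
import pytest

from conftest import random_array_morphology
from neurolems.arraymorph import ArrayMorphology, from_morphology, to_morphology, totals
from neurolems.errors import StructureError
from neurolems.nml import Morphology, Point3DWithDiam, Segment, SegmentParent, cell_totals


def _chain_morphology(n):
    segments = [
        Segment(
            id=0,
            proximal=Point3DWithDiam(0, 0, 0, 10),
            distal=Point3DWithDiam(10, 0, 0, 10),
        )
    ]
    for k in range(1, n):
        segments.append(
            Segment(
                id=k,
                distal=Point3DWithDiam(10 * (k + 1), 0, 0, 10),
                parent=SegmentParent(segment=k - 1),
            )
        )
    return Morphology(id="chain", segments=segments)


class TestConstruction:
    def test_single_cylinder(self):
        am = from_morphology(_chain_morphology(1))
        assert len(am) == 2
        assert am.connectivity.tolist() == [-1, 0]

    def test_unbranched_chain(self):
        am = from_morphology(_chain_morphology(3))
        assert len(am) == 4
        assert am.connectivity.tolist() == [-1, 0, 1, 2]

    def test_branch_point_shares_parent_vertex(self):
        morph = _chain_morphology(2)
        morph.segments.append(
            Segment(
                id=2,
                distal=Point3DWithDiam(10, 10, 0, 6),
                parent=SegmentParent(segment=0),
            )
        )
        am = from_morphology(morph)
        assert am.connectivity.tolist() == [-1, 0, 1, 1]

    def test_two_minus_ones_rejected(self):
        with pytest.raises(StructureError):
            ArrayMorphology(
                vertices=np.zeros((3, 4)), connectivity=np.array([-1, -1, 0])
            )

    def test_cycle_rejected(self):
        with pytest.raises(StructureError):
            ArrayMorphology(
                vertices=np.zeros((3, 4)), connectivity=np.array([-1, 2, 1])
            )

    def test_intermediate_fraction_along_not_representable(self):
        morph = _chain_morphology(1)
        morph.segments.append(
            Segment(
                id=1,
                distal=Point3DWithDiam(5, 5, 0, 4),
                parent=SegmentParent(segment=0, fraction_along=0.5),
            )
        )
        with pytest.raises(StructureError, match="fractionAlong"):
            from_morphology(morph)

    def test_proximal_override_not_representable(self):
        morph = _chain_morphology(2)
        morph.segments[1].proximal = Point3DWithDiam(10, 0, 0, 3.0)  # thinner start
        with pytest.raises(StructureError, match="proximal"):
            from_morphology(morph)


class TestAppendChild:
    def test_append_to_root(self):
        am = ArrayMorphology(vertices=np.zeros((1, 4)), connectivity=np.array([-1]))
        index = am.append_child(0, Point3DWithDiam(1, 0, 0, 2))
        assert index == 1
        assert am.connectivity.tolist() == [-1, 0]

    def test_two_appends_make_branch(self):
        am = ArrayMorphology(vertices=np.zeros((1, 4)), connectivity=np.array([-1]))
        am.append_child(0, Point3DWithDiam(1, 0, 0, 2))
        am.append_child(1, Point3DWithDiam(2, 0, 0, 2))
        am.append_child(1, Point3DWithDiam(1, 1, 0, 2))
        assert am.connectivity.tolist() == [-1, 0, 1, 1]

    def test_bad_parent_raises_index_error(self):
        am = ArrayMorphology(vertices=np.zeros((1, 4)), connectivity=np.array([-1]))
        with pytest.raises(IndexError):
            am.append_child(1, Point3DWithDiam(0, 0, 0, 1))


class TestRoundTrip:
    def test_root_only_gives_zero_segments(self):
        am = ArrayMorphology(vertices=np.zeros((1, 4)), connectivity=np.array([-1]))
        assert to_morphology(am).segments == []
        assert totals(am) == (0.0, 0.0)

    def test_per_segment_geometry_preserved_on_random_trees(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            am = random_array_morphology(rng, int(rng.integers(1, 60)))
            morph = to_morphology(am)
            am2 = from_morphology(morph)
            assert np.allclose(am.vertices, am2.vertices, rtol=1e-12, atol=0)
            assert np.array_equal(am.connectivity, am2.connectivity)

    def test_multiple_root_children_keep_single_root_segment(self):
        am = ArrayMorphology(vertices=np.zeros((1, 4)) + 1.0, connectivity=np.array([-1]))
        am.append_child(0, Point3DWithDiam(5, 1, 1, 2))
        am.append_child(0, Point3DWithDiam(1, 5, 1, 2))
        morph = to_morphology(am)
        roots = [s for s in morph.segments if s.parent is None]
        assert len(roots) == 1
        other = [s for s in morph.segments if s.parent is not None][0]
        assert other.parent.fraction_along == 0.0
        # geometry must be identical either way
        assert totals(am) == pytest.approx(cell_totals(morph), rel=1e-12)


class TestTotals:
    def test_single_cylinder_closed_form(self):
        import math

        am = from_morphology(_chain_morphology(1))
        area, volume = totals(am)
        assert area == pytest.approx(100 * math.pi)
        assert volume == pytest.approx(250 * math.pi)

    def test_object_model_oracle_on_random_trees(self):
        """Equivalence on 50 random morphologies, 10-5000 segments, rel 1e-9."""
        rng = np.random.default_rng(5)
        sizes = list(rng.integers(10, 400, size=48)) + [2000, 5000]
        for n in sizes:
            am = random_array_morphology(rng, int(n))
            a_arr, v_arr = totals(am)
            a_obj, v_obj = cell_totals(to_morphology(am))
            assert a_arr == pytest.approx(a_obj, rel=1e-9)
            assert v_arr == pytest.approx(v_obj, rel=1e-9)


class TestSegmentView:
    def test_write_through_diameter_changes_totals(self):
        am = from_morphology(_chain_morphology(2))
        before = totals(am)
        view = am.segment_view(1)
        view.distal_diameter = 2.0
        assert am.vertices[2, 3] == 2.0
        after = totals(am)
        assert after[0] < before[0]

    def test_array_edit_visible_through_view(self):
        am = from_morphology(_chain_morphology(2))
        am.vertices[1, 0] = 42.0
        assert am.segment_view(0).distal.x == 42.0

    def test_memory_contract_is_flat_arrays(self):
        am = from_morphology(_chain_morphology(100))
        assert am.vertices.shape == (101, 4)
        assert am.vertices.dtype == np.float64
        assert am.connectivity.shape == (101,)
        assert am.connectivity.dtype == np.int64
        # exactly 4 reals + 1 integer per vertex
        assert am.vertices.nbytes + am.connectivity.nbytes == 101 * (4 * 8 + 8)
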