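import math

import numpy as np
import pytest

from neurolems.fixtures import example_network_document, two_segment_document
from neurolems.nml import (
    Morphology,
    Point3DWithDiam,
    Segment,
    SegmentParent,
    attribute_to_field_name,
    cell_totals,
    element_to_type_name,
    frustum_lateral_area,
    frustum_volume,
    validate_neuroml,
)


def _cylinder(r, h):
    return (
        Point3DWithDiam(0, 0, 0, 2 * r),
        Point3DWithDiam(h, 0, 0, 2 * r),
    )


class TestFrustumGeometry:
    def test_cylinder_closed_forms(self):
        p, d = _cylinder(5.0, 10.0)
        assert frustum_lateral_area(p, d) == pytest.approx(100 * math.pi)
        assert frustum_volume(p, d) == pytest.approx(250 * math.pi)

    def test_cone_closed_forms(self):
        p = Point3DWithDiam(0, 0, 0, 6.0)
        d = Point3DWithDiam(0, 4.0, 0, 0.0)
        assert frustum_lateral_area(p, d) == pytest.approx(15 * math.pi)  # slant 5
        assert frustum_volume(p, d) == pytest.approx(12 * math.pi)

    def test_degenerate_frustum_is_zero(self):
        p = Point3DWithDiam(1, 2, 3, 8.0)
        d = Point3DWithDiam(1, 2, 3, 8.0)
        assert frustum_lateral_area(p, d) == 0.0
        assert frustum_volume(p, d) == 0.0

    def test_matches_surface_and_solid_of_revolution(self):
        """Numeric-integration oracle on 100 random frusta, rel err < 1e-6."""
        rng = np.random.default_rng(7)
        slices = 10_000
        t = (np.arange(slices) + 0.5) / slices
        for _ in range(100):
            r1, r2 = rng.uniform(0.1, 8.0, size=2)
            h = rng.uniform(0.5, 30.0)
            p = Point3DWithDiam(0, 0, 0, 2 * r1)
            d = Point3DWithDiam(0, 0, h, 2 * r2)
            radius = r1 + (r2 - r1) * t
            slant = math.sqrt(h * h + (r2 - r1) ** 2)
            area_num = float(np.sum(2 * math.pi * radius * slant / slices))
            vol_num = float(np.sum(math.pi * radius ** 2 * h / slices))
            assert frustum_lateral_area(p, d) == pytest.approx(area_num, rel=1e-6)
            assert frustum_volume(p, d) == pytest.approx(vol_num, rel=1e-6)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = Point3DWithDiam(*rng.uniform(-50, 50, 3), rng.uniform(0, 10))
            d = Point3DWithDiam(*rng.uniform(-50, 50, 3), rng.uniform(0, 10))
            assert frustum_lateral_area(p, d) >= 0.0
            assert frustum_volume(p, d) >= 0.0


class TestCellTotals:
    def test_single_root_cylinder(self):
        morph = Morphology(
            id="m",
            segments=[Segment(id=0, proximal=_cylinder(5, 10)[0], distal=_cylinder(5, 10)[1])],
        )
        area, volume = cell_totals(morph)
        assert area == pytest.approx(100 * math.pi)
        assert volume == pytest.approx(250 * math.pi)

    def test_child_inherits_parent_distal_as_proximal(self):
        p, d = _cylinder(5, 10)
        morph = Morphology(
            id="m",
            segments=[
                Segment(id=0, proximal=p, distal=d),
                Segment(
                    id=1,
                    distal=Point3DWithDiam(20, 0, 0, 10.0),
                    parent=SegmentParent(segment=0),
                ),
            ],
        )
        area, volume = cell_totals(morph)
        assert area == pytest.approx(200 * math.pi)
        assert volume == pytest.approx(500 * math.pi)

    def test_fraction_along_interpolates_linearly(self):
        p, d = _cylinder(5, 10)
        morph = Morphology(
            id="m",
            segments=[
                Segment(id=0, proximal=p, distal=d),
                Segment(
                    id=1,
                    distal=Point3DWithDiam(5, 7, 0, 10.0),
                    parent=SegmentParent(segment=0, fraction_along=0.5),
                ),
            ],
        )
        prox = morph.resolved_proximal(morph.segments[1])
        assert (prox.x, prox.y, prox.z, prox.diameter) == (5.0, 0.0, 0.0, 10.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        from conftest import random_array_morphology
        from neurolems.arraymorph import to_morphology

        morph = to_morphology(random_array_morphology(rng, 40))
        base = cell_totals(morph)
        shuffled = Morphology(id=morph.id, segments=list(morph.segments), groups=morph.groups)
        rng.shuffle(shuffled.segments)
        assert cell_totals(shuffled) == pytest.approx(base)

    def test_empty_morphology_is_zero(self):
        assert cell_totals(Morphology(id="empty")) == (0.0, 0.0)


class TestNaming:
    def test_printed_mappings(self):
        assert element_to_type_name("izhikevichCell") == "IzhikevichCell"
        assert attribute_to_field_name("q10Settings") == "q10_settings"

    @pytest.mark.parametrize(
        "element,expected",
        [("cell", "Cell"), ("pulseGenerator", "PulseGenerator"), ("expTwoSynapse", "ExpTwoSynapse")],
    )
    def test_element_conversion(self, element, expected):
        assert element_to_type_name(element) == expected

    @pytest.mark.parametrize(
        "attribute,expected",
        [
            ("fractionAlong", "fraction_along"),
            ("leakReversal", "leak_reversal"),
            ("tauDecay", "tau_decay"),
            ("presynapticPopulation", "presynaptic_population"),
        ],
    )
    def test_attribute_conversion(self, attribute, expected):
        assert attribute_to_field_name(attribute) == expected

    def test_idempotent_on_converted_names(self):
        for name in ["q10_settings", "fraction_along", "tau_decay"]:
            assert attribute_to_field_name(name) == name

    def test_injective_on_vocabulary(self):
        vocabulary = [
            "izhikevichCell",
            "iafCell",
            "expTwoSynapse",
            "pulseGenerator",
            "morphology",
            "segment",
            "segmentGroup",
            "network",
            "population",
            "projection",
            "connection",
            "explicitInput",
        ]
        converted = [element_to_type_name(v) for v in vocabulary]
        assert len(set(converted)) == len(vocabulary)


class TestValidateNeuroml:
    def test_fixture_documents_are_clean(self):
        assert validate_neuroml(two_segment_document()) == []
        assert validate_neuroml(example_network_document()) == []

    def test_duplicate_segment_id(self):
        doc = two_segment_document()
        doc.morphologies[0].segments[1].id = 0
        assert any("duplicate segment id" in i.message for i in validate_neuroml(doc))

    def test_unknown_population_reference(self):
        doc = example_network_document()
        doc.networks[0].projections[0].presynaptic_population = "ghostPop"
        assert any("ghostPop" in i.message for i in validate_neuroml(doc))

    def test_connection_index_out_of_range(self):
        doc = example_network_document()
        doc.networks[0].projections[0].connections[0].post_cell_id = 99
        assert any("out of range" in i.message for i in validate_neuroml(doc))

    def test_wrong_dimension_on_cell_parameter(self):
        doc = example_network_document()
        doc.iaf_cells[0].C = "1.0mV"
        assert any("capacitance" in i.message for i in validate_neuroml(doc))

    def test_spherical_segment_warns(self):
        doc = two_segment_document()
        seg = doc.morphologies[0].segments[0]
        seg.distal = Point3DWithDiam(seg.proximal.x, seg.proximal.y, seg.proximal.z, 10.0)
        issues = validate_neuroml(doc)
        assert any(i.severity == "warning" and "cylinder" in i.message for i in issues)
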