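import numpy as np
import pytest

from conftest import random_array_morphology
from neurolems.arraymorph import from_morphology, to_morphology
from neurolems.errors import ParseError, UnsupportedError, ValidationError
from neurolems.fixtures import (
    NEUROML_TWO_SEGMENT_XML,
    SWC_TOY,
    example_network_document,
    two_segment_document,
)
from neurolems.nml import NeuroMLDocument, cell_totals
from neurolems.serialization import (
    dumps_neuroml_xml,
    load_hdf5,
    load_json,
    load_neuroml_xml,
    load_swc,
    loads_neuroml_xml,
    measure,
    write_hdf5,
    write_json,
    write_neuroml_xml,
    write_swc,
)
from neurolems.synth import MorphGenSpec, _wrap, generate_morphology


def _docs():
    rng = np.random.default_rng(9)
    yield "network", example_network_document()
    yield "two_segment", two_segment_document()
    yield "generated", _wrap(generate_morphology(MorphGenSpec(n_segments=80, seed=4)))
    tree = _wrap(from_morphology(to_morphology(random_array_morphology(rng, 30))))
    tree.id = "random_tree_doc"
    yield "random_tree", tree


class TestXml:
    @pytest.mark.parametrize("name,doc", list(_docs()))
    def test_round_trip_is_semantic_identity(self, tmp_path, name, doc):
        path = tmp_path / f"{name}.nml"
        write_neuroml_xml(doc, path)
        doc2 = load_neuroml_xml(path)
        assert dumps_neuroml_xml(doc2) == dumps_neuroml_xml(doc)

    def test_invalid_document_blocks_writing(self, tmp_path):
        doc = example_network_document()
        doc.networks[0].projections[0].synapse = "ghost"
        with pytest.raises(ValidationError):
            write_neuroml_xml(doc, tmp_path / "bad.nml")

    def test_unknown_elements_collected_not_fatal(self):
        text = NEUROML_TWO_SEGMENT_XML.replace(
            "</neuroml>", "    <mysteryElement foo=\"1\"/>\n</neuroml>"
        )
        doc = loads_neuroml_xml(text)
        assert len(doc.morphologies) == 1
        assert any("mysteryElement" in i.message for i in doc.load_issues)

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(ParseError):
            loads_neuroml_xml("<neuroml id='x'><morphology></neuroml>")


class TestJson:
    @pytest.mark.parametrize("name,doc", list(_docs()))
    def test_xml_json_xml_triangle(self, tmp_path, name, doc):
        xml_path = tmp_path / "doc.nml"
        write_neuroml_xml(doc, xml_path)
        from_xml = load_neuroml_xml(xml_path)
        json_text = write_json(from_xml)
        from_json = load_json(json_text)
        assert dumps_neuroml_xml(from_json) == dumps_neuroml_xml(from_xml)

    def test_empty_document_minimal(self):
        text = write_json(NeuroMLDocument(id="empty_doc"))
        doc = load_json(text)
        assert doc.id == "empty_doc"
        assert doc.morphologies == []

    def test_truncated_vertex_row_rejected(self):
        text = (
            '{"id":"bad","morphologies":[{"id":"m",'
            '"vertices":[[0,0,0,1],[1,0,0]],"connectivity":[-1,0]}]}'
        )
        with pytest.raises(ParseError):
            load_json(text)

    def test_non_canonical_groups_survive(self, tmp_path):
        doc = two_segment_document()
        from neurolems.nml import SegmentGroup

        doc.morphologies[0].groups.append(SegmentGroup(id="custom", members=[1], includes=["all"]))
        text = write_json(doc)
        doc2 = load_json(text)
        groups = {g.id: g for g in doc2.morphologies[0].groups}
        assert groups["custom"].members == [1]
        assert groups["custom"].includes == ["all"]


class TestHdf5:
    def test_bit_exact_round_trip(self, tmp_path):
        morph = generate_morphology(MorphGenSpec(n_segments=200, seed=6))
        path = tmp_path / "m.h5"
        write_hdf5(morph, path)
        loaded = load_hdf5(path)
        assert np.array_equal(morph.vertices, loaded.vertices)
        assert np.array_equal(morph.connectivity, loaded.connectivity)
        assert loaded.id == morph.id

    def test_storage_cost_per_vertex(self, tmp_path):
        # 40 B/vertex of array data plus a size-independent header
        sizes = {}
        for n in (500, 1000):
            path = tmp_path / f"m{n}.h5"
            write_hdf5(generate_morphology(MorphGenSpec(n_segments=n, seed=1)), path)
            sizes[n] = path.stat().st_size
        assert sizes[1000] - sizes[500] == 40 * 500

    def test_full_document_unsupported(self, tmp_path):
        with pytest.raises(UnsupportedError):
            write_hdf5(example_network_document(), tmp_path / "doc.h5")

    def test_missing_datasets_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as fh:
            fh.create_group("morphology")
        with pytest.raises(ParseError):
            load_hdf5(path)


class TestSwc:
    def test_toy_file_shares_proximal_point(self):
        morph = load_swc(SWC_TOY)
        assert len(morph.segments) == 2
        prox0 = morph.resolved_proximal(morph.segments[0])
        prox1 = morph.resolved_proximal(morph.segments[1])
        assert (prox0.x, prox0.y, prox0.z) == (prox1.x, prox1.y, prox1.z) == (0.0, 0.0, 0.0)
        assert morph.segments[0].distal.diameter == 4.0  # radius column doubled

    def test_round_trip_preserves_totals(self):
        rng = np.random.default_rng(13)
        morph = to_morphology(random_array_morphology(rng, 120))
        morph2 = load_swc(write_swc(morph))
        a1, v1 = cell_totals(morph)
        a2, v2 = cell_totals(morph2)
        assert a2 == pytest.approx(a1, rel=1e-9)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_radius_convention_has_no_drift(self):
        morph = load_swc(SWC_TOY)
        twice = load_swc(write_swc(morph))
        d1 = sorted(s.distal.diameter for s in morph.segments)
        d2 = sorted(s.distal.diameter for s in twice.segments)
        assert d1 == d2

    def test_type_codes_become_groups(self):
        morph = load_swc(SWC_TOY)
        group_ids = {g.id for g in morph.groups}
        assert "dendrite_group" in group_ids and "all" in group_ids

    def test_dangling_parent_rejected(self):
        bad = "1 1 0 0 0 5 -1\n2 3 1 0 0 2 99\n"
        with pytest.raises(ParseError):
            load_swc(bad)

    def test_short_record_rejected(self):
        with pytest.raises(ParseError):
            load_swc("1 1 0 0 0 5\n")


class TestMeasure:
    def test_xml_report(self, tmp_path):
        path = tmp_path / "doc.nml"
        write_neuroml_xml(two_segment_document(), path)
        report = measure(path)
        assert report.format == "xml"
        assert report.lossless is True
        assert report.segment_count == 2
        assert report.byte_size == path.stat().st_size

    def test_hdf5_is_lossy(self, tmp_path):
        path = tmp_path / "m.h5"
        write_hdf5(generate_morphology(MorphGenSpec(n_segments=10, seed=2)), path)
        report = measure(path)
        assert report.lossless is False
        assert report.segment_count == 10

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            measure(tmp_path / "nope.nml")
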