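import pytest

from neurolems.errors import (
    StructureError,
    UnresolvedReferenceError,
    ValidationError,
)
from neurolems.fixtures import (
    LEMS_IZHIKEVICH,
    hindmarsh_rose_model,
    izhikevich_model,
    leaky_decay_model,
    synapse_model,
)
from neurolems.lems import (
    canonical_form,
    flatten_type,
    load_lems,
    resolve_component,
    validate_lems,
    write_lems,
)


class TestLoading:
    def test_izhikevich_fixture_shape(self):
        model = izhikevich_model()
        ctype = model.component_types["izhikevichCell"]
        assert [p.name for p in ctype.parameters] == ["a", "b", "c", "d", "thresh"]
        assert len(ctype.dynamics.state_variables) == 2
        assert model.target == "izhRS"

    def test_element_order_is_irrelevant(self):
        # move <Parameter> elements after <Dynamics>
        reordered = LEMS_IZHIKEVICH.replace(
            '        <Parameter name="a" dimension="none"/>\n', ""
        ).replace(
            "        </Dynamics>\n",
            '        </Dynamics>\n        <Parameter name="a" dimension="none"/>\n',
        )
        assert canonical_form(load_lems(reordered)) == canonical_form(izhikevich_model())

    def test_wrong_containment_is_structural_error(self):
        bad = """<Lems>
            <ComponentType name="broken">
                <StateVariable name="v" dimension="none"/>
            </ComponentType>
        </Lems>"""
        with pytest.raises(StructureError):
            load_lems(bad)

    def test_duplicate_component_id_rejected(self):
        bad = LEMS_IZHIKEVICH.replace(
            "<Target",
            '<izhikevichCell id="izhRS" a="1" b="1" c="0mV" d="1" thresh="0mV"/>\n    <Target',
        )
        with pytest.raises(StructureError):
            load_lems(bad)


class TestWriting:
    @pytest.mark.parametrize(
        "model_factory",
        [izhikevich_model, hindmarsh_rose_model, synapse_model, leaky_decay_model],
    )
    def test_semantic_round_trip(self, model_factory):
        model = model_factory()
        assert canonical_form(load_lems(write_lems(model))) == canonical_form(model)

    def test_empty_model_is_minimal_document(self):
        from neurolems.lems import LemsModel

        text = write_lems(LemsModel())
        assert "<Lems" in text
        assert canonical_form(load_lems(text)) == canonical_form(LemsModel())

    def test_unresolved_extends_blocks_writing(self):
        model = synapse_model()
        model.component_types["expTwoSynapse"].extends = "noSuchBase"
        with pytest.raises(ValidationError):
            write_lems(model)

    def test_written_model_revalidates_clean(self):
        for factory in (izhikevich_model, hindmarsh_rose_model, synapse_model):
            assert validate_lems(load_lems(write_lems(factory()))) == []


class TestFlattening:
    def test_extension_adds_parameters(self):
        text = """<Lems>
            <ComponentType name="A"><Parameter name="p1" dimension="none"/></ComponentType>
            <ComponentType name="B" extends="A"><Parameter name="p2" dimension="none"/></ComponentType>
        </Lems>"""
        flat = flatten_type(load_lems(text), "B")
        assert sorted(p.name for p in flat.parameters) == ["p1", "p2"]

    def test_no_extends_is_identity(self):
        model = izhikevich_model()
        assert flatten_type(model, "izhikevichCell") is model.component_types["izhikevichCell"]

    def test_synapse_inherits_base_event_port(self):
        flat = flatten_type(synapse_model(), "expTwoSynapse")
        assert [(p.name, p.direction) for p in flat.event_ports] == [("in", "in")]
        assert any(e.name == "g" for e in flat.exposures)

    def test_flatten_idempotent(self):
        model = synapse_model()
        flat = flatten_type(model, "expTwoSynapse")
        model.component_types["flat"] = flat
        again = flatten_type(model, "flat")
        assert [p.name for p in again.parameters] == [p.name for p in flat.parameters]
        assert again.dynamics.on_events == flat.dynamics.on_events

    def test_extension_cycle_detected(self):
        text = """<Lems>
            <ComponentType name="A" extends="B"/>
            <ComponentType name="B" extends="A"/>
        </Lems>"""
        with pytest.raises(StructureError):
            flatten_type(load_lems(text), "A")


class TestValidation:
    def test_valid_fixtures_produce_no_issues(self):
        for factory in (izhikevich_model, hindmarsh_rose_model, synapse_model, leaky_decay_model):
            assert validate_lems(factory()) == []

    def test_missing_parameter_value_named(self):
        model = izhikevich_model()
        del model.components["izhRS"].parameter_values["d"]
        issues = validate_lems(model)
        assert any("d" in i.message and i.severity == "error" for i in issues)

    def test_wrong_dimension_flagged(self):
        model = izhikevich_model()
        model.components["izhRS"].parameter_values["thresh"] = "30 ms"
        issues = validate_lems(model)
        assert any("thresh" in i.message or "30 ms" in i.message for i in issues if i.severity == "error")

    def test_cyclic_derived_variables_flagged(self):
        text = """<Lems>
            <ComponentType name="loop">
                <Dynamics>
                    <StateVariable name="v" dimension="none"/>
                    <DerivedVariable name="d1" value="d2 + v"/>
                    <DerivedVariable name="d2" value="d1 * 2"/>
                </Dynamics>
            </ComponentType>
        </Lems>"""
        issues = validate_lems(load_lems(text))
        assert any("cyclic" in i.message for i in issues)

    def test_unknown_target_flagged(self):
        model = leaky_decay_model()
        model.target = "ghost"
        assert any("ghost" in i.message for i in validate_lems(model))


class TestResolution:
    def test_si_conversion_of_parameters(self):
        resolved = resolve_component(izhikevich_model(), "izhRS")
        assert resolved.parameters["thresh"] == pytest.approx(0.03)
        assert resolved.parameters["c"] == pytest.approx(-0.065)
        assert resolved.parameters["a"] == 0.02

    def test_nested_components_resolve_depth_first(self):
        text = """<Lems>
            <ComponentType name="leaf"><Parameter name="p" dimension="none"/></ComponentType>
            <ComponentType name="holder">
                <Parameter name="q" dimension="time"/>
                <Children name="leaves" type="leaf"/>
            </ComponentType>
            <Component id="top" type="holder" q="2ms">
                <Component id="l1" type="leaf" p="1"/>
                <Component id="l2" type="leaf" p="3"/>
            </Component>
        </Lems>"""
        resolved = resolve_component(load_lems(text), "top")
        assert resolved.parameters["q"] == pytest.approx(0.002)
        assert [c.id for c in resolved.children] == ["l1", "l2"]
        assert resolved.children[1].parameters["p"] == 3.0

    def test_dangling_child_type_raises(self):
        text = """<Lems>
            <ComponentType name="holder"/>
            <Component id="top" type="holder">
                <Component id="child" type="ghostType" p="1"/>
            </Component>
        </Lems>"""
        with pytest.raises(UnresolvedReferenceError):
            resolve_component(load_lems(text), "top")
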