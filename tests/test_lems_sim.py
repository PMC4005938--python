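import math

import numpy as np
import pytest

from neurolems.errors import NumericError, StructureError
from neurolems.fixtures import (
    izhikevich_model,
    leaky_decay_model,
    synapse_model,
)
from neurolems.lems import load_lems
from neurolems.lems_sim import (
    SimulationSpec,
    build_runnable,
    load_trace,
    run,
    write_trace,
)


class TestBuildRunnable:
    def test_on_start_applies_si_values(self):
        inst = build_runnable(izhikevich_model(), "izhRS")
        assert inst.state["v"] == pytest.approx(-0.065)
        assert inst.state["U"] == pytest.approx(0.2 * -65.0)

    def test_state_without_on_start_defaults_to_zero(self):
        inst = build_runnable(synapse_model(), "syn")
        assert inst.state == {"A": 0.0, "B": 0.0}

    def test_derived_variable_chain_sorted_by_dependency(self):
        text = """<Lems>
            <ComponentType name="chain">
                <Dynamics>
                    <StateVariable name="v" dimension="none"/>
                    <DerivedVariable name="d2" value="d1 * 2"/>
                    <DerivedVariable name="d1" value="v + 1"/>
                    <TimeDerivative variable="v" value="0"/>
                    <OnStart><StateAssignment variable="v" value="1"/></OnStart>
                </Dynamics>
            </ComponentType>
            <chain id="c"/>
        </Lems>"""
        inst = build_runnable(load_lems(text), "c")
        assert inst.derived_order == ["d1", "d2"]
        assert inst.derived == {"d1": 2.0, "d2": 4.0}

    def test_cyclic_derived_variables_rejected(self):
        text = """<Lems>
            <ComponentType name="loop">
                <Dynamics>
                    <StateVariable name="v" dimension="none"/>
                    <DerivedVariable name="d1" value="d2"/>
                    <DerivedVariable name="d2" value="d1"/>
                </Dynamics>
            </ComponentType>
            <loop id="c"/>
        </Lems>"""
        with pytest.raises((StructureError, Exception)):
            build_runnable(load_lems(text), "c")


class TestStepping:
    def test_single_euler_step_of_leaky_decay(self):
        # dv/dt = -v/tau with tau=10ms: one 1 ms step from v=1 -> 0.9
        model = leaky_decay_model()
        model.components["decay"].parameter_values["tau"] = "10ms"
        inst = build_runnable(model, "decay")
        inst.step(0.0, 0.001)
        assert inst.state["v"] == pytest.approx(0.9)

    def test_threshold_reset_applies_both_assignments_in_one_step(self):
        inst = build_runnable(izhikevich_model(), "izhRS")
        inst.state["v"] = 0.0299  # just below thresh = 30 mV
        inst.condition_flags = [False]
        u_before = inst.state["U"]
        # step pushes v across threshold; reset must fire within the same step
        events = inst.step(0.0, 1e-5)
        assert inst.state["v"] == pytest.approx(-0.065)
        # U gains d=8 on reset (plus only the tiny drift of one Euler step)
        assert inst.state["U"] == pytest.approx(u_before + 8.0, abs=0.02)
        assert [e[1] for e in events] == ["spike"]

    def test_condition_true_at_start_is_edge_triggered(self):
        text = """<Lems>
            <ComponentType name="alwaysHigh">
                <EventPort name="out" direction="out"/>
                <Dynamics>
                    <StateVariable name="v" dimension="none"/>
                    <TimeDerivative variable="v" value="0"/>
                    <OnStart><StateAssignment variable="v" value="5"/></OnStart>
                    <OnCondition test="v .gt. 1">
                        <EventOut port="out"/>
                    </OnCondition>
                </Dynamics>
            </ComponentType>
            <alwaysHigh id="c"/>
        </Lems>"""
        inst = build_runnable(load_lems(text), "c")
        assert inst.condition_flags == [True]
        assert inst.step(0.0, 0.001) == []  # no false->true transition

    def test_non_finite_state_raises_numeric_error(self):
        text = """<Lems>
            <ComponentType name="explode">
                <Dynamics>
                    <StateVariable name="v" dimension="none"/>
                    <TimeDerivative variable="v" value="v * v"/>
                    <OnStart><StateAssignment variable="v" value="1e200"/></OnStart>
                </Dynamics>
            </ComponentType>
            <explode id="c"/>
        </Lems>"""
        inst = build_runnable(load_lems(text), "c")
        with pytest.raises(NumericError, match="v"):
            for k in range(10):
                inst.step(k * 0.1, 0.1)


class TestRun:
    def test_leaky_decay_matches_closed_form(self):
        rec = run(
            leaky_decay_model(),
            SimulationSpec("decay", dt=1e-6, duration=0.02, records=["v"]),
        )
        assert rec.series["v"][-1] == pytest.approx(math.exp(-2.0), abs=1e-4)
        assert len(rec.times) == 20001
        assert np.all(np.diff(rec.times) > 0)

    def test_constant_state_stays_flat(self):
        text = """<Lems>
            <ComponentType name="flat">
                <Dynamics>
                    <StateVariable name="x" dimension="none"/>
                    <TimeDerivative variable="x" value="0"/>
                    <OnStart><StateAssignment variable="x" value="7"/></OnStart>
                </Dynamics>
            </ComponentType>
            <flat id="c"/>
        </Lems>"""
        rec = run(load_lems(text), SimulationSpec("c", dt=0.001, duration=0.05, records=["x"]))
        assert np.all(rec.series["x"] == 7.0)

    def test_identical_specs_are_bit_identical(self):
        spec = SimulationSpec("izhRS", dt=5e-5, duration=0.05, records=["v"])
        r1 = run(izhikevich_model(), spec)
        r2 = run(izhikevich_model(), spec)
        assert np.array_equal(r1.series["v"], r2.series["v"])
        assert r1.events == r2.events

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            run(leaky_decay_model(), SimulationSpec("decay", dt=0.0, duration=1.0))


class TestEventWiring:
    def test_spike_events_drive_synapse_on_event(self):
        izh = build_runnable(izhikevich_model(), "izhRS")
        syn = build_runnable(synapse_model(), "syn")
        izh.connect("spike", syn, "in")
        dt = 5e-5
        spikes = 0
        for k in range(int(0.05 / dt)):
            events = izh.step(k * dt, dt)
            syn.step(k * dt, dt)
            spikes += len(events)
        assert spikes >= 1
        # each delivered spike increments both exponentials; decay pulls them down
        assert syn.state["B"] > syn.state["A"] > 0.0
        assert syn.derived["g"] > 0.0


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path):
        rec = run(
            leaky_decay_model(),
            SimulationSpec("decay", dt=0.001, duration=0.003, records=["v"]),
        )
        path = tmp_path / "trace.csv"
        write_trace(rec, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "time,v"
        assert len(lines) == 5  # header + 4 samples
        rec2 = load_trace(path)
        assert np.allclose(rec2.series["v"], rec.series["v"], rtol=1e-11)

    def test_empty_record_list_gives_time_only_column(self, tmp_path):
        rec = run(leaky_decay_model(), SimulationSpec("decay", dt=0.001, duration=0.002))
        path = tmp_path / "trace.csv"
        write_trace(rec, path)
        assert path.read_text().splitlines()[0] == "time"
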