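"""Forward-Euler simulation of LEMS dynamics with edge-triggered events.

A resolved component becomes a :class:`RunnableInstance`: a flattened state
machine whose parameters are SI reals, whose derived variables are sorted in
dependency order, and whose expressions are compiled once.  Stepping follows
a fixed recipe:

1. evaluate derived variables (dependency order) at the pre-step state;
2. update all states simultaneously, ``x <- x + dt * dx/dt``, with every
   derivative evaluated at the pre-step state (Jacobi-style update, so the
   result does not depend on declaration order);
3. re-evaluate derived variables at the new state;
4. for each ``OnCondition`` in document order, fire if its test is true now
   and was false at the previous check (edge-triggered, sampled at step
   boundaries -- no interpolation of the crossing time, a known O(dt) error
   source); assignments within a handler apply sequentially;
5. deliver emitted events to wired ``OnEvent`` handlers in emission order;
6. refresh the condition flags.

States without an ``OnStart`` assignment initialize to 0.  Time, ``dt`` and
durations are SI seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EvalError, NumericError, StructureError, ValidationError, has_errors
from .expressions import compile_expr, free_variables, parse_expr
from .lems import (
    LemsModel,
    ResolvedComponent,
    _derived_order,
    resolve_component,
    resolved_constants,
    validate_lems,
)

__all__ = [
    "RunnableInstance",
    "SimulationSpec",
    "Recording",
    "build_runnable",
    "run",
    "write_trace",
    "load_trace",
]


@dataclass
class SimulationSpec:
    """What to run: target component, step, duration, variables to record."""

    target: str
    dt: float  # seconds
    duration: float  # seconds
    records: list[str] = field(default_factory=list)

    def validate(self):
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")


@dataclass
class Recording:
    times: np.ndarray
    series: dict[str, np.ndarray]
    events: list[tuple[float, str, str]]  # (time, port, instance id)


class RunnableInstance:
    """A flattened, SI-converted, steppable instance of one component."""

    def __init__(self, resolved: ResolvedComponent, constants: dict[str, float]):
        self.id = resolved.id
        self.params: dict[str, float] = dict(constants)
        self.params.update(resolved.parameters)
        dyn = resolved.type.dynamics

        self.state: dict[str, float] = {sv.name: 0.0 for sv in dyn.state_variables}
        self.derived: dict[str, float] = {}
        order = _derived_order(dyn)
        self.derived_order = [dv.name for dv in order]
        self._derived_fns = [(dv.name, compile_expr(parse_expr(dv.value))) for dv in order]
        self._deriv_fns = [
            (td.variable, compile_expr(parse_expr(td.value))) for td in dyn.time_derivatives
        ]
        for variable, _ in self._deriv_fns:
            if variable not in self.state:
                raise StructureError(f"time derivative targets non-state {variable!r}")
        self._on_start = [
            [(sa.variable, compile_expr(parse_expr(sa.value))) for sa in h.assignments]
            for h in dyn.on_start
        ]
        self._conditions = [
            (
                compile_expr(parse_expr(h.test)),
                [(sa.variable, compile_expr(parse_expr(sa.value))) for sa in h.assignments],
                list(h.event_outs),
            )
            for h in dyn.on_conditions
        ]
        self._on_events: dict[str, list] = {}
        for h in dyn.on_events:
            self._on_events.setdefault(h.port, []).append(
                [(sa.variable, compile_expr(parse_expr(sa.value))) for sa in h.assignments]
            )
        self.condition_flags: list[bool] = [False] * len(self._conditions)
        #: out-port -> list of (receiver instance, receiver in-port)
        self.listeners: dict[str, list[tuple["RunnableInstance", str]]] = {}

        self._check_bindings(dyn)
        self.initialize()

    def _check_bindings(self, dyn):
        known = set(self.params) | set(self.state) | {dv.name for dv in dyn.derived_variables} | {"t"}
        texts = (
            [dv.value for dv in dyn.derived_variables]
            + [td.value for td in dyn.time_derivatives]
            + [sa.value for h in dyn.on_start for sa in h.assignments]
            + [h.test for h in dyn.on_conditions]
            + [sa.value for h in dyn.on_conditions for sa in h.assignments]
            + [sa.value for h in dyn.on_events for sa in h.assignments]
        )
        for text in texts:
            for ident in free_variables(parse_expr(text)):
                if ident not in known:
                    raise EvalError(f"unbound identifier {ident!r} in {text!r}")

    # -- wiring ------------------------------------------------------------

    def connect(self, out_port: str, receiver: "RunnableInstance", in_port: str):
        """Wire this instance's out-port to an OnEvent port of ``receiver``."""
        self.listeners.setdefault(out_port, []).append((receiver, in_port))

    def receive(self, port: str, t: float):
        env = self._env(t)
        for assignments in self._on_events.get(port, []):
            for variable, fn in assignments:
                value = fn(env)
                self.state[variable] = value
                env[variable] = value
        self._eval_derived(self._env(t))

    # -- stepping ----------------------------------------------------------

    def _env(self, t: float) -> dict:
        env = dict(self.params)
        env.update(self.state)
        env.update(self.derived)
        env["t"] = t
        return env

    def _eval_derived(self, env) -> dict:
        for name, fn in self._derived_fns:
            value = fn(env)
            env[name] = value
            self.derived[name] = value
        return env

    def initialize(self):
        """Zero states, apply OnStart, compute derived values and flags at t=0."""
        for name in self.state:
            self.state[name] = 0.0
        env = self._eval_derived(self._env(0.0))
        for assignments in self._on_start:
            for variable, fn in assignments:
                value = fn(env)
                self.state[variable] = value
                env[variable] = value
        env = self._eval_derived(self._env(0.0))
        self.condition_flags = [bool(test(env)) for test, _, _ in self._conditions]

    def step(self, t: float, dt: float) -> list[tuple[float, str, str]]:
        """Advance one step from time ``t``; returns events emitted at t+dt."""
        env = self._eval_derived(self._env(t))
        deltas = [(variable, dt * fn(env)) for variable, fn in self._deriv_fns]
        for variable, delta in deltas:
            self.state[variable] += delta
        t_new = t + dt
        env = self._eval_derived(self._env(t_new))

        events: list[tuple[float, str, str]] = []
        fired = False
        for index, (test, assignments, event_outs) in enumerate(self._conditions):
            now = bool(test(env))
            if now and not self.condition_flags[index]:
                for variable, fn in assignments:
                    value = fn(env)
                    self.state[variable] = value
                    env[variable] = value
                for port in event_outs:
                    events.append((t_new, port, self.id))
                fired = True
        if fired:
            env = self._eval_derived(self._env(t_new))
        self.condition_flags = [bool(test(env)) for test, _, _ in self._conditions]

        for time, port, _ in events:
            for receiver, in_port in self.listeners.get(port, []):
                receiver.receive(in_port, time)

        for name, value in self.state.items():
            if not math.isfinite(value):
                raise NumericError(f"state {name!r} became non-finite at t={t_new:g} s")
        return events

    def value_of(self, path: str) -> float:
        if path in self.state:
            return self.state[path]
        if path in self.derived:
            return self.derived[path]
        raise EvalError(f"no recordable variable {path!r}")


def build_runnable(model: LemsModel, component_id: str) -> RunnableInstance:
    """Resolve a component and wrap it as a steppable instance."""
    issues = [i for i in validate_lems(model) if i.severity == "error"]
    if issues:
        raise ValidationError(f"model does not validate for {component_id!r}", issues)
    resolved = resolve_component(model, component_id)
    return RunnableInstance(resolved, resolved_constants(model))


def run(model: LemsModel, sim: SimulationSpec) -> Recording:
    """Integrate with forward Euler and return the sampled recording.

    ``floor(duration/dt)`` steps; every variable in ``sim.records`` is
    sampled at t=0 and after each step, so series have ``n+1`` samples.
    Two runs with identical specs produce bit-identical recordings.
    """
    sim.validate()
    inst = build_runnable(model, sim.target)
    n_steps = int(math.floor(sim.duration / sim.dt + 1e-9))
    times = np.arange(n_steps + 1, dtype=float) * sim.dt
    series = {path: np.empty(n_steps + 1) for path in sim.records}
    events: list[tuple[float, str, str]] = []

    for path in sim.records:
        series[path][0] = inst.value_of(path)
    for k in range(n_steps):
        try:
            events.extend(inst.step(k * sim.dt, sim.dt))
        except NumericError as exc:
            raise NumericError(f"{exc} (step {k + 1})") from None
        for path in sim.records:
            series[path][k + 1] = inst.value_of(path)
    return Recording(times=times, series=series, events=events)


def write_trace(rec: Recording, path) -> None:
    """Write a recording as CSV: header ``time,<path>...``, one row per sample."""
    names = list(rec.series)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(["time"] + names) + "\n")
        for k in range(len(rec.times)):
            row = [f"{rec.times[k]:.12g}"] + [f"{rec.series[n][k]:.12g}" for n in names]
            fh.write(",".join(row) + "\n")


def load_trace(path) -> Recording:
    """Reload a CSV trace written by :func:`write_trace`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    times = data[:, 0]
    series = {name: data[:, k + 1] for k, name in enumerate(header[1:])}
    return Recording(times=times, series=series, events=[])
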