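# neurolems

A Python toolkit for **declarative neuronal modeling**: an object model and
serializers for a NeuroML v2 subset (morphologies, point-neuron cells,
synapses, networks), an array-backed morphology representation, and a LEMS
language core — dimensional quantities, the expression language,
ComponentType/Component prototypes with validation — plus a forward-Euler
simulator for the dynamical models it parses.

It is written for computational neuroscientists who want to build, check,
convert and run standards-based model descriptions from Python instead of
editing XML by hand: network structure generated procedurally with a seeded
script, morphologies moved between XML/JSON/HDF5/SWC, and new cell models
defined in LEMS and executed immediately.

## The core ideas

**Dimensional quantities.** Every LEMS/NeuroML parameter is a magnitude plus
a unit whose dimension is declared over the seven SI base dimensions
(`-65mV`, `0.05uS`). The toolkit checks units against the declared dimension
and converts everything to one consistent SI system before any arithmetic;
unknown units are hard errors, never silently dimensionless.

**Prototype + instance.** A LEMS `ComponentType` declares parameters,
exposures, event ports and a `Dynamics` state machine

- state variables *s* with time derivatives *ds/dt = f(s, p, t)*,
- derived variables evaluated in dependency order,
- `OnCondition` handlers that fire on a **false→true edge** of a boolean
  test (written with Fortran-style operators, e.g. `v .gt. thresh`) and
  apply state assignments / emit events,

and a `Component` instantiates it with concrete quantities. Types compose
by prototype extension (`extends`) and containment.

**Forward-Euler simulation.** A resolved component becomes a runnable
instance stepped as *s ← s + dt·f(s)* with all derivatives evaluated at the
pre-step state, condition events detected at step boundaries and delivered
to wired `OnEvent` handlers. First-order accuracy and the O(dt) event-time
bias are verified against closed forms and an adaptive-step reference
integrator in the test suite.

**Conical-frustum morphologies.** A neuronal morphology is a tree of
segments between 3D points with diameters. Lateral area and volume of a
segment are `π(r₁+r₂)·√((r₁−r₂)²+h²)` and `(πh/3)(r₁²+r₁r₂+r₂²)`. The
`arraymorph` module stores the same tree as an N×4 vertex array plus an
integer parent array (SWC-style, exactly 4 floats + 1 int per vertex) with
write-through segment views, which is what makes 10⁵-segment reconstructions
cheap to hold and fast to serialize.

## Worked example

```python
from neurolems.fixtures import izhikevich_model, two_segment_document
from neurolems.lems_sim import SimulationSpec, run
from neurolems.nml import cell_totals

# Regular-spiking Izhikevich cell, defined entirely in LEMS, 200 ms at dt = 10 µs
rec = run(izhikevich_model(), SimulationSpec(target="izhRS", dt=1e-5,
                                             duration=0.2, records=["v"]))
print(f"{len(rec.events)} spikes at "
      + ", ".join(f"{t*1000:.2f} ms" for t, _, _ in rec.events))

# Geometry helpers on a two-segment cell (cylindrical soma + tapering dendrite)
area, volume = cell_totals(two_segment_document().morphologies[0])
print(f"area = {area:.1f} um^2, volume = {volume:.1f} um^3")
```

prints

```
5 spikes at 3.15 ms, 26.30 ms, 71.16 ms, 116.00 ms, 160.84 ms
area = 758.9 um^2, volume = 1602.2 um^3
```

The five spike times agree with an adaptive-step reference integration of
the same equations (3.13, 26.23, 71.06, 115.87, 160.68 ms) to within the
expected O(dt) threshold-detection bias.

The same machinery is scriptable from the shell:

```bash
neurolems validate model.nml
neurolems convert reconstruction.swc reconstruction.nml
neurolems simulate izhikevich.xml --dt 0.01ms --duration 200ms --record v --out trace.csv
neurolems bench --formats xml,json,hdf5 --sizes 1000,2000 --out bench.csv
```

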