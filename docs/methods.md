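# Methods

This note documents the models, conventions and numerical choices behind
neurolems: what is computed, under which assumptions, and where design
freedom existed and how it was resolved. File-format byte layouts are in
`formats.md`.

## Units and dimensions

All quantities are dimensional: a magnitude plus a unit symbol whose
dimension is declared over the seven SI base dimensions (mass, length,
time, current, temperature, amount, luminosity). The built-in registry
covers the dimensions and units the NeuroML core types assume (voltage,
time, capacitance, conductance, conductance density, current, length, area,
volume, rates; symbols from `pV`-scale through SI base units — the full
table is in `formats.md`). Documents may declare additional dimensions and
units, which overlay the built-ins.

Assumptions and consequences:

* Every unit is a pure power of ten relative to the SI unit of its
  dimension. Offset units (degrees Celsius) are out of scope; nothing in
  the supported NeuroML subset needs them.
* Unknown unit symbols raise immediately. Treating an unrecognized unit as
  dimensionless is the failure mode a unit system exists to prevent, so
  there is deliberately no lenient mode.
* Dimension equality is by exponent vector, so user-defined aliases of a
  built-in dimension interoperate.
* The canonical text form has no space between number and symbol
  (`-65mV`); whitespace is accepted on input.

## The expression language

Expressions in time derivatives, derived variables, assignments and
condition tests use arithmetic (`+ - * / ^`), the functions `exp`, `ln`,
`log` (natural log, alias of `ln`), `sqrt`, `abs`, `sin`, `cos`, `tan`,
Fortran-style comparisons (`.gt.`, `.lt.`, `.geq.`, `.leq.`, `.eq.`,
`.neq.` — XML cannot contain a bare `<`), and boolean connectives
(`.and.`, `.or.`, `.not.`). Bare keyword spellings (`v gt thresh`) are
accepted on input; the dotted form is canonical output.

Choices the language definition leaves open, fixed here:

* Precedence, loosest→tightest: `or` < `and` < `not` < comparisons <
  `+ -` < `* /` < unary minus < `^`.
* `^` is right-associative (`2^3^2 = 512`) and binds tighter than unary
  minus (`-2^2 = -4`), matching mathematical convention.
* There is no `random()` in expressions; stochasticity lives only in the
  generators, so simulations are reproducible by construction.

The AST-walking evaluator is the semantic reference. The simulator uses
expressions compiled to Python code objects for speed; the compiled path is
property-tested against the walker on random trees, and the walker against
direct host-language evaluation with substituted values.

## LEMS documents, extension and validation

The document model holds dimensions, units, constants, component types,
components and an optional simulation target. The XML reader is
order-tolerant (elements may appear in any order within their parent) but
enforces containment through an internal table — a `<StateVariable>`
outside `<Dynamics>` is a structural error. The containment table replaces
an external XSD so the rules are self-contained and testable.

Type extension flattens a chain of prototypes into one type: the derived
type overrides its base on name collision for keyed items (parameters,
exposures, requirements, ports, state/derived variables, time derivatives
by target); handler lists concatenate base-first. Overriding is legal and
recorded as an `info` issue. Flattening is idempotent and cycle-checked.

Validation returns issues as data rather than raising: unique ids, resolvable
references, every parameter valued with a dimension-compatible quantity,
expressions parseable with all identifiers bound, derivatives targeting
declared states, and an acyclic derived-variable graph. Component parameter
values stay as the author's original text until resolve time so unit errors
can quote the original spelling; resolution converts everything to SI reals
and recurses depth-first through children. Components are tree-shaped;
cross-references between component subtrees are flagged rather than
followed.

## Forward-Euler simulation

A resolved component becomes a runnable instance: parameters and constants
as SI reals, derived variables topologically sorted, expressions compiled,
states initialized. One step from *t* to *t+dt*:

1. evaluate derived variables at the pre-step state;
2. evaluate **all** time derivatives at the pre-step state, then update all
   states simultaneously (*x ← x + dt·dx/dt*). This Jacobi-style update
   makes the result independent of declaration order;
3. re-evaluate derived variables;
4. scan `OnCondition` handlers in document order: one fires iff its test is
   true now and was false at the previous check (edge-triggered). Its
   assignments apply sequentially (later assignments see earlier ones);
   its events are emitted in order;
5. deliver events to wired `OnEvent` handlers in emission order;
6. re-evaluate the condition flags from the post-assignment state.

Numerical and semantic choices:

* `dt` and durations are SI seconds everywhere in the API; the CLI accepts
  quantity strings (`--dt 0.01ms`).
* A run of duration *T* takes `floor(T/dt)` steps and records `n+1`
  samples including *t = 0*.
* Events are detected at step boundaries with no interpolation of the
  crossing time; event times therefore carry an O(dt) bias. This is the
  simplest semantics consistent with a fixed-step explicit method and is
  the documented trade-off of choosing forward Euler.
* Condition flags are initialized at *t = 0* after `OnStart`, so a
  condition already true at start never fires spuriously (edge rule).
* States without an `OnStart` assignment initialize to 0. This is loud in
  the documentation because it is a common source of surprise.
* Any non-finite state aborts the run with the state name and time.

Verified properties (test suite): the leaky-decay fixture matches
*v(t) = e^(−t/τ)* to 1e−4 at dt = 1 µs; the empirical convergence order
over dt ∈ {1e−3…1e−6} s is 1.0 ± 0.1; the Izhikevich fixture's spike count
over 200 ms equals that of an adaptive-step reference integration with the
identical reset rule; trajectories agree with the reference integrator to
1e−3 relative before the first event; runs are bit-for-bit reproducible.

Fixture conventions: the classic Izhikevich and Hindmarsh–Rose equations
are written in their dimensionless textbook form and made dimensionally
honest through document constants `MVOLT` (1 mV) and `MSEC` (1 ms), so "one
unit of model time" is one millisecond of SI time. The Hindmarsh–Rose
fixture uses the square-wave bursting regime (a=1, b=3, c=1, d=5, s=4,
x₁=−1.6, r=0.003, I=2.7).

## Morphology geometry

A segment is the conical frustum between its proximal and distal
`(x, y, z, diameter)` points: lateral area `π(r₁+r₂)·√((r₁−r₂)² + h²)`,
volume `(πh/3)(r₁² + r₁r₂ + r₂²)`; totals are sums over segments. Both are
cross-checked against numeric surface-/solid-of-revolution integration.

* A segment without an explicit proximal inherits its attachment point on
  the parent: `fraction_along = 1` (default) is the parent's distal point,
  `0` its proximal point, intermediate values interpolate position **and
  diameter** linearly along the parent's axis — the only continuous rule
  for frusta.
* Zero-length segments (proximal = distal, a "spherical soma") contribute
  zero area and volume and draw a validator warning suggesting a
  cylindrical soma; a true sphere-surface convention is deliberately not
  invented.
* Coordinates are micrometres throughout.

## Array-backed morphologies

`ArrayMorphology` stores one N×4 float64 row per 3D point and a length-N
int64 parent-index array with −1 at the single root: exactly 4 reals + 1
integer per vertex regardless of tree size. Segments are edges to the
parent vertex; geometry totals are vectorized over the arrays and agree
with the object-model sums to 1e−9 relative on random trees.

Representable subset (checked, with clear errors): branch points share one
parent vertex, so per-child proximal overrides and intermediate
`fraction_along` attachments cannot be expressed. Extra children of the
root vertex convert to segments attached to the first root segment at
`fraction_along = 0`, which keeps the object-model invariant of exactly one
root segment while preserving geometry exactly. Diameters (not radii) are
stored, matching NeuroML; the factor of two lives in the SWC reader/writer
only.

## Synthetic data: what it emulates, what it does not

**Morphologies.** The generator grows a seeded random walk of
conical-frustum segments: steps of 5–15 µm in uniformly random directions,
branching with probability 0.1 per segment from a uniformly chosen earlier
point, diameters tapering by 0.998 per segment under ±3% jitter, all
confined to a 1 mm cube by mirror reflection. This emulates what matters
for serialization and geometry work — realistic segment counts, branch
structure, coordinate/diameter magnitudes — and does **not** emulate
biological branch statistics (no Rall ratios, no tortuosity model, no
soma/neurite typing). Passing tests therefore demonstrate correctness of
storage, conversion and measurement on reconstruction-shaped trees, not
fidelity to any species' anatomy.

Two deliberate dialect couplings: coordinates stay in [1, 999] µm and
diameters in [1, 10] µm, and every emitted value is snapped to 6
significant digits with a non-zero final digit (a < 4e−6 relative nudge).
Every real then renders at exactly 7 characters under `%.6g`, so file sizes
are functions of the segment count alone, up to the 1–2 bytes contributed
by variable-width integer ids (HDF5 sizes are exactly seed-invariant; text
formats vary by a few bytes in ~100 kB).

**Networks.** Two populations of five integrate-and-fire cells; one shared
cell and synapse prototype; a square current pulse per presynaptic cell
with amplitude uniform in 0.15–0.35 nA; connections are independent
Bernoulli(0.3) draws per (pre, post) pair in pre-major order. Over many
seeds the connection count has mean 25·p = 7.5 and variance 25·p(1−p),
which the tests check at the 3σ level over 10 000 seeds.

Randomness is split into named substreams (coordinates, branching,
amplitudes, connectivity) derived from one integer seed, so adding a draw
to one concern never shifts another and a published seed reproduces the
artifact bit-for-bit.

## Serialization footprints

With the dialect fixed (`formats.md`), per-segment costs are arithmetic:
an XML segment costs ~301 bytes plus 4 integer-id renderings (≈316 B/segment
across 1k–50k segments); a JSON segment costs ~49 bytes plus 3 id renderings
(≈60 B/segment); HDF5 costs exactly 40 bytes per vertex plus a 5 632-byte
fixed header (≈42 B/segment amortized). Sizes are measured, not asserted,
by `scripts/acceptance.py` at n = 1 000, 2 000, 5 000, 10 000 and 50 000
segments (chosen to span the regime where fixed overheads stop mattering
while keeping the whole measurement under a few seconds); linear regression
of size on segment count gives R² > 0.999 for every format. Wall-clock
write times are reported by the benchmark harness but never asserted —
they are hardware facts, not properties of this code.

## Known limitations

* Single-compartment dynamics only: the LEMS subset does not describe
  cable-equation compartmental models, and the simulator makes no attempt
  to couple segments electrically.
* Kinetic-scheme ion channels and HH gate types are not modeled; cells
  reference channel mechanisms opaquely.
* Forward Euler only; stiff models need small steps, and event times carry
  O(dt) bias. The reference-integrator comparisons in the tests are the
  guard rail.
* Networks of runnable instances are wired explicitly via
  `RunnableInstance.connect`; the document-level `Simulation`/`Display`
  vocabulary is out of scope beyond a minimal target.
* HDF5 and SWC serialize morphology structure only, by design.
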