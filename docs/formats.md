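# On-disk formats and the unit registry

## NeuroML XML dialect

UTF-8, 4-space indentation, attributes in schema order, reals formatted
with `%.6g`. Document structure (elements in this order):

```xml
<?xml version="1.0" encoding="UTF-8"?>
<neuroml id="...">
    <izhikevichCell id="..." a="..." b="..." c="..." d="..." thresh="..."/>
    <iafCell id="..." leakReversal="..." thresh="..." reset="..." C="..." leakConductance="..."/>
    <expTwoSynapse id="..." gbase="..." erev="..." tauRise="..." tauDecay="..."/>
    <pulseGenerator id="..." delay="..." duration="..." amplitude="..."/>
    <morphology id="...">
        <segment id="0" name="segment_0">
            <parent segment="..." fractionAlong="1.0"/>   <!-- absent on the root -->
            <proximal x="..." y="..." z="..." diameter="..."/>
            <distal   x="..." y="..." z="..." diameter="..."/>
        </segment>
        <segmentGroup id="all">
            <member segment="0"/>
            <include segmentGroup="..."/>
        </segmentGroup>
    </morphology>
    <network id="...">
        <population id="..." component="..." size="..."/>
        <projection id="..." presynapticPopulation="..." postsynapticPopulation="..." synapse="...">
            <connection id="0" preCellId="0" postCellId="1"/>
        </projection>
        <explicitInput target="prePop[0]" input="pulse_0"/>
    </network>
</neuroml>
```

The writer always emits an explicit `proximal` (resolved from the parent
when the author omitted it) and an explicit `fractionAlong`; the reader
accepts both omitted. Unknown elements and attributes are collected as
issues and skipped (tolerant reader); schema validation is a separate,
explicit step.

Cell/synapse/input attribute values are quantity strings (`-65mV`) and are
preserved verbatim, so documents round-trip with the author's spelling.

## JSON schema (lossless)

One object, compact separators, quantity strings preserved verbatim.
Collections are present only when non-empty.

```json
{
  "id": "doc-id",
  "izhikevich_cells":  [{"id": "...", "a": "...", "b": "...", "c": "...", "d": "...", "thresh": "..."}],
  "iaf_cells":         [{"id": "...", "leak_reversal": "...", "thresh": "...", "reset": "...",
                         "C": "...", "leak_conductance": "..."}],
  "synapses":          [{"id": "...", "gbase": "...", "erev": "...", "tau_rise": "...", "tau_decay": "..."}],
  "pulse_generators":  [{"id": "...", "delay": "...", "duration": "...", "amplitude": "..."}],
  "morphologies": [{
      "id": "...",
      "vertices":      [[x, y, z, diameter], ...],
      "connectivity":  [-1, 0, ...],
      "segment_ids":   [0, 1, ...],
      "segment_names": ["segment_0", ...],
      "segment_types": [0, 0, ...],
      "groups":        [{"id": "...", "spans": [[first, last], ...], "includes": ["..."]}]
  }],
  "networks": [{
      "id": "...",
      "populations":     [["pop-id", "component-id", size], ...],
      "projections":     [{"id": "...", "pre": "...", "post": "...", "synapse": "...",
                           "connections": [[id, pre, post], ...]}],
      "explicit_inputs": [["prePop[0]", "pulse_0"], ...]
  }]
}
```

Morphologies are stored array-backed — numeric rows, reals at 6 significant
digits — which is what gives JSON its compact footprint. The canonical
groups (`all` plus the SWC-type groups below) are regenerated from
`segment_ids`/`segment_types` on load and never stored; only other groups
are stored, with members run-length-encoded as `[first, last]` spans.
`groups` is omitted when empty.

## HDF5 layout (morphology only, lossy)

```
/morphology            group, attribute "id" (string)
/morphology/vertices   dataset, N x 4 float64  (x, y, z, diameter; µm)
/morphology/connectivity  dataset, N int64     (parent vertex index, root = -1)
```

Files are written with `libver="latest"`, `meta_block_size=512` and
`track_times=False`: array payload is exactly 40 bytes per vertex and the
header is a fixed 5 632 bytes, so sizes are bit-deterministic. Arrays
round-trip bit-exactly. Anything that is not a morphology is refused.

## SWC (morphology only, lossy)

Seven whitespace-separated columns per record, `#` comments ignored:

```
id  type  x  y  z  radius  parent
```

* `radius` is **half** the stored diameter (doubled on load, halved on
  write; exact in binary, so repeated round trips cannot drift).
* Type codes map to canonical segment groups on load and are regenerated
  from them on write: 1 → `soma_group`, 2 → `axon_group`,
  3 → `dendrite_group`, 4 → `apical_dendrite_group`; unknown codes → 0.
* The writer emits 1-based contiguous ids with every parent before its
  children; the root record is tagged soma and carries parent −1.
* Coordinates are written at full float precision (SWC is not part of the
  fixed-size dialect).

## LEMS XML elements

Root `Lems`; children `Dimension`, `Unit`, `Constant`, `ComponentType`,
`Component` (or typed shorthand named after the type), `Target`.
`ComponentType` contains `Parameter`, `Exposure`, `Requirement`, `Child`,
`Children`, `EventPort`, `Dynamics`; `Dynamics` contains `StateVariable`,
`DerivedVariable`, `TimeDerivative`, `OnStart`, `OnCondition`, `OnEvent`;
handlers contain `StateAssignment` and `EventOut`. Element order within a
parent is irrelevant on input; the writer uses the order above.

## Built-in unit registry

| Dimension (exponents m,l,t,i) | Units (symbol → power of ten vs SI) |
|---|---|
| voltage (1,2,−3,−1) | V→0, mV→−3 |
| time (0,0,1,0) | s→0, ms→−3, us→−6 |
| per_time (0,0,−1,0) | per_s→0, Hz→0, per_ms→3 |
| capacitance (−1,−2,4,2) | F→0, uF→−6, nF→−9, pF→−12 |
| conductance (−1,−2,3,2) | S→0, mS→−3, uS→−6, nS→−9, pS→−12 |
| conductanceDensity (−1,−4,3,2) | S_per_m2→0, mS_per_cm2→1 |
| resistance (1,2,−3,−2) | ohm→0, kohm→3, Mohm→6 |
| current (0,0,0,1) | A→0, mA→−3, uA→−6, nA→−9, pA→−12 |
| length (0,1,0,0) | m→0, cm→−2, um→−6 |
| area (0,2,0,0) | m2→0, cm2→−4, um2→−12 |
| volume (0,3,0,0) | m3→0, cm3→−6, um3→−18 |
| none | (bare numbers) |

Temperature, amount and luminosity carry no curated units (no supported
quantity uses them) but are available to document-defined dimensions.
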