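"""Synthetic morphologies, random spiking networks, and the write benchmark.

The morphology generator emulates a reconstructed neuron for serialization
work: a seeded 3D random walk of conical-frustum segments inside a 1 mm
cube, branching from a random earlier point with fixed probability, with
diameters tapering multiplicatively under jitter.  Coordinates stay in
[1, 999] µm and diameters in [1, 10] µm (enforced by reflection at the
bounds), so every real renders as exactly 6 significant digits in the
``%.6g`` serialization dialect and file sizes depend only on the segment
count -- a property the byte-footprint measurements rely on.

Randomness is split into named substreams (coordinates, branching,
amplitudes, connectivity) so adding a draw to one concern never shifts
another; everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .arraymorph import ArrayMorphology
from .nml import (
    Connection,
    ExplicitInput,
    ExpTwoSynapse,
    IafCell,
    Network,
    NeuroMLDocument,
    Population,
    Projection,
    PulseGenerator,
)
from .serialization import write_hdf5, write_json, write_neuroml_xml

__all__ = [
    "MorphGenSpec",
    "NetGenSpec",
    "BenchmarkRow",
    "generate_morphology",
    "build_random_network",
    "benchmark",
    "write_benchmark_csv",
]

# substream tags for the seeded generators
_COORDS, _BRANCHING, _AMPLITUDES, _CONNECTIVITY = 101, 102, 103, 104


@dataclass
class MorphGenSpec:
    """Parameters of the synthetic-morphology random walk."""

    n_segments: int = 1000
    seed: int = 0
    branch_probability: float = 0.1
    step_min: float = 5.0  # µm
    step_max: float = 15.0  # µm
    taper: float = 0.998  # diameter decay per segment
    root_diameter: float = 8.0  # µm

    def validate(self):
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")


@dataclass
class NetGenSpec:
    """Parameters of the random two-population integrate-and-fire network."""

    n_pre: int = 5
    n_post: int = 5
    connection_probability: float = 0.3
    amplitude_min: float = 0.15  # nA
    amplitude_max: float = 0.35  # nA
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.connection_probability <= 1.0:
            raise ValueError("connection_probability must be in [0, 1]")
        if self.n_pre < 1 or self.n_post < 1:
            raise ValueError("population sizes must be >= 1")


_LOW, _HIGH = 1.0, 999.0  # µm, keeps %.6g rendering at fixed width
_DIAM_LOW, _DIAM_HIGH = 1.0, 10.0


def _reflect(value: float, low: float, high: float) -> float:
    """Fold a value back into [low, high] by mirror reflection."""
    span = high - low
    value = (value - low) % (2.0 * span)
    if value > span:
        value = 2.0 * span - value
    return low + value


def _quantize6(value: float) -> float:
    """Snap to 6 significant digits with a non-zero final digit.

    ``%.6g`` strips trailing zeros, so a raw draw renders at a variable
    width about 10% of the time.  Emitting values whose sixth significant
    digit is never zero makes every coordinate exactly 7 characters wide in
    the serialization dialect, which in turn makes file sizes functions of
    the segment count alone.  The nudge is < 4e-6 relative -- irrelevant
    for synthetic geometry.
    """
    exponent = math.floor(math.log10(abs(value)))
    scale = 10.0 ** (exponent - 5)
    digits = int(value / scale)  # first 6 significant digits
    if digits % 10 == 0:
        digits += 3
    return digits * scale


def generate_morphology(spec: MorphGenSpec) -> ArrayMorphology:
    """Grow a seeded branching tree with exactly ``spec.n_segments`` segments."""
    spec.validate()
    rng_coords = np.random.default_rng([spec.seed, _COORDS])
    rng_branch = np.random.default_rng([spec.seed, _BRANCHING])
    n = spec.n_segments

    vertices = np.empty((n + 1, 4))
    connectivity = np.empty(n + 1, dtype=np.int64)
    vertices[0] = (500.0, 500.0, 500.0, spec.root_diameter)
    connectivity[0] = -1

    # draw everything up front so the stream layout is stable
    directions = rng_coords.normal(size=(n, 3))
    lengths = rng_coords.uniform(spec.step_min, spec.step_max, size=n)
    jitters = rng_coords.uniform(0.97, 1.03, size=n)
    branch_draws = rng_branch.random(size=n)
    branch_targets = rng_branch.random(size=n)

    for k in range(1, n + 1):
        j = k - 1
        if k == 1:
            parent = 0
        elif branch_draws[j] < spec.branch_probability and k > 2:
            # branch from a uniformly chosen earlier non-root vertex
            parent = 1 + int(branch_targets[j] * (k - 1))
        else:
            parent = k - 1
        direction = directions[j]
        norm = float(np.sqrt(direction @ direction))
        if norm == 0.0:  # pragma: no cover - probability zero
            direction, norm = np.array([1.0, 0.0, 0.0]), 1.0
        step = direction / norm * lengths[j]
        x = _quantize6(_reflect(vertices[parent, 0] + step[0], _LOW, _HIGH))
        y = _quantize6(_reflect(vertices[parent, 1] + step[1], _LOW, _HIGH))
        z = _quantize6(_reflect(vertices[parent, 2] + step[2], _LOW, _HIGH))
        diameter = _quantize6(
            _reflect(vertices[parent, 3] * spec.taper * jitters[j], _DIAM_LOW, _DIAM_HIGH)
        )
        vertices[k] = (x, y, z, diameter)
        connectivity[k] = parent

    return ArrayMorphology(
        vertices=vertices,
        connectivity=connectivity,
        segment_ids=np.arange(n, dtype=np.int64),
        segment_names=[f"segment_{k}" for k in range(n)],
        segment_types=np.zeros(n, dtype=np.int64),
        id="synthetic_morphology",
    )


def build_random_network(spec: NetGenSpec) -> NeuroMLDocument:
    """Two populations of integrate-and-fire cells, Bernoulli(p) connectivity.

    One iafCell prototype and one expTwoSynapse prototype are shared; every
    presynaptic cell receives a square current pulse whose amplitude is
    drawn uniformly from the configured range.  Connections are independent
    Bernoulli(p) draws per (pre, post) pair in pre-major order, so a fixed
    seed reproduces the network exactly.
    """
    spec.validate()
    rng_amp = np.random.default_rng([spec.seed, _AMPLITUDES])
    rng_conn = np.random.default_rng([spec.seed, _CONNECTIVITY])

    doc = NeuroMLDocument(id="random_iaf_network")
    doc.iaf_cells.append(
        IafCell(
            id="iaf0",
            leak_reversal="-65mV",
            thresh="-50mV",
            reset="-65mV",
            C="1.0nF",
            leak_conductance="0.05uS",
        )
    )
    doc.synapses.append(
        ExpTwoSynapse(id="syn0", gbase="1nS", erev="0mV", tau_rise="0.5ms", tau_decay="2ms")
    )
    net = Network(id="net0")
    net.populations.append(Population(id="prePop", component="iaf0", size=spec.n_pre))
    net.populations.append(Population(id="postPop", component="iaf0", size=spec.n_post))

    amplitudes = rng_amp.uniform(spec.amplitude_min, spec.amplitude_max, size=spec.n_pre)
    for k in range(spec.n_pre):
        doc.pulse_generators.append(
            PulseGenerator(
                id=f"pulse_{k}",
                delay="0ms",
                duration="100ms",
                amplitude=f"{amplitudes[k]:.4g}nA",
            )
        )
        net.explicit_inputs.append(ExplicitInput(target=f"prePop[{k}]", input=f"pulse_{k}"))

    proj = Projection(
        id="proj0",
        presynaptic_population="prePop",
        postsynaptic_population="postPop",
        synapse="syn0",
    )
    draws = rng_conn.random(size=(spec.n_pre, spec.n_post))
    conn_id = 0
    for pre in range(spec.n_pre):
        for post in range(spec.n_post):
            if draws[pre, post] < spec.connection_probability:
                proj.connections.append(
                    Connection(id=conn_id, pre_cell_id=pre, post_cell_id=post)
                )
                conn_id += 1
    net.projections.append(proj)
    doc.networks.append(net)
    return doc


# --------------------------------------------------------------------------
# Benchmark harness


@dataclass
class BenchmarkRow:
    format: str
    n_segments: int
    mean_s: float
    sd_s: float
    file_size: int  # bytes
    repeats: int


_WRITERS = {
    "xml": lambda morph, path: write_neuroml_xml(_wrap(morph), path),
    "json": lambda morph, path: write_json(_wrap(morph), path),
    "hdf5": write_hdf5,
}

_EXT = {"xml": ".nml", "json": ".json", "hdf5": ".h5"}


def _wrap(morph: ArrayMorphology) -> NeuroMLDocument:
    doc = NeuroMLDocument(id="synthetic_morphology_doc")
    doc.morphologies.append(morph)
    return doc


def benchmark(formats, sizes, repeats: int = 10, seed: int = 0, outdir=None) -> list[BenchmarkRow]:
    """Time serialization writes for each (format, size) pair.

    For every pair, ``repeats`` morphologies are generated with seeds
    ``seed .. seed+repeats-1`` and written to disk; the row reports the mean
    and standard deviation of the per-write wall time and the final file
    size.  Sizes are seed-invariant by construction of the generator's
    fixed-width dialect; times are hardware-dependent and reported only.
    """
    unknown = set(formats) - set(_WRITERS)
    if unknown:
        raise ValueError(f"unknown formats: {sorted(unknown)}")
    import tempfile

    own_tmp = None
    if outdir is None:
        own_tmp = tempfile.TemporaryDirectory(prefix="neurolems_bench_")
        outdir = own_tmp.name
    rows = []
    try:
        for fmt in formats:
            for size in sizes:
                times = []
                file_size = 0
                for r in range(repeats):
                    morph = generate_morphology(MorphGenSpec(n_segments=size, seed=seed + r))
                    path = Path(outdir) / f"bench_{fmt}_{size}_{r}{_EXT[fmt]}"
                    start = time.perf_counter()
                    _WRITERS[fmt](morph, path)
                    times.append(time.perf_counter() - start)
                    file_size = path.stat().st_size
                arr = np.asarray(times)
                rows.append(
                    BenchmarkRow(
                        format=fmt,
                        n_segments=size,
                        mean_s=float(arr.mean()),
                        sd_s=float(arr.std(ddof=1)) if repeats > 1 else 0.0,
                        file_size=file_size,
                        repeats=repeats,
                    )
                )
    finally:
        if own_tmp is not None:
            own_tmp.cleanup()
    return rows


def write_benchmark_csv(rows, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format,n_segments,mean_s,sd_s,bytes,repeats\n")
        for row in rows:
            fh.write(
                f"{row.format},{row.n_segments},{row.mean_s:.6g},{row.sd_s:.6g},"
                f"{row.file_size},{row.repeats}\n"
            )
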