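"""Deterministic, seeded generation of cortical-circuit structure and activity.

The generator emulates the organization of a cortical-column microcircuit:
columns arranged on hexagonal rings, each column holding a grid of
minicolumns, each minicolumn a vertical stack of neurons spanning six
depth-ordered layers (I outermost / largest y ... VI innermost). Stimulus
responses start in layer VI and propagate outward across layers with a fixed
per-layer latency, on top of homogeneous Poisson background firing.

Everything is driven by named RNG streams derived from a master seed — one
stream per concern (placement, types, morphometrics, spikes) — so changing
e.g. the activity parameters never perturbs the circuit layout, and equal
seeds yield byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simdata import (
    MORPHOMETRIC_KEYS,
    N_LAYERS,
    NeuronRecord,
    SpikeReport,
    ValidationError,
    VoltageReport,
)

__all__ = [
    "CircuitSpec",
    "ActivitySpec",
    "PRESETS",
    "generate_circuit",
    "generate_spikes",
    "generate_voltage",
    "voltage_from_spikes",
]

# Stable stream ids: one independent RNG per concern.
_STREAMS = {"placement": 0, "types": 1, "morphometrics": 2, "spikes": 3}


def _rng(seed: int, concern: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[concern]]))


# Log-normal (mu of ln, sigma of ln) per morphometric attribute. Medians are
# plausible orders of magnitude for cortical neurons (µm³ / µm² / counts).
_DEFAULT_MORPHO = {
    "soma_volume": (7.6, 0.4),
    "soma_surface": (6.7, 0.3),
    "dendritic_volume": (8.5, 0.5),
    "dendritic_surface": (9.1, 0.5),
    "axon_volume": (8.0, 0.5),
    "neuritic_surface": (9.4, 0.4),
    "dendritic_bifurcations": (3.4, 0.4),
}


@dataclass
class CircuitSpec:
    """Parameters of a synthetic circuit.

    The defaults reproduce the organization of a 7-column cortical circuit
    with 310 minicolumns per column and 100 neurons per minicolumn
    (7 * 310 * 100 = 217,000 neurons across six layers).
    """

    n_columns: int = 7
    n_minicolumns_per_column: int = 310
    n_neurons_per_minicolumn: int = 100
    inhibitory_fraction: float = 0.10
    column_spacing: float = 500.0  # µm between column centers
    minicolumn_spacing: float = 30.0  # µm between minicolumn stacks
    layer_thickness: float = 280.0  # µm per layer; total depth 6x this
    couple_mtype_to_etype: bool = True  # pyramidal <=> excitatory
    pyramidal_fraction: float = 0.9  # used only when uncoupled
    morphometrics: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MORPHO)
    )
    seed: int = 0

    n_layers: int = N_LAYERS  # fixed six-layer laminar organization

    def validate(self) -> None:
        if min(self.n_columns, self.n_minicolumns_per_column,
               self.n_neurons_per_minicolumn) < 1:
            raise ValidationError("all counts must be >= 1")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValidationError("inhibitory_fraction must be in [0, 1]")
        if self.n_layers != N_LAYERS:
            raise ValidationError("the laminar organization is fixed at six layers")
        for key in MORPHOMETRIC_KEYS:
            if key not in self.morphometrics:
                raise ValidationError(f"missing morphometric distribution for {key!r}")

    @property
    def n_neurons(self) -> int:
        return (self.n_columns * self.n_minicolumns_per_column
                * self.n_neurons_per_minicolumn)


@dataclass
class ActivitySpec:
    """Parameters of synthetic spiking activity.

    Background firing is homogeneous Poisson per neuron. Each stimulus
    triggers, layer by layer in ``wave_layer_order`` (deep layer VI first by
    default), a Poisson burst of ``burst_rate`` Hz lasting ``burst_width`` ms,
    delayed by ``layer_latency`` ms per rank in the order.
    """

    duration: float = 300.0  # ms
    background_rate: float = 2.0  # Hz per neuron
    stimulus_times: list[float] = field(default_factory=lambda: [50.0])
    wave_layer_order: tuple[int, ...] = (6, 5, 4, 3, 2, 1)
    layer_latency: float = 10.0  # ms between successive layers of the wave
    burst_rate: float = 300.0  # Hz per neuron during a burst
    burst_width: float = 8.0  # ms
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.background_rate < 0 or self.burst_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.layer_latency < 0 or self.burst_width < 0:
            raise ValidationError("latency and burst width must be >= 0")
        if len(set(self.wave_layer_order)) != len(self.wave_layer_order):
            raise ValidationError("wave_layer_order must not repeat layers")
        for lyr in self.wave_layer_order:
            if not 1 <= lyr <= N_LAYERS:
                raise ValidationError(f"layer {lyr} out of range in wave order")


#: Named parameter presets. ``bbp-like`` mirrors the organization of the
#: 217,000-neuron cortical-column dataset; ``tiny`` is a fast test circuit.
PRESETS: dict[str, CircuitSpec] = {
    "bbp-like": CircuitSpec(),
    "tiny": CircuitSpec(n_columns=2, n_minicolumns_per_column=3,
                        n_neurons_per_minicolumn=10),
}


def _column_centers(n: int, spacing: float) -> np.ndarray:
    """(n, 2) xz centers: one at the origin, then hexagonal rings outward."""
    centers = [(0.0, 0.0)]
    ring = 1
    while len(centers) < n:
        k = 6 * ring
        for j in range(k):
            ang = 2.0 * math.pi * j / k
            centers.append((ring * spacing * math.cos(ang),
                            ring * spacing * math.sin(ang)))
            if len(centers) == n:
                break
        ring += 1
    return np.array(centers[:n])


def generate_circuit(spec: CircuitSpec) -> list[NeuronRecord]:
    """Generate a circuit as a list of validated neuron records.

    Layout: columns on hexagonal rings (1 center + 6 around for the default
    seven), minicolumns on a jittered square grid inside each column
    footprint, neurons stacked by depth with the layer assigned by equal
    depth bands (layer I at the top / largest y).
    """
    spec.validate()
    placement = _rng(spec.seed, "placement")
    types = _rng(spec.seed, "types")
    morpho = _rng(spec.seed, "morphometrics")

    n_col = spec.n_columns
    n_mc = spec.n_minicolumns_per_column
    n_per = spec.n_neurons_per_minicolumn
    total = spec.n_neurons
    height = spec.n_layers * spec.layer_thickness

    col_centers = _column_centers(n_col, spec.column_spacing)

    # Minicolumn grid per column, jittered.
    g = math.ceil(math.sqrt(n_mc))
    mc_idx = np.arange(n_mc)
    gx = (mc_idx % g - (g - 1) / 2.0) * spec.minicolumn_spacing
    gz = (mc_idx // g - (g - 1) / 2.0) * spec.minicolumn_spacing
    jitter = placement.uniform(-0.25 * spec.minicolumn_spacing,
                               0.25 * spec.minicolumn_spacing,
                               size=(n_col, n_mc, 2))

    # Depth stack within a minicolumn: even coverage of the six layer bands.
    depth = (np.arange(n_per) + 0.5) * height / n_per
    layer_of_depth = np.minimum(
        spec.n_layers, 1 + (depth // spec.layer_thickness).astype(np.int64)
    )
    lateral = placement.uniform(-0.3 * spec.minicolumn_spacing,
                                0.3 * spec.minicolumn_spacing,
                                size=(total, 2))

    inhibitory = types.random(total) < spec.inhibitory_fraction
    if spec.couple_mtype_to_etype:
        interneuron = inhibitory.copy()
    else:
        interneuron = types.random(total) >= spec.pyramidal_fraction

    morph_vals = {
        key: morpho.lognormal(mu, sigma, size=total)
        for key, (mu, sigma) in ((k, spec.morphometrics[k]) for k in MORPHOMETRIC_KEYS)
    }
    morph_vals["dendritic_bifurcations"] = np.rint(
        morph_vals["dendritic_bifurcations"]
    )

    records: list[NeuronRecord] = []
    gid = 0
    for c in range(n_col):
        cx, cz = col_centers[c]
        for m in range(n_mc):
            mx = cx + gx[m] + jitter[c, m, 0]
            mz = cz + gz[m] + jitter[c, m, 1]
            for k in range(n_per):
                x = mx + lateral[gid, 0]
                z = mz + lateral[gid, 1]
                y = height - depth[k]
                records.append(NeuronRecord(
                    gid=gid,
                    position=(float(x), float(y), float(z)),
                    layer=int(layer_of_depth[k]),
                    column=c,
                    minicolumn=m,
                    mtype="interneuron" if interneuron[gid] else "pyramidal",
                    etype="inhibitory" if inhibitory[gid] else "excitatory",
                    morphometrics={key: float(morph_vals[key][gid])
                                   for key in MORPHOMETRIC_KEYS},
                ))
                gid += 1
    return records


def generate_spikes(circuit: Sequence[NeuronRecord], aspec: ActivitySpec) -> SpikeReport:
    """Poisson background plus layer-ordered stimulus bursts, merged and
    sorted, clipped to ``[0, duration)``."""
    aspec.validate()
    rng = _rng(aspec.seed, "spikes")
    T = aspec.duration
    gids = np.array([r.gid for r in circuit], dtype=np.int64)
    layers = np.array([r.layer for r in circuit], dtype=np.int64)

    all_times: list[np.ndarray] = []
    all_gids: list[np.ndarray] = []

    # Homogeneous Poisson background over [0, T).
    if aspec.background_rate > 0:
        counts = rng.poisson(aspec.background_rate * T / 1000.0, size=gids.size)
        tot = int(counts.sum())
        if tot:
            all_times.append(rng.uniform(0.0, T, size=tot))
            all_gids.append(np.repeat(gids, counts))

    # Stimulus-evoked bursts, deep layers first.
    if aspec.burst_rate > 0:
        for s in aspec.stimulus_times:
            for rank, lyr in enumerate(aspec.wave_layer_order):
                w0 = s + rank * aspec.layer_latency
                w1 = min(w0 + aspec.burst_width, T)
                if w1 <= max(w0, 0.0):
                    continue
                w0 = max(w0, 0.0)
                members = gids[layers == lyr]
                if members.size == 0:
                    continue
                counts = rng.poisson(
                    aspec.burst_rate * (w1 - w0) / 1000.0, size=members.size
                )
                tot = int(counts.sum())
                if tot:
                    all_times.append(rng.uniform(w0, w1, size=tot))
                    all_gids.append(np.repeat(members, counts))

    if not all_times:
        return SpikeReport(np.empty(0), np.empty(0, dtype=np.int64), 0.0, T)
    times = np.concatenate(all_times)
    spike_gids = np.concatenate(all_gids)
    keep = times < T
    times, spike_gids = times[keep], spike_gids[keep]
    order = np.lexsort((spike_gids, times))
    return SpikeReport(times[order], spike_gids[order], 0.0, T)


def generate_voltage(
    circuit: Sequence[NeuronRecord],
    aspec: ActivitySpec,
    v_rest: float = -65.0,
    v_peak: float = 20.0,
    tau: float = 5.0,
    dt: float = 0.5,
) -> VoltageReport:
    """Display-style membrane trace: each spike jumps the neuron to
    ``v_peak`` and relaxes exponentially back toward ``v_rest`` with time
    constant ``tau``; ``v_rest`` before any spike. Sampled every ``dt`` ms.

    This is a rendering trace, not a biophysical membrane model.
    """
    spikes = generate_spikes(circuit, aspec)
    gids = [r.gid for r in circuit]
    return voltage_from_spikes(spikes, gids, v_rest, v_peak, tau, dt)


def voltage_from_spikes(
    spikes: SpikeReport,
    gids: Sequence[int],
    v_rest: float = -65.0,
    v_peak: float = 20.0,
    tau: float = 5.0,
    dt: float = 0.5,
) -> VoltageReport:
    """The display trace itself: sample
    ``v(t) = v_rest + (v_peak - v_rest) * exp(-(t - t_last_spike)/tau)``
    (``v_rest`` before any spike) at ``t_start + k*dt`` for an existing
    spike report."""
    if tau <= 0 or dt <= 0:
        raise ValidationError("tau and dt must be > 0")
    n_frames = int(math.floor((spikes.t_end - spikes.t_start) / dt)) + 1
    t = spikes.t_start + dt * np.arange(n_frames)
    values = np.full((n_frames, len(gids)), float(v_rest))

    by_gid: dict[int, list[float]] = {}
    for st, sg in zip(spikes.times, spikes.gids):
        by_gid.setdefault(int(sg), []).append(float(st))
    for j, g in enumerate(gids):
        st = by_gid.get(int(g))
        if not st:
            continue
        st_arr = np.array(st)  # already ascending
        last = np.searchsorted(st_arr, t, side="right") - 1
        fired = last >= 0
        elapsed = t[fired] - st_arr[last[fired]]
        values[fired, j] = v_rest + (v_peak - v_rest) * np.exp(-elapsed / tau)
    return VoltageReport(t_start=float(spikes.t_start), dt=dt,
                         gids=[int(g) for g in gids], values=values)
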