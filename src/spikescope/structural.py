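"""Symbolic structural views: glyph encoding of morphometrics, range
filtering, sorting, layouts and hierarchical selection states.

A neuron's glyph encodes its physiological type as a color category (reddish
for excitatory, bluish for inhibitory), its morphological type as the central
symbol (triangle for pyramidal cells, circle for interneurons), dendritic
bifurcations as a pie fraction, and the volume/surface of soma and dendrites
on two rings: brightness for volume, sweep angle for surface (greenish inner
soma ring, reddish outer dendrite ring). All ring/pie encodings are
normalized against the currently displayed population so each view uses the
full visual dynamic range.

The selection hierarchy covers column → (layer-within-column | minicolumn) →
neuron; aggregate nodes are marked *full* when every member neuron is
selected, *partial* when only some are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .simdata import (
    MORPHOMETRIC_KEYS,
    NeuronRecord,
    Selection,
    ValidationError,
)

__all__ = [
    "GlyphDescriptor",
    "FilterSpec",
    "FADE_OPACITY",
    "attribute_ranges",
    "glyph",
    "apply_filter",
    "sort_neurons",
    "layout_grid",
    "layout_3d",
    "rubber_band",
    "aggregate_state",
]

FADE_OPACITY = 0.25

_SCALAR_FIELDS = ("gid", "layer", "column", "minicolumn")


@dataclass
class GlyphDescriptor:
    """Display parameters of one neuron's glyph."""

    fill: str  # 'reddish' | 'bluish'
    symbol: str  # 'triangle' | 'circle'
    pie_fraction: float
    soma_angle: float  # degrees in [0, 360]
    soma_brightness: float
    dendrite_angle: float
    dendrite_brightness: float
    soma_hue: str = "greenish"
    dendrite_hue: str = "reddish"
    opacity: float = 1.0


@dataclass
class FilterSpec:
    """Conjunction of closed morphometric ranges; removed neurons are either
    faded (kept in the layout at low opacity) or hidden."""

    ranges: list[tuple[str, float, float]]
    mode: str = "fade"  # or 'hide'

    def __post_init__(self) -> None:
        if self.mode not in ("fade", "hide"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        for attr, lo, hi in self.ranges:
            if attr not in MORPHOMETRIC_KEYS:
                raise ValidationError(f"unknown morphometric attribute {attr!r}")
            if lo > hi:
                raise ValidationError(f"empty range for {attr!r}: {lo} > {hi}")


def attribute_ranges(
    neurons: Sequence[NeuronRecord],
) -> dict[str, tuple[float, float]]:
    """(min, max) of every morphometric over the displayed population."""
    out: dict[str, tuple[float, float]] = {}
    for key in MORPHOMETRIC_KEYS:
        vals = [n.morphometrics[key] for n in neurons]
        out[key] = (min(vals), max(vals)) if vals else (0.0, 0.0)
    return out


def _norm(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.0
    return min(1.0, max(0.0, (x - lo) / (hi - lo)))


def glyph(
    neuron: NeuronRecord,
    norm: Mapping[str, tuple[float, float]],
    opacity: float = 1.0,
) -> GlyphDescriptor:
    """Build the glyph for one neuron given population (min, max) ranges."""
    if neuron.etype == "excitatory":
        fill = "reddish"
    elif neuron.etype == "inhibitory":
        fill = "bluish"
    else:
        raise ValidationError(f"unknown etype {neuron.etype!r}")
    if neuron.mtype == "pyramidal":
        symbol = "triangle"
    elif neuron.mtype == "interneuron":
        symbol = "circle"
    else:
        raise ValidationError(f"unknown mtype {neuron.mtype!r}")

    m = neuron.morphometrics

    def nrm(key: str) -> float:
        lo, hi = norm[key]
        return _norm(m[key], lo, hi)

    return GlyphDescriptor(
        fill=fill,
        symbol=symbol,
        pie_fraction=nrm("dendritic_bifurcations"),
        soma_angle=360.0 * nrm("soma_surface"),
        soma_brightness=nrm("soma_volume"),
        dendrite_angle=360.0 * nrm("dendritic_surface"),
        dendrite_brightness=nrm("dendritic_volume"),
        opacity=opacity,
    )


def apply_filter(
    neurons: Sequence[NeuronRecord], spec: FilterSpec
) -> tuple[set[int], set[int]]:
    """Split gids into (kept, removed): kept neurons satisfy every closed
    range of the spec."""
    kept: set[int] = set()
    removed: set[int] = set()
    for n in neurons:
        ok = all(lo <= n.morphometrics[attr] <= hi for attr, lo, hi in spec.ranges)
        (kept if ok else removed).add(n.gid)
    return kept, removed


def _attr_value(n: NeuronRecord, attribute: str) -> float:
    if attribute in MORPHOMETRIC_KEYS:
        return n.morphometrics[attribute]
    if attribute in _SCALAR_FIELDS:
        return float(getattr(n, attribute))
    raise ValidationError(f"unknown sort attribute {attribute!r}")


def sort_neurons(
    neurons: Sequence[NeuronRecord], attribute: str, ascending: bool = True
) -> list[NeuronRecord]:
    """Stable sort by one attribute, ties broken by gid ascending."""
    if neurons and attribute not in MORPHOMETRIC_KEYS and attribute not in _SCALAR_FIELDS:
        raise ValidationError(f"unknown sort attribute {attribute!r}")
    sign = 1.0 if ascending else -1.0
    return sorted(neurons, key=lambda n: (sign * _attr_value(n, attribute), n.gid))


def layout_grid(
    n_items: int, viewport: tuple[float, float]
) -> list[tuple[float, float]]:
    """Row-major square-ish grid: cell centers for ``n_items`` glyphs."""
    if n_items < 0:
        raise ValidationError("n_items must be >= 0")
    if n_items == 0:
        return []
    w, h = viewport
    cols = math.ceil(math.sqrt(n_items))
    rows = math.ceil(n_items / cols)
    cw, ch = w / cols, h / rows
    return [
        ((i % cols + 0.5) * cw, (i // cols + 0.5) * ch)
        for i in range(n_items)
    ]


def layout_3d(circuit: Sequence[NeuronRecord], camera) -> dict[int, tuple[float, float]]:
    """2D glyph positions mimicking the spatial render: each soma projected
    through the shared camera; neurons behind the camera are omitted."""
    import numpy as np

    from .particles import project_points

    if not circuit:
        return {}
    pos = np.array([r.position for r in circuit], dtype=float)
    x, y, _, vis = project_points(camera, pos)
    return {
        r.gid: (float(x[i]), float(y[i]))
        for i, r in enumerate(circuit)
        if vis[i]
    }


def rubber_band(
    positions: Mapping[int, tuple[float, float]],
    rectangle: tuple[float, float, float, float],
    name: str = "rubber-band",
) -> Selection:
    """Select all visible items whose layout position lies inside the closed
    axis-aligned rectangle (any two opposite corners)."""
    x0, y0, x1, y1 = rectangle
    xlo, xhi = min(x0, x1), max(x0, x1)
    ylo, yhi = min(y0, y1), max(y0, y1)
    gids = {
        g for g, (px, py) in positions.items()
        if xlo <= px <= xhi and ylo <= py <= yhi
    }
    return Selection(name, frozenset(gids))


def aggregate_state(
    selection: Iterable[int], circuit: Sequence[NeuronRecord]
) -> dict[tuple, str]:
    """Full/partial/none marking of every aggregate node.

    Node keys: ``('column', c)``, ``('layer', c, l)`` for a layer within a
    column, and ``('minicolumn', c, m)``.
    """
    selected = set(int(g) for g in selection)
    members: dict[tuple, list[int]] = {}
    for n in circuit:
        members.setdefault(("column", n.column), []).append(n.gid)
        members.setdefault(("layer", n.column, n.layer), []).append(n.gid)
        members.setdefault(("minicolumn", n.column, n.minicolumn), []).append(n.gid)
    out: dict[tuple, str] = {}
    for node, gids in members.items():
        n_sel = sum(1 for g in gids if g in selected)
        if n_sel == 0:
            out[node] = "none"
        elif n_sel == len(gids):
            out[node] = "full"
        else:
            out[node] = "partial"
    return out
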