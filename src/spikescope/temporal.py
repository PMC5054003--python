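"""Binned activity views with dual normalization, scale mapping and a
focus+context magnifier.

The central object is a stack of per-subset histograms sharing one binning of
the analysis window ``[t0, t1]``. Each histogram carries the raw per-bin
magnitudes (spike counts, or mean voltages) and two curves in ``[0, 1]``:

* a **local** curve, normalized by the subset's own maximum — good for
  reading one subset's temporal structure ("horizontal" analysis);
* a **global** curve, normalized by the whole-dataset maximum — good for
  comparing magnitudes across subsets ("vertical" analysis).

Either curve can be displayed on a linear or a logarithmic scale; the log
mapping ``y = ln(1 + c*x) / ln(1 + c)`` keeps the curve in ``[0, 1]`` and is
defined at 0, while strongly expanding small values (a faint precursor peak a
thousandth of the global maximum maps to about 0.1 of the axis at the default
``c = 1000``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .simdata import Selection, SpikeReport, ValidationError, VoltageReport

__all__ = [
    "DEFAULT_N_BINS",
    "LOG_SCALE_C",
    "HistogramView",
    "StackedViews",
    "ROISpec",
    "bin_spikes",
    "bin_voltage",
    "normalize_local",
    "normalize_global",
    "apply_scale",
    "build_stack",
    "focus_roi",
]

DEFAULT_N_BINS = 250
LOG_SCALE_C = 1000.0

Report = Union[SpikeReport, VoltageReport]


@dataclass
class HistogramView:
    """One subset's binned activity over ``[t0, t1]`` with both normalized
    curves (post scale mapping)."""

    t0: float
    t1: float
    n_bins: int
    counts: np.ndarray
    local_curve: np.ndarray
    global_curve: np.ndarray
    scale: str = "linear"
    subset_name: str = "all"


@dataclass
class StackedViews:
    """Ordered histogram stack; row 0 is always the whole-dataset view and
    supplies ``global_max`` for every row's global curve."""

    views: list[HistogramView]
    t0: float
    t1: float
    n_bins: int
    global_max: float


@dataclass
class ROISpec:
    """Region of interest for the focus view: a window of ``width`` ms around
    ``center``, magnified by ``scaling_factor`` (>= 1)."""

    center: float
    width: float
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("ROI width must be > 0")
        if self.scaling_factor < 1:
            raise ValidationError("scaling_factor must be >= 1")

    def clamped(self, t0: float, t1: float) -> tuple[float, float]:
        lo = max(t0, self.center - self.width / 2.0)
        hi = min(t1, self.center + self.width / 2.0)
        if hi <= lo:
            raise ValidationError("ROI does not intersect the analysis window")
        return lo, hi


def _check_window(t0: float, t1: float, n_bins: int) -> None:
    if t1 <= t0:
        raise ValidationError("need t1 > t0")
    if n_bins < 1:
        raise ValidationError("need n_bins >= 1")


def bin_spikes(
    report: SpikeReport,
    subset: Iterable[int],
    t0: float,
    t1: float,
    n_bins: int,
) -> np.ndarray:
    """Per-bin spike counts of ``subset`` over ``[t0, t1]``.

    Bin ``i`` covers ``[t0 + i*w, t0 + (i+1)*w)`` with ``w = (t1-t0)/n_bins``;
    an event exactly at ``t1`` lands in the last bin. An empty subset yields
    all-zero counts.
    """
    _check_window(t0, t1, n_bins)
    subset = np.asarray(sorted(set(int(g) for g in subset)), dtype=np.int64)
    if subset.size == 0 or report.n_events == 0:
        return np.zeros(n_bins)
    mask = np.isin(report.gids, subset)
    t = report.times[mask]
    t = t[(t >= t0) & (t <= t1)]
    w = (t1 - t0) / n_bins
    idx = np.minimum(((t - t0) / w).astype(np.int64), n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)


def bin_voltage(
    report: VoltageReport,
    subset: Iterable[int],
    t0: float,
    t1: float,
    n_bins: int,
) -> np.ndarray:
    """Per-bin mean voltage over the subset's neurons and the frames whose
    timestamp falls in the bin.

    A bin containing no frame copies its left neighbor; an empty first bin
    takes the report's first frame value.
    """
    _check_window(t0, t1, n_bins)
    subset = sorted(set(int(g) for g in subset))
    if not subset:
        raise ValidationError("bin_voltage needs a non-empty subset")
    col_of = {g: j for j, g in enumerate(report.gids)}
    try:
        cols = [col_of[g] for g in subset]
    except KeyError as exc:
        raise ValidationError(f"gid {exc.args[0]} not in voltage report") from exc

    frame_mean = report.values[:, cols].mean(axis=1)
    times = report.times
    w = (t1 - t0) / n_bins
    in_win = (times >= t0) & (times <= t1)
    idx = np.minimum(((times[in_win] - t0) / w).astype(np.int64), n_bins - 1)
    vals = frame_mean[in_win]

    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    nums = np.bincount(idx, minlength=n_bins)
    counts = np.empty(n_bins)
    prev = float(frame_mean[0])
    for i in range(n_bins):
        if nums[i] > 0:
            prev = sums[i] / nums[i]
        counts[i] = prev
    return counts


def normalize_local(counts: np.ndarray) -> np.ndarray:
    """Divide by the subset's own maximum; all-zero input stays all-zero."""
    counts = np.asarray(counts, dtype=float)
    m = counts.max() if counts.size else 0.0
    if m <= 0:
        return np.zeros_like(counts)
    return counts / m


def normalize_global(counts: np.ndarray, global_max: float) -> np.ndarray:
    """Divide by the whole-dataset maximum."""
    counts = np.asarray(counts, dtype=float)
    if global_max < 0:
        raise ValidationError("global_max must be >= 0")
    if counts.size and counts.max() > global_max * (1 + 1e-12) + 1e-12:
        raise ValidationError("global_max smaller than a subset count")
    if global_max == 0:
        return np.zeros_like(counts)
    return counts / global_max


def apply_scale(curve: np.ndarray, scale: str, c: float = LOG_SCALE_C) -> np.ndarray:
    """Map a curve in [0, 1] to display space.

    ``linear`` is the identity; ``logarithmic`` applies the monotone
    bijection ``y = ln(1 + c*x) / ln(1 + c)`` (0 -> 0 and 1 -> 1).
    """
    curve = np.asarray(curve, dtype=float)
    if scale == "linear":
        return curve.copy()
    if scale in ("logarithmic", "log"):
        return np.log1p(c * curve) / math.log1p(c)
    raise ValidationError(f"unknown scale {scale!r}")


def _is_voltage(report: Report) -> bool:
    return isinstance(report, VoltageReport)


def _all_gids(report: Report) -> set[int]:
    if _is_voltage(report):
        return set(report.gids)
    return set(int(g) for g in np.unique(report.gids))


def _make_view(
    counts: np.ndarray,
    name: str,
    t0: float,
    t1: float,
    n_bins: int,
    scale: str,
    global_max: float,
    global_shift: float,
    voltage: bool,
) -> HistogramView:
    if voltage:
        # Shift so curves live in [0, 1] even for negative mV: local against
        # the subset minimum, global against the dataset min-max frame. A
        # subset's mean can leave the dataset-mean range, so the global
        # curve is clamped rather than treated as a contract violation.
        local_raw = counts - counts.min() if counts.size else counts
        local = apply_scale(normalize_local(local_raw), scale)
        if global_max > 0:
            glob_raw = np.clip((counts - global_shift) / global_max, 0.0, 1.0)
        else:
            glob_raw = np.zeros_like(counts)
        glob = apply_scale(glob_raw, scale)
    else:
        local = apply_scale(normalize_local(counts), scale)
        glob = apply_scale(normalize_global(counts, global_max), scale)
    return HistogramView(t0, t1, n_bins, counts, local, glob, scale, name)


def build_stack(
    report: Report,
    selections: Sequence[Selection] = (),
    t0: float | None = None,
    t1: float | None = None,
    n_bins: int = DEFAULT_N_BINS,
    scale: str = "linear",
    all_gids: Iterable[int] | None = None,
) -> StackedViews:
    """Assemble the histogram stack: the whole-dataset view first, then one
    view per selection, all sharing the binning and the row-0 global maximum.
    """
    voltage = _is_voltage(report)
    if t0 is None:
        t0 = report.t_start
    if t1 is None:
        t1 = report.t_end
    _check_window(t0, t1, n_bins)
    universe = set(all_gids) if all_gids is not None else _all_gids(report)

    binner = bin_voltage if voltage else bin_spikes
    base_counts = binner(report, universe, t0, t1, n_bins)
    if voltage:
        global_shift = float(base_counts.min())
        global_max = float((base_counts - global_shift).max())
    else:
        global_shift = 0.0
        global_max = float(base_counts.max()) if base_counts.size else 0.0

    views = [_make_view(base_counts, "all", t0, t1, n_bins, scale,
                        global_max, global_shift, voltage)]
    for sel in selections:
        counts = binner(report, sel.gids, t0, t1, n_bins)
        views.append(_make_view(counts, sel.name, t0, t1, n_bins, scale,
                                global_max, global_shift, voltage))
    return StackedViews(views, t0, t1, n_bins, global_max)


def focus_roi(
    report: Report,
    subset: Iterable[int],
    roi: ROISpec,
    t0: float,
    t1: float,
    n_bins: int,
    scale: str = "linear",
    global_max: float | None = None,
) -> HistogramView:
    """Magnified re-binning of the raw data inside the ROI (never an
    interpolation of the context curve).

    The focus view uses ``ceil(n_bins * scaling_factor * width / (t1 - t0))``
    bins (at least 1) over the clamped ROI window.
    """
    _check_window(t0, t1, n_bins)
    lo, hi = roi.clamped(t0, t1)
    n_focus = max(1, math.ceil(n_bins * roi.scaling_factor * (hi - lo) / (t1 - t0)))
    voltage = _is_voltage(report)
    binner = bin_voltage if voltage else bin_spikes
    counts = binner(report, subset, lo, hi, n_focus)
    if voltage:
        shift = float(counts.min())
        gmax = global_max if global_max is not None else float((counts - shift).max())
        return _make_view(counts, "focus", lo, hi, n_focus, scale, gmax, shift, True)
    gmax = global_max if global_max is not None else float(counts.max())
    return _make_view(counts, "focus", lo, hi, n_focus, scale, gmax, 0.0, False)
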