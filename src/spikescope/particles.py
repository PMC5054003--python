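"""Spike-triggered particle engine with decay, transfer functions, a pinhole
camera and a deterministic CPU rasterizer.

Each neuron is one particle. In spike mode a spike sets the particle's *life*
to 1, and life then decays linearly to 0 over the configured decay time (the
"tail effect"); color and size are looked up from piecewise-linear transfer
functions over life, so any perceptual shaping — from abrupt blinking to slow
fades — is expressed through control points rather than the clock itself. In
voltage mode the instantaneous membrane value is min–max mapped into the same
[0, 1] parameter.

Rendering is a deliberately simple, bit-reproducible CPU rasterizer: each
active particle becomes a filled disk at its projected position, composited
either back-to-front with the source-over rule (depth cues preserved) or
additively in any order (saturating summary of dense activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .simdata import NeuronRecord, Selection, SpikeReport, ValidationError, VoltageReport

__all__ = [
    "TransferFunction",
    "SizeFunction",
    "DEFAULT_TF",
    "DEFAULT_SIZEF",
    "ParticleState",
    "CameraState",
    "RenderSettings",
    "init_state",
    "advance",
    "seek",
    "voltage_state",
    "voltage_to_t",
    "project",
    "project_points",
    "render_frame",
]

RGBA = tuple[float, float, float, float]


def _check_knots(ts: Sequence[float]) -> None:
    if len(ts) < 2 or ts[0] != 0.0 or ts[-1] != 1.0:
        raise ValidationError("control points must start at t=0 and end at t=1")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValidationError("control-point t values must be strictly increasing")


@dataclass(frozen=True)
class TransferFunction:
    """Piecewise-linear map from a normalized parameter in [0, 1] to RGBA."""

    points: tuple[tuple[float, RGBA], ...]

    def __post_init__(self) -> None:
        _check_knots([t for t, _ in self.points])
        for _, rgba in self.points:
            if len(rgba) != 4 or any(not 0.0 <= ch <= 1.0 for ch in rgba):
                raise ValidationError("RGBA channels must be in [0, 1]")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        ts = np.array([p[0] for p in self.points])
        chans = np.array([p[1] for p in self.points])  # (k, 4)
        out = np.stack([np.interp(t, ts, chans[:, c]) for c in range(4)], axis=-1)
        return out


@dataclass(frozen=True)
class SizeFunction:
    """Piecewise-linear map from the parameter to a particle diameter (px)."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        _check_knots([t for t, _ in self.points])
        if any(s <= 0 for _, s in self.points):
            raise ValidationError("sizes must be > 0 pixels")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        ts = np.array([p[0] for p in self.points])
        ss = np.array([p[1] for p in self.points])
        return np.interp(t, ts, ss)


# Spike-mode default: red at full life through orange to blue at rest.
DEFAULT_TF = TransferFunction((
    (0.0, (0.0, 0.1, 1.0, 0.2)),
    (0.5, (1.0, 0.55, 0.0, 0.6)),
    (1.0, (1.0, 0.0, 0.0, 1.0)),
))
DEFAULT_SIZEF = SizeFunction(((0.0, 2.0), (1.0, 8.0)))


@dataclass
class ParticleState:
    """Per-neuron life fractions at one instant of playback."""

    gids: np.ndarray
    life: np.ndarray
    time: float
    decay: float
    mode: str = "spike"  # 'spike' or 'voltage'

    def __post_init__(self) -> None:
        self.gids = np.asarray(self.gids, dtype=np.int64)
        self.life = np.asarray(self.life, dtype=float)
        if self.mode == "spike" and self.decay <= 0:
            raise ValidationError("decay must be > 0 ms")
        if self.life.size and (self.life.min() < 0 or self.life.max() > 1):
            raise ValidationError("life values must lie in [0, 1]")


def init_state(gids: Sequence[int], decay: float, time: float = 0.0) -> ParticleState:
    gids = np.asarray(gids, dtype=np.int64)
    return ParticleState(gids, np.zeros(gids.size), time, decay)


def advance(
    state: ParticleState,
    spike_times: Sequence[float],
    spike_gids: Sequence[int],
    t_now: float,
) -> ParticleState:
    """Step the state forward to ``t_now`` given the spikes in
    ``(state.time, t_now]``.

    A spiking neuron's life restarts at 1 at its latest spike (no additive
    stacking) and then decays linearly; every other life simply decays.
    """
    if t_now < state.time:
        raise ValidationError("time must not move backward; use seek()")
    spike_times = np.asarray(spike_times, dtype=float)
    spike_gids = np.asarray(spike_gids, dtype=np.int64)
    in_win = (spike_times > state.time) & (spike_times <= t_now)
    spike_times, spike_gids = spike_times[in_win], spike_gids[in_win]

    dt = t_now - state.time
    life = np.clip(state.life - dt / state.decay, 0.0, 1.0)
    if spike_times.size:
        idx_of = {int(g): i for i, g in enumerate(state.gids)}
        latest: dict[int, float] = {}
        for t, g in zip(spike_times, spike_gids):
            g = int(g)
            if g in idx_of and (g not in latest or t > latest[g]):
                latest[g] = float(t)
        for g, ts in latest.items():
            life[idx_of[g]] = max(0.0, 1.0 - (t_now - ts) / state.decay)
    return ParticleState(state.gids, life, t_now, state.decay, state.mode)


def seek(
    report: SpikeReport,
    t: float,
    decay: float,
    gids: Sequence[int] | None = None,
) -> ParticleState:
    """Random-access state at time ``t``: computed from each neuron's last
    spike at or before ``t``, equivalent to advancing from the report start.
    """
    if gids is None:
        gids = np.unique(report.gids)
    gids = np.asarray(gids, dtype=np.int64)
    life = np.zeros(gids.size)
    past = report.times <= t
    if past.any():
        pt, pg = report.times[past], report.gids[past]
        # events are time-sorted, so the last occurrence per gid is its
        # latest spike
        last: dict[int, float] = {}
        for st, sg in zip(pt, pg):
            last[int(sg)] = float(st)
        for i, g in enumerate(gids):
            ts = last.get(int(g))
            if ts is not None:
                life[i] = max(0.0, 1.0 - (t - ts) / decay)
    return ParticleState(gids, life, float(t), decay)


def voltage_to_t(v: float | np.ndarray, v_min: float, v_max: float):
    """Min–max map a membrane value (mV) into the transfer-function
    parameter, clamped to [0, 1]."""
    if v_max <= v_min:
        raise ValidationError("need v_max > v_min")
    return np.clip((np.asarray(v, dtype=float) - v_min) / (v_max - v_min), 0.0, 1.0)


def voltage_state(
    report: VoltageReport, frame: int, v_min: float, v_max: float
) -> ParticleState:
    """Particle state for one voltage frame: life holds the mapped voltage
    and every particle renders (no decay in voltage mode)."""
    values = report.values[frame]
    t = float(report.t_start + frame * report.dt)
    return ParticleState(
        np.asarray(report.gids, dtype=np.int64),
        np.asarray(voltage_to_t(values, v_min, v_max)),
        t,
        decay=1.0,
        mode="voltage",
    )


@dataclass
class CameraState:
    """Pinhole camera: 4x4 world→camera view matrix (right-handed, column
    vectors, looking down camera −z), vertical field of view in degrees, and
    a pixel viewport with y down and the origin at the top-left."""

    view: np.ndarray = field(default_factory=lambda: np.eye(4))
    fov_deg: float = 60.0
    viewport: tuple[int, int] = (640, 480)
    near: float = 0.1
    far: float = 1e6

    def __post_init__(self) -> None:
        self.view = np.asarray(self.view, dtype=float)
        if self.view.shape != (4, 4):
            raise ValidationError("view matrix must be 4x4")
        if abs(np.linalg.det(self.view)) < 1e-12:
            raise ValidationError("view matrix must be invertible")
        if not 0.0 < self.fov_deg < 180.0:
            raise ValidationError("fov must be in (0, 180) degrees")
        if min(self.viewport) <= 0:
            raise ValidationError("viewport must be positive")

    @property
    def focal(self) -> float:
        return (self.viewport[1] / 2.0) / math.tan(math.radians(self.fov_deg) / 2.0)


def project_points(camera: CameraState, points: np.ndarray):
    """Project (N, 3) world points; returns (x_px, y_px, depth, visible).

    ``visible`` is False for points at or behind the near plane; their pixel
    coordinates are undefined.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    homo = np.hstack([points, np.ones((points.shape[0], 1))])
    cam = (camera.view @ homo.T).T
    z = cam[:, 2]
    visible = z < -camera.near
    w, h = camera.viewport
    with np.errstate(divide="ignore", invalid="ignore"):
        x_px = w / 2.0 + camera.focal * cam[:, 0] / (-z)
        y_px = h / 2.0 - camera.focal * cam[:, 1] / (-z)
    depth = -z
    return x_px, y_px, depth, visible


def project(camera: CameraState, position) -> tuple[float, float, float] | None:
    """Project one world point; ``None`` means behind the camera."""
    x, y, d, vis = project_points(camera, np.asarray(position, dtype=float))
    if not vis[0]:
        return None
    return float(x[0]), float(y[0]), float(d[0])


@dataclass
class RenderSettings:
    """Compositing mode, background, and selection-aware context styling."""

    blend: str = "traditional"  # or 'accumulative'
    background: RGBA = (0.0, 0.0, 0.0, 1.0)
    selection: Selection | None = None
    context_color: RGBA = (0.5, 0.5, 0.5, 0.25)
    context_size: float = 2.0  # px diameter floor for non-selected neurons

    def __post_init__(self) -> None:
        if self.blend not in ("traditional", "accumulative"):
            raise ValidationError(f"unknown blend mode {self.blend!r}")
        for ch in tuple(self.background) + tuple(self.context_color):
            if not 0.0 <= ch <= 1.0:
                raise ValidationError("color channels must be in [0, 1]")


def _positions_of(circuit, gids: np.ndarray) -> np.ndarray:
    if isinstance(circuit, Mapping):
        lookup = circuit
    else:
        lookup = {r.gid: r.position for r in circuit}
    try:
        return np.array([lookup[int(g)] for g in gids], dtype=float)
    except KeyError as exc:
        raise ValidationError(f"no position for gid {exc.args[0]}") from exc


def render_frame(
    circuit: Sequence[NeuronRecord] | Mapping[int, tuple[float, float, float]],
    state: ParticleState,
    tf: TransferFunction = DEFAULT_TF,
    sizef: SizeFunction = DEFAULT_SIZEF,
    camera: CameraState | None = None,
    settings: RenderSettings | None = None,
) -> np.ndarray:
    """Rasterize one frame; returns a float (H, W, 4) RGBA image in [0, 1].

    Active particles (life > 0 in spike mode, every particle in voltage
    mode) are filled disks — a pixel belongs to a disk when its center lies
    within the radius. Traditional blending composites far→near with the
    source-over rule (depth ties broken by gid ascending); accumulative
    blending adds alpha-weighted color order-independently and clamps.
    Under an active selection, non-selected neurons render in the context
    color at the context size.
    """
    camera = camera or CameraState()
    settings = settings or RenderSettings()
    w, h = camera.viewport
    if w <= 0 or h <= 0:
        raise ValidationError("zero-size viewport")

    active = np.ones(state.gids.size, dtype=bool)
    if state.mode == "spike":
        active = state.life > 0.0
    gids = state.gids[active]
    life = state.life[active]
    if gids.size == 0:
        img = np.empty((h, w, 4))
        img[:] = settings.background
        return img

    pos = _positions_of(circuit, gids)
    x, y, depth, vis = project_points(camera, pos)
    gids, life = gids[vis], life[vis]
    x, y, depth = x[vis], y[vis], depth[vis]

    colors = tf(life)
    radii = sizef(life) / 2.0
    if settings.selection is not None:
        ctx = ~np.isin(gids, np.fromiter(settings.selection.gids, dtype=np.int64))
        colors[ctx] = settings.context_color
        radii[ctx] = settings.context_size / 2.0

    img = np.empty((h, w, 4))
    img[:] = settings.background

    if settings.blend == "traditional":
        order = np.lexsort((gids, -depth))  # far to near, gid breaks ties
    else:
        order = np.arange(gids.size)

    ys, xs = np.mgrid[0:h, 0:w]
    cx = xs + 0.5
    cy = ys + 0.5
    for i in order:
        r = radii[i]
        x0 = max(0, int(math.floor(x[i] - r - 1)))
        x1 = min(w, int(math.ceil(x[i] + r + 1)))
        y0 = max(0, int(math.floor(y[i] - r - 1)))
        y1 = min(h, int(math.ceil(y[i] + r + 1)))
        if x0 >= x1 or y0 >= y1:
            continue
        dx = cx[y0:y1, x0:x1] - x[i]
        dy = cy[y0:y1, x0:x1] - y[i]
        disk = dx * dx + dy * dy <= r * r
        if not disk.any():
            continue
        src = colors[i]
        tile = img[y0:y1, x0:x1]
        if settings.blend == "traditional":
            sa = src[3]
            tile[disk, :3] = src[:3] * sa + tile[disk, :3] * (1.0 - sa)
            tile[disk, 3] = sa + tile[disk, 3] * (1.0 - sa)
        else:
            tile[disk, :3] += src[:3] * src[3]
            tile[disk, 3] += src[3]
    if settings.blend == "accumulative":
        np.clip(img, 0.0, 1.0, out=img)
    return img


def to_image(frame: np.ndarray):
    """Convert a float RGBA frame to an 8-bit PIL image."""
    from PIL import Image

    arr = (np.clip(frame, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return Image.fromarray(arr, mode="RGBA")
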