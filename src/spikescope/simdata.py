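"""Domain types and plain-text readers/writers for circuit, spike and voltage data.

Three file dialects are supported, all UTF-8 text with '.' as the decimal
separator:

* **circuit CSV** — one row per neuron with the fixed header
  ``gid,x,y,z,layer,column,minicolumn,mtype,etype,<morphometrics...>``.
* **spike ASCII** — whitespace-separated ``time gid`` pairs, one event per
  line, ``#`` starts a comment (the NEST-style interchange layout). Times are
  milliseconds.
* **voltage CSV** — first row ``t_start,dt``, second row the comma-separated
  gid order, each following row one frame of per-neuron membrane values (mV).

Writers emit floats with ``repr``-shortest formatting so that write-then-read
reproduces integers bit-exactly and reals within 1e-9.

Time intervals are half-open ``[t_start, t_end)`` except for a report's final
instant, which is included; all ids are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MORPHOMETRIC_KEYS",
    "CIRCUIT_COLUMNS",
    "MTYPES",
    "ETYPES",
    "SimDataError",
    "ValidationError",
    "FormatError",
    "NeuronRecord",
    "SpikeReport",
    "VoltageReport",
    "Selection",
    "validate_circuit",
    "circuit_frame",
    "read_circuit",
    "write_circuit",
    "read_spikes",
    "write_spikes",
    "read_voltage",
    "write_voltage",
]

#: Morphometric attributes every circuit must carry, in file-column order.
MORPHOMETRIC_KEYS: tuple[str, ...] = (
    "soma_volume",
    "soma_surface",
    "dendritic_volume",
    "dendritic_surface",
    "axon_volume",
    "neuritic_surface",
    "dendritic_bifurcations",
)

CIRCUIT_COLUMNS: tuple[str, ...] = (
    "gid",
    "x",
    "y",
    "z",
    "layer",
    "column",
    "minicolumn",
    "mtype",
    "etype",
) + MORPHOMETRIC_KEYS

MTYPES = ("pyramidal", "interneuron")
ETYPES = ("excitatory", "inhibitory")

N_LAYERS = 6


class SimDataError(Exception):
    """Base class for data-layer errors."""


class ValidationError(SimDataError):
    """A well-formed file or object violates a domain invariant."""


class FormatError(SimDataError):
    """A file does not follow its dialect (bad token, missing column, ...)."""


@dataclass
class NeuronRecord:
    """One neuron: id, 3D position (µm), structural membership, types and
    morphometric scalars.

    ``morphometrics`` maps attribute name to a non-negative real; the keys in
    :data:`MORPHOMETRIC_KEYS` are required. ``dendritic_bifurcations`` is a
    non-negative integer count stored as a float.
    """

    gid: int
    position: tuple[float, float, float]
    layer: int
    column: int
    minicolumn: int
    mtype: str
    etype: str
    morphometrics: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.gid < 0:
            raise ValidationError(f"gid must be non-negative, got {self.gid}")
        if not 1 <= self.layer <= N_LAYERS:
            raise ValidationError(
                f"layer must be in 1..{N_LAYERS}, got {self.layer} (gid {self.gid})"
            )
        if self.column < 0 or self.minicolumn < 0:
            raise ValidationError(f"negative column/minicolumn id (gid {self.gid})")
        if self.mtype not in MTYPES:
            raise ValidationError(f"unknown mtype {self.mtype!r} (gid {self.gid})")
        if self.etype not in ETYPES:
            raise ValidationError(f"unknown etype {self.etype!r} (gid {self.gid})")
        for key in MORPHOMETRIC_KEYS:
            if key not in self.morphometrics:
                raise FormatError(f"missing morphometric {key!r} (gid {self.gid})")
            if self.morphometrics[key] < 0:
                raise ValidationError(
                    f"negative morphometric {key!r} (gid {self.gid})"
                )
        bif = self.morphometrics["dendritic_bifurcations"]
        if bif != int(bif):
            raise ValidationError(
                f"dendritic_bifurcations must be an integer, got {bif} (gid {self.gid})"
            )


def validate_circuit(records: Sequence[NeuronRecord]) -> None:
    """Check circuit-level invariants (per-record validity, unique gids)."""
    seen: set[int] = set()
    for rec in records:
        rec.validate()
        if rec.gid in seen:
            raise ValidationError(f"duplicate gid {rec.gid}")
        seen.add(rec.gid)


def circuit_frame(records: Sequence[NeuronRecord]) -> pd.DataFrame:
    """Tabular view of a circuit, one row per neuron, columns as in the CSV."""
    data = {
        "gid": np.fromiter((r.gid for r in records), dtype=np.int64, count=len(records)),
        "x": np.fromiter((r.position[0] for r in records), dtype=float, count=len(records)),
        "y": np.fromiter((r.position[1] for r in records), dtype=float, count=len(records)),
        "z": np.fromiter((r.position[2] for r in records), dtype=float, count=len(records)),
        "layer": np.fromiter((r.layer for r in records), dtype=np.int64, count=len(records)),
        "column": np.fromiter((r.column for r in records), dtype=np.int64, count=len(records)),
        "minicolumn": np.fromiter(
            (r.minicolumn for r in records), dtype=np.int64, count=len(records)
        ),
        "mtype": [r.mtype for r in records],
        "etype": [r.etype for r in records],
    }
    for key in MORPHOMETRIC_KEYS:
        data[key] = np.fromiter(
            (r.morphometrics[key] for r in records), dtype=float, count=len(records)
        )
    return pd.DataFrame(data, columns=list(CIRCUIT_COLUMNS))


@dataclass
class SpikeReport:
    """Sparse spiking activity: parallel time (ms) and gid arrays plus the
    report window ``[t_start, t_end]``.

    Events are kept sorted ascending by time with ties broken by gid.
    """

    times: np.ndarray
    gids: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gids = np.asarray(self.gids, dtype=np.int64)
        if self.times.shape != self.gids.shape:
            raise ValidationError("times and gids must have equal length")
        if self.t_end < self.t_start:
            raise ValidationError("t_end must be >= t_start")
        if self.times.size:
            if self.times.min() < self.t_start or self.times.max() > self.t_end:
                raise ValidationError("event time outside [t_start, t_end]")
            order = np.lexsort((self.gids, self.times))
            if not (np.all(np.diff(self.times) >= 0)
                    and np.array_equal(order, np.arange(self.times.size))):
                raise ValidationError("events not sorted by (time, gid)")

    @classmethod
    def from_events(
        cls,
        events: Iterable[tuple[float, int]],
        t_start: float,
        t_end: float,
    ) -> "SpikeReport":
        """Build a report from (time, gid) pairs in any order; sorts them."""
        ev = list(events)
        times = np.array([t for t, _ in ev], dtype=float)
        gids = np.array([g for _, g in ev], dtype=np.int64)
        order = np.lexsort((gids, times))
        return cls(times[order], gids[order], t_start, t_end)

    @property
    def events(self) -> list[tuple[float, int]]:
        return list(zip(self.times.tolist(), self.gids.tolist()))

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass
class VoltageReport:
    """Dense membrane-voltage traces: a frame-major matrix (one row per time
    step, one column per gid in ``gids`` order), sampled at
    ``t_start + k * dt`` milliseconds, values in mV."""

    t_start: float
    dt: float
    gids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if self.values.ndim != 2:
            raise FormatError("values must be a 2D frame-major matrix")
        if self.values.shape[0] < 1:
            raise ValidationError("voltage report needs at least one frame")
        if self.values.shape[1] != len(self.gids):
            raise ValidationError("value columns do not match declared gid order")
        if len(set(self.gids)) != len(self.gids):
            raise ValidationError("duplicate gid in voltage header")

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_frames)

    @property
    def t_end(self) -> float:
        return float(self.t_start + self.dt * (self.n_frames - 1))


@dataclass(frozen=True)
class Selection:
    """A named subset of neuron gids (the payload of the bus selection topic)."""

    name: str
    gids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("selection name must be non-empty")
        object.__setattr__(self, "gids", frozenset(int(g) for g in self.gids))


# ---------------------------------------------------------------------------
# circuit CSV


def read_circuit(path) -> list[NeuronRecord]:
    """Read and validate a circuit CSV; returns records in file order."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty circuit file") from exc
    for col in CIRCUIT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    records: list[NeuronRecord] = []
    seen: set[int] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            gid = int(getattr(row, "gid"))
            pos = (float(row.x), float(row.y), float(row.z))
            layer = int(row.layer)
            column = int(row.column)
            minicolumn = int(row.minicolumn)
            morph = {k: float(getattr(row, k)) for k in MORPHOMETRIC_KEYS}
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: bad numeric token ({exc})") from exc
        rec = NeuronRecord(gid, pos, layer, column, minicolumn, row.mtype, row.etype, morph)
        try:
            rec.validate()
        except SimDataError as exc:
            raise type(exc)(f"{path}: row {i}: {exc}") from exc
        if gid in seen:
            raise ValidationError(f"{path}: row {i}: duplicate gid {gid}")
        seen.add(gid)
        records.append(rec)
    return records


def _fmt(x: float) -> str:
    """repr-shortest float, but integers without a trailing '.0'."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def write_circuit(records: Sequence[NeuronRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CIRCUIT_COLUMNS) + "\n")
        for r in records:
            cells = [
                str(r.gid),
                _fmt(r.position[0]),
                _fmt(r.position[1]),
                _fmt(r.position[2]),
                str(r.layer),
                str(r.column),
                str(r.minicolumn),
                r.mtype,
                r.etype,
            ] + [_fmt(r.morphometrics[k]) for k in MORPHOMETRIC_KEYS]
            fh.write(",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# spike ASCII


def read_spikes(path, t_start: float, t_end: float) -> SpikeReport:
    """Read ``time gid`` lines, keep events in ``[t_start, t_end]``, sorted."""
    times: list[float] = []
    gids: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {ln}: expected 'time gid'")
            try:
                t = float(parts[0])
                g = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-numeric token") from exc
            if t < 0:
                raise ValidationError(f"{path}: line {ln}: negative spike time {t}")
            if g < 0:
                raise ValidationError(f"{path}: line {ln}: negative gid {g}")
            if t_start <= t <= t_end:
                times.append(t)
                gids.append(g)
    return SpikeReport.from_events(zip(times, gids), t_start, t_end)


def write_spikes(report: SpikeReport, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# t_start {_fmt(report.t_start)} t_end {_fmt(report.t_end)}\n")
        for t, g in zip(report.times, report.gids):
            fh.write(f"{_fmt(t)} {g}\n")


# ---------------------------------------------------------------------------
# voltage CSV


def read_voltage(path) -> VoltageReport:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: need header, gid row and at least one frame")
    try:
        t_start, dt = (float(tok) for tok in lines[0].split(","))
    except ValueError as exc:
        raise FormatError(f"{path}: line 1: expected 't_start,dt'") from exc
    try:
        gids = [int(tok) for tok in lines[1].split(",")]
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: bad gid token") from exc
    rows: list[list[float]] = []
    width = len(gids)
    for ln, line in enumerate(lines[2:], start=3):
        try:
            row = [float(tok) for tok in line.split(",")]
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln}: non-numeric token") from exc
        if len(row) != width:
            raise FormatError(
                f"{path}: line {ln}: ragged row ({len(row)} values, expected {width})"
            )
        rows.append(row)
    return VoltageReport(t_start=t_start, dt=dt, gids=gids, values=np.array(rows))


def write_voltage(report: VoltageReport, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{_fmt(report.t_start)},{_fmt(report.dt)}\n")
        fh.write(",".join(str(g) for g in report.gids) + "\n")
        for row in report.values:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
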