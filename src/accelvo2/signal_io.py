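"""Readers, validation and minute segmentation for recorded sessions.

A *session* couples three synchronously recorded streams for one
participant: a triaxial accelerometer log (nominally 50 Hz, units of g),
a gas-analyzer oxygen-uptake export (VO₂, weight-normalized to
mL·kg⁻¹·min⁻¹), and an annotation file marking the start/end of each
activity.  All timestamps are seconds relative to session start; the
accelerometer reader rebases absolute clock stamps by subtracting the
first stamp.

Gravity is deliberately not removed from the acceleration channels: the
downstream features operate on the raw, gravity-inclusive signal.  No
resampling is performed; irregular sampling is tolerated as long as the
median inter-sample gap stays within ±20% of the nominal period.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MinuteWindow

log = logging.getLogger(__name__)

GRAVITY_MS2 = 9.80665

#: Exact header of the Physics Toolbox accelerometer export dialect.
PHYSICS_TOOLBOX_COLUMNS = ("time", "gFx", "gFy", "gFz")
GENERIC_COLUMNS = ("t", "ax", "ay", "az")
ANNOTATION_COLUMNS = ("label", "type", "start_s", "end_s")

ACTIVITY_TYPES = ("Sedentary", "Housework", "Locomotion")


class DialectError(ValueError):
    """The file header does not match the declared reader dialect."""


class FormatError(ValueError):
    """The file parsed but violates a stream invariant (e.g. time order)."""


@dataclass
class AccelRecording:
    """Timestamped triaxial acceleration in g.

    ``time`` is seconds since session start, strictly increasing; the
    median inter-sample gap must lie within ±20% of ``1/nominal_rate``.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.time.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise FormatError("accelerometer channels must have equal lengths")
        if n < 2:
            raise FormatError("accelerometer recording needs at least 2 samples")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if self.time[0] < 0:
            raise FormatError("time must be non-negative")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise FormatError("time must be strictly increasing")
        med = float(np.median(dt))
        nominal = 1.0 / self.nominal_rate
        if not (0.8 * nominal <= med <= 1.2 * nominal):
            raise FormatError(
                f"median inter-sample gap {med:.6g}s deviates more than 20% "
                f"from nominal {nominal:.6g}s"
            )

    def __len__(self) -> int:
        return self.time.size


@dataclass
class Vo2Series:
    """Weight-normalized oxygen-uptake measurements (mL·kg⁻¹·min⁻¹)."""

    time: np.ndarray
    vo2: np.ndarray
    mass_kg: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.time.size != self.vo2.size:
            raise FormatError("vo2 and time must have equal lengths")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("vo2 time must be strictly increasing")
        if np.any(self.vo2 < 0):
            raise FormatError("vo2 must be non-negative")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class ActivityAnnotation:
    """One labelled activity interval, in session-relative seconds."""

    label: str
    type: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"annotation {self.label!r}: start must precede end")


@dataclass
class Session:
    """One participant's aligned accelerometer, VO₂ and annotation streams."""

    participant_id: str
    accel: AccelRecording
    vo2: Vo2Series
    annotations: list[ActivityAnnotation]

    def __post_init__(self) -> None:
        anns = sorted(self.annotations, key=lambda a: a.start)
        for prev, cur in zip(anns, anns[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"annotations {prev.label!r} and {cur.label!r} overlap"
                )
        # allow one nominal sample period of slack at the recording tail
        slack = 1.5 / self.accel.nominal_rate
        t_acc = (self.accel.time[0], self.accel.time[-1] + slack)
        t_vo2 = (self.vo2.time[0], self.vo2.time[-1])
        for a in anns:
            if a.start < t_acc[0] or a.end > t_acc[1]:
                raise ValueError(
                    f"annotation {a.label!r} [{a.start}, {a.end}] not covered "
                    f"by the accelerometer recording"
                )
            if a.start < t_vo2[0] or a.end > t_vo2[1]:
                raise ValueError(
                    f"annotation {a.label!r} [{a.start}, {a.end}] not covered "
                    f"by the VO2 series"
                )
        self.annotations = anns


# ---------------------------------------------------------------------------
# readers


def _read_table(path, expected: tuple[str, ...], dialect: str,
                delimiter: str = ",") -> pd.DataFrame:
    path = Path(path)
    # round_trip float parsing so 17-digit exports read back bit-exact
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    cols = tuple(str(c).strip() for c in df.columns)
    if cols != expected:
        raise DialectError(
            f"{path.name}: header {list(cols)} does not match the "
            f"{dialect!r} dialect {list(expected)}"
        )
    df.columns = cols
    n0 = len(df)
    for c in cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna()
    dropped = n0 - len(df)
    if dropped:
        log.warning("%s: dropped %d rows with unparseable numerics", path.name, dropped)
    return df


def read_accel(path, dialect: str = "physics_toolbox", nominal_rate: float = 50.0,
               delimiter: str = ",", sidecar=None) -> AccelRecording:
    """Read an accelerometer log into a validated :class:`AccelRecording`.

    Parameters
    ----------
    dialect
        ``physics_toolbox`` expects the header ``time,gFx,gFy,gFz`` with
        acceleration already in g.  ``generic`` expects ``t,ax,ay,az`` and a
        JSON sidecar (default ``<path>.json``) declaring ``{"units": "g"}``
        or ``{"units": "m/s^2"}`` and optionally ``rate_hz``.
    nominal_rate
        Expected sampling rate in Hz; the median inter-sample gap must be
        within ±20% of its period.

    Rows with unparseable numerics are dropped with a logged count.  Time
    is rebased so the first retained sample is t = 0; duplicate timestamps
    are de-duplicated (first kept) and any remaining non-monotonicity is a
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "physics_toolbox":
        df = _read_table(path, PHYSICS_TOOLBOX_COLUMNS, dialect, delimiter)
        t, x, y, z = (df[c].to_numpy(float) for c in PHYSICS_TOOLBOX_COLUMNS)
        scale = 1.0
    elif dialect == "generic":
        df = _read_table(path, GENERIC_COLUMNS, dialect, delimiter)
        t, x, y, z = (df[c].to_numpy(float) for c in GENERIC_COLUMNS)
        sidecar = Path(sidecar) if sidecar is not None else path.with_name(path.name + ".json")
        if not sidecar.exists():
            raise DialectError(f"generic dialect requires a units sidecar at {sidecar}")
        meta = json.loads(sidecar.read_text())
        units = meta.get("units", "g")
        if units in ("g",):
            scale = 1.0
        elif units in ("m/s^2", "m/s2", "ms-2"):
            scale = 1.0 / GRAVITY_MS2
        else:
            raise DialectError(f"unknown acceleration units {units!r} in {sidecar}")
        nominal_rate = float(meta.get("rate_hz", nominal_rate))
    else:
        raise DialectError(f"unknown accelerometer dialect {dialect!r}")

    if t.size == 0:
        raise FormatError(f"{path.name}: no parseable samples")
    t = t - t[0]
    keep = np.concatenate(([True], np.diff(t) != 0))
    if not keep.all():
        log.warning("%s: dropped %d duplicate timestamps", path.name, int((~keep).sum()))
    t, x, y, z = t[keep], x[keep], y[keep], z[keep]
    if np.any(np.diff(t) < 0):
        raise FormatError(f"{path.name}: time is not monotonic after de-duplication")
    return AccelRecording(time=t, x=x * scale, y=y * scale, z=z * scale,
                          nominal_rate=nominal_rate)


def read_vo2(path, mass_kg: float, already_normalized: bool = False,
             delimiter: str = ",", t0: float = 0.0) -> Vo2Series:
    """Read a gas-analyzer VO₂ export (columns ``time,vo2``).

    If ``already_normalized`` is false, ``vo2`` is absolute uptake in
    mL·min⁻¹ and is divided by ``mass_kg``; otherwise values pass through
    unchanged as mL·kg⁻¹·min⁻¹.  ``t0`` (seconds) is subtracted from the
    time column for files stamped with absolute clock time.
    """
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    df = _read_table(Path(path), ("time", "vo2"), "vo2", delimiter)
    t = df["time"].to_numpy(float) - t0
    v = df["vo2"].to_numpy(float)
    if not already_normalized:
        v = v / mass_kg
    return Vo2Series(time=t, vo2=v, mass_kg=mass_kg)


def read_annotations(path, delimiter: str = ",") -> list[ActivityAnnotation]:
    """Read an activity annotation file (columns ``label,type,start_s,end_s``)."""
    df = pd.read_csv(Path(path), sep=delimiter)
    cols = tuple(str(c).strip() for c in df.columns)
    if cols != ANNOTATION_COLUMNS:
        raise DialectError(
            f"annotation header {list(cols)} != {list(ANNOTATION_COLUMNS)}"
        )
    return [
        ActivityAnnotation(label=str(r.label), type=str(r.type),
                           start=float(r.start_s), end=float(r.end_s))
        for r in df.itertuples()
    ]


def read_session(directory, dialect: str = "physics_toolbox") -> Session:
    """Read a session bundle directory (``accel.csv``, ``vo2.csv``,
    ``annotations.csv``, ``meta.json``) written by
    :func:`accelvo2.synthetic.write_session`."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    accel = read_accel(d / "accel.csv", dialect=dialect,
                       nominal_rate=float(meta["nominal_rate"]))
    vo2 = read_vo2(d / "vo2.csv", mass_kg=float(meta["mass_kg"]),
                   already_normalized=bool(meta.get("already_normalized", True)))
    anns = read_annotations(d / "annotations.csv")
    return Session(participant_id=str(meta["participant_id"]), accel=accel,
                   vo2=vo2, annotations=anns)


# ---------------------------------------------------------------------------
# derived series and segmentation


def resultant_vector(rec: AccelRecording) -> np.ndarray:
    """Per-sample Euclidean norm √(x² + y² + z²) of the three axes, in g."""
    return np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)


def segment_minutes(session: Session, window_s: float = 60.0) -> list[MinuteWindow]:
    """Cut each annotated activity into consecutive non-overlapping windows.

    Windows are anchored at each annotation's start; a trailing partial
    window is discarded, so an activity of duration d yields ⌊d/window_s⌋
    windows.  Each window carries the four channels (x, y, z and the
    resultant vector), the activity label/type, and the minute VO₂ value —
    the arithmetic mean of all VO₂ measurements with time in
    [window start, window end).  Windows with no VO₂ measurement, or with
    fewer than 4 accelerometer samples, are dropped with a logged warning.
    """
    acc = session.accel
    rv = resultant_vector(acc)
    out: list[MinuteWindow] = []
    for ann in session.annotations:
        n_win = int(math.floor((ann.end - ann.start) / window_s + 1e-9))
        for i in range(n_win):
            w0 = ann.start + i * window_s
            w1 = ann.start + (i + 1) * window_s
            i0, i1 = np.searchsorted(acc.time, [w0, w1], side="left")
            if i1 - i0 < 4:
                log.warning(
                    "window %s@%gs: only %d accelerometer samples, dropped",
                    ann.label, w0, i1 - i0,
                )
                continue
            j0, j1 = np.searchsorted(session.vo2.time, [w0, w1], side="left")
            if j1 == j0:
                log.warning("window %s@%gs: no VO2 measurements, dropped", ann.label, w0)
                continue
            out.append(MinuteWindow(
                x=acc.x[i0:i1], y=acc.y[i0:i1], z=acc.z[i0:i1], rv=rv[i0:i1],
                label=ann.label, type=ann.type,
                vo2=float(np.mean(session.vo2.vo2[j0:j1])),
                participant_id=session.participant_id, start_s=w0,
            ))
    return out
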