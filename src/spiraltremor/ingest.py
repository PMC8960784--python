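"""Reading and segmenting pen-tablet and accelerometer recordings.

A spiral-drawing session consists of a digital-tablet pen stream (time, x, y,
pen-tip pressure) and one triaxial accelerometer stream per sensor site on the
dominant arm: hand dorsum (S1), mid-forearm (S2) and upper arm (S3).  Pen-tip
pressure separates movement on the tablet from movement above it: samples with
pressure > 0 are "pen-down", samples with pressure = 0 are "pen-up".  The task
window runs from the first to the last pen-down sample, and the task-time
feature T is the total pen-down duration (pen-up gaps inside the task are
excluded from T but not from the accelerometer segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DataError,
    NoPenDownError,
    SchemaError,
    TooShortError,
)

logger = logging.getLogger(__name__)

SITES = ("S1", "S2", "S3")
GROUP_LABELS = ("control", "ET0", "ET1plus", "ET2plus")

#: Nominal accelerometer sampling rate of the acquisition hardware, Hz.
NOMINAL_FS_ACCEL = 148.1

#: Minimum accelerometer segment length (s) for a usable spectral estimate.
MIN_SEGMENT_S = 2.0


def _estimate_fs(t: np.ndarray) -> float:
    """Sampling rate as the reciprocal of the median timestamp increment."""
    dt = np.diff(t)
    if dt.size == 0:
        raise DataError("cannot estimate sampling rate from a single sample")
    return 1.0 / float(np.median(dt))


def _check_monotone(t: np.ndarray, what: str) -> None:
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{what}: timestamps must be strictly increasing")


@dataclass
class AccelTrace:
    """Timestamped triaxial acceleration stream from one sensor site.

    Units are whatever the recording used (g or m/s^2); the band-power ratio
    downstream is scale invariant so the choice does not matter.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    site: str = "S2"
    fs: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if any(a.size != n for a in (self.ax, self.ay, self.az)):
            raise DataError("accelerometer columns must have equal length")
        if n < 2:
            raise DataError("accelerometer trace needs at least 2 samples")
        _check_monotone(self.t, "accelerometer")
        if self.fs is None:
            self.fs = _estimate_fs(self.t)
        # flag (but tolerate) dropped packets: gaps beyond 3 sample periods
        max_gap = float(np.max(np.diff(self.t)))
        if max_gap > 3.0 / self.fs:
            logger.warning(
                "accelerometer trace (site %s) has a %.3f s gap (> 3/fs)",
                self.site,
                max_gap,
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ax": self.ax, "ay": self.ay, "az": self.az})


@dataclass
class PenTrace:
    """Timestamped tablet stream: position (mm or device units) + pen pressure."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    fs: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        n = self.t.size
        if any(a.size != n for a in (self.x, self.y, self.pressure)):
            raise DataError("pen columns must have equal length")
        if n < 2:
            raise DataError("pen trace needs at least 2 samples")
        _check_monotone(self.t, "pen")
        if np.any(self.pressure < 0):
            raise DataError("pen pressure must be non-negative")
        if self.fs is None:
            self.fs = _estimate_fs(self.t)

    def __len__(self) -> int:
        return self.t.size

    @property
    def pen_down(self) -> np.ndarray:
        """Boolean mask of pen-down samples (pressure > 0)."""
        return self.pressure > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "pressure": self.pressure}
        )


@dataclass(frozen=True)
class TaskWindow:
    """Task delimitation derived from the pen stream.

    ``pen_down_duration`` is the feature T: the summed duration of pen-down
    samples, which excludes pen-up gaps inside the task.  The window
    [t_start, t_end] spans first to last pen-down sample and is what the
    accelerometer is sliced to.
    """

    t_start: float
    t_end: float
    pen_down_duration: float

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise DataError("task window has t_end < t_start")
        if self.pen_down_duration <= 0:
            raise DataError("pen_down_duration must be positive")


@dataclass(frozen=True)
class Stroke:
    """A maximal run of pen-up or pen-down samples; indices are inclusive."""

    kind: str  # "pen_up" | "pen_down"
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ClinicalRecord:
    """Clinical labels for one subject; controls carry no FTM score."""

    subject_id: str
    group_label: str
    ftm_rater1: float | None = None
    ftm_rater2: float | None = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise DataError(
                f"unknown group label {self.group_label!r}; expected one of {GROUP_LABELS}"
            )
        for v in (self.ftm_rater1, self.ftm_rater2):
            if v is not None and v < 0:
                raise DataError("FTM scores must be non-negative")

    @property
    def ftm_mean(self) -> float | None:
        if self.ftm_rater1 is None or self.ftm_rater2 is None:
            return None
        return 0.5 * (self.ftm_rater1 + self.ftm_rater2)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_ACCEL_COLUMNS = ("t", "ax", "ay", "az")
_PEN_COLUMNS = ("t", "x", "y", "pressure")


def _read_csv(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{what} file is empty: {path}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} missing columns {missing}")
    if len(df) < 2:
        raise SchemaError(f"{what} file {path} has fewer than 2 data rows")
    return df


def read_accel_csv(
    path: str | Path,
    site: str = "S2",
    nominal_fs: float = NOMINAL_FS_ACCEL,
    fs_tolerance: float = 0.05,
) -> AccelTrace:
    """Read one accelerometer CSV (columns t, ax, ay, az; any order).

    The sampling rate is estimated as 1/median(dt) and checked against the
    nominal rate; a deviation beyond ``fs_tolerance`` (relative) is logged
    and the estimated rate is used.
    """
    df = _read_csv(path, _ACCEL_COLUMNS, "accelerometer")
    trace = AccelTrace(
        t=df["t"].to_numpy(),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        site=site,
    )
    assert trace.fs is not None
    if nominal_fs > 0 and abs(trace.fs - nominal_fs) / nominal_fs > fs_tolerance:
        logger.warning(
            "%s: estimated fs %.2f Hz deviates > %.0f%% from nominal %.1f Hz; "
            "using estimate",
            path,
            trace.fs,
            100 * fs_tolerance,
            nominal_fs,
        )
    return trace


def read_pen_csv(path: str | Path) -> PenTrace:
    """Read a pen-tablet CSV (columns t, x, y, pressure; any order)."""
    df = _read_csv(path, _PEN_COLUMNS, "pen")
    return PenTrace(
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        pressure=df["pressure"].to_numpy(),
    )


_FLOAT_FMT = "%.10g"


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_pen_csv(trace: PenTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Read the cohort clinical table (subject_id, group, ftm_rater1, ftm_rater2)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"clinical file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical file {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        r1 = getattr(row, "ftm_rater1", None)
        r2 = getattr(row, "ftm_rater2", None)
        records.append(
            ClinicalRecord(
                subject_id=str(row.subject_id),
                group_label=str(row.group),
                ftm_rater1=None if r1 is None or pd.isna(r1) else float(r1),
                ftm_rater2=None if r2 is None or pd.isna(r2) else float(r2),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Stroke labelling and task segmentation
# ---------------------------------------------------------------------------


def label_strokes(pen: PenTrace) -> list[Stroke]:
    """Partition the pen trace into maximal pen-up / pen-down runs.

    Returns strokes in temporal order; their lengths always sum to the trace
    length.
    """
    down = pen.pen_down.astype(int)
    boundaries = np.flatnonzero(np.diff(down)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries - 1, [len(pen) - 1]))
    return [
        Stroke("pen_down" if down[s] else "pen_up", int(s), int(e))
        for s, e in zip(starts, ends)
    ]


def segment_task(pen: PenTrace, min_stroke_duration: float = 0.0) -> TaskWindow:
    """Delimit the drawing task from pen pressure and compute task time T.

    T = (number of pen-down samples) / fs_pen.  ``min_stroke_duration`` (s),
    when positive, drops pen-down runs shorter than that duration before
    segmenting — a chatter guard for real sensors, off by default.
    """
    down = pen.pen_down.copy()
    if min_stroke_duration > 0:
        assert pen.fs is not None
        min_len = int(np.ceil(min_stroke_duration * pen.fs))
        for stroke in label_strokes(pen):
            if stroke.kind == "pen_down" and len(stroke) < min_len:
                down[stroke.start : stroke.end + 1] = False
    idx = np.flatnonzero(down)
    if idx.size == 0:
        raise NoPenDownError("pen trace contains no pen-down sample")
    assert pen.fs is not None
    return TaskWindow(
        t_start=float(pen.t[idx[0]]),
        t_end=float(pen.t[idx[-1]]),
        pen_down_duration=idx.size / pen.fs,
    )


def slice_accel(
    accel: AccelTrace,
    window: TaskWindow,
    clock_offset: float = 0.0,
    min_duration: float = MIN_SEGMENT_S,
) -> AccelTrace:
    """Slice an accelerometer trace to the closed task window [t_start, t_end].

    ``clock_offset`` is the accelerometer-minus-pen clock difference in
    seconds (default 0: shared clock); it is subtracted from the
    accelerometer timestamps before comparison.  Boundary samples are
    included iff their (aligned) time lies within the closed interval.
    """
    t_aligned = accel.t - clock_offset
    mask = (t_aligned >= window.t_start) & (t_aligned <= window.t_end)
    if not mask.any():
        raise AlignmentError(
            "task window does not overlap the accelerometer trace; "
            "check the clock offset"
        )
    sliced = AccelTrace(
        t=accel.t[mask],
        ax=accel.ax[mask],
        ay=accel.ay[mask],
        az=accel.az[mask],
        site=accel.site,
        fs=accel.fs,
    )
    if sliced.duration < min_duration:
        raise TooShortError(
            f"accelerometer segment of {sliced.duration:.2f} s is shorter than "
            f"{min_duration:.1f} s; spectral estimate would be unreliable"
        )
    return sliced
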