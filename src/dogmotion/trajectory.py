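"""Single-animal track model: delimited-text I/O, calibration, QC, windowing.

A :class:`Trajectory` is the substrate of every movement metric: per-frame
planar positions of one subject with timestamps and a per-frame validity
flag (the tracker either produced a confident detection that frame or it
did not).  Positions start in pixels and are converted to centimetres with
a per-recording-site calibration before any metric is computed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Union

import numpy as np
import pandas as pd

__all__ = [
    "TrackSample",
    "Trajectory",
    "CalibrationSpec",
    "SubjectMeta",
    "TrackParseError",
    "EmptyTrackError",
    "read_track",
    "read_metadata",
    "write_metadata",
    "calibrate",
    "window",
    "missing_fraction",
    "qc_pass",
    "fill_gaps",
    "resample",
]

TRACK_COLUMNS = ["frame", "time", "x", "y", "confidence"]
META_COLUMNS = ["subject_id", "group", "sex", "age", "weight", "neutered"]

#: Per-frame detection confidence below which a sample is treated as missing.
DEFAULT_CONFIDENCE_THRESHOLD = 0.5

#: Frames that are missing in more than this fraction fail quality control.
DEFAULT_QC_THRESHOLD = 0.30


class TrackParseError(ValueError):
    """A track file row could not be interpreted."""


class EmptyTrackError(ValueError):
    """An operation was asked to produce or consume a track with no samples."""


@dataclass(frozen=True)
class TrackSample:
    frame_index: int
    time: float
    x: float
    y: float
    valid: bool


@dataclass(frozen=True)
class Trajectory:
    """Ordered per-frame positions of one subject.

    Arrays are aligned and sorted by frame index; ``units`` is ``"px"``
    before calibration and ``"cm"`` after.  Invalid samples keep whatever
    x/y the file carried (possibly NaN) and are excluded from all metrics.
    """

    frames: np.ndarray
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    frame_rate: float
    units: str = "cm"
    site_id: str = ""

    def __post_init__(self):
        n = len(self.frames)
        for name in ("times", "x", "y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory arrays must be aligned")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.units not in ("px", "cm"):
            raise ValueError(f"unknown units {self.units!r}")
        if n > 1:
            if np.any(np.diff(self.frames) <= 0):
                dup = int(self.frames[np.flatnonzero(np.diff(self.frames) <= 0)[0] + 1])
                raise ValueError(f"duplicate or unsorted frame index {dup}")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("time must strictly increase with frame index")
        if np.any(~np.isfinite(self.x[self.valid])) or np.any(~np.isfinite(self.y[self.valid])):
            raise ValueError("valid samples must have finite positions")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[TrackSample]:
        for i in range(len(self)):
            yield TrackSample(
                int(self.frames[i]), float(self.times[i]),
                float(self.x[i]), float(self.y[i]), bool(self.valid[i]),
            )

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_positions(self) -> np.ndarray:
        """(n, 2) array of the valid positions, in track units."""
        return np.column_stack([self.x[self.valid], self.y[self.valid]])

    def valid_times(self) -> np.ndarray:
        return self.times[self.valid]

    @property
    def duration(self) -> float:
        """Elapsed time (s) between first and last valid sample."""
        t = self.valid_times()
        return float(t[-1] - t[0]) if len(t) >= 2 else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time": self.times,
                "x": self.x,
                "y": self.y,
                "confidence": np.where(self.valid, 1.0, 0.0),
            }
        )


@dataclass(frozen=True)
class CalibrationSpec:
    """Pixel-to-centimetre conversion for one recording site."""

    scale: float  # cm per pixel
    site_id: str = ""
    room_width: float = 300.0  # cm
    room_height: float = 160.0  # cm

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0 cm/px")
        if self.room_width <= 0 or self.room_height <= 0:
            raise ValueError("room dimensions must be > 0")


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics of one subject; drives normalization and group tests."""

    subject_id: str
    group: str  # "H" (case) or "C" (control)
    sex: str  # "m" / "f"
    age: float  # years
    weight: float  # kg
    neutered: bool

    def __post_init__(self):
        if self.group not in ("H", "C"):
            raise ValueError(f"group must be 'H' or 'C', got {self.group!r}")
        if self.sex not in ("m", "f"):
            raise ValueError(f"sex must be 'm' or 'f', got {self.sex!r}")
        if self.weight <= 0:
            raise ValueError("weight must be > 0 kg")
        if self.age <= 0:
            raise ValueError("age must be > 0 years")


def read_track(
    source: Union[str, io.IOBase],
    frame_rate: float,
    units: str = "px",
    site_id: str = "",
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> Trajectory:
    """Read a track from delimited text with header frame,time,x,y,confidence.

    Rows whose confidence falls below ``confidence_threshold`` or whose x/y
    fields are blank are kept but flagged invalid.  Rows are sorted by frame
    index; a duplicated frame index or an unparseable field is an error
    naming the offending frame or line.
    """
    try:
        df = pd.read_csv(source, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyTrackError("track file is empty") from None
    missing_cols = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrackParseError(f"track file missing columns: {missing_cols}")
    if len(df) == 0:
        raise EmptyTrackError("track file has a header but no rows")

    def numeric(col: str, required: bool) -> np.ndarray:
        raw = df[col].str.strip() if df[col].dtype == object else df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        blank = raw.isna() | (raw == "")
        bad = vals.isna() & ~blank
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise TrackParseError(f"line {line}: cannot parse {col}={raw[bad.idxmax()]!r}")
        if required and blank.any():
            line = int(blank.idxmax()) + 2
            raise TrackParseError(f"line {line}: missing required field {col!r}")
        return vals.to_numpy(dtype=float)

    frames = numeric("frame", required=True)
    times = numeric("time", required=True)
    x = numeric("x", required=False)
    y = numeric("y", required=False)
    conf = numeric("confidence", required=False)
    conf = np.nan_to_num(conf, nan=0.0)

    order = np.argsort(frames, kind="stable")
    frames, times, x, y, conf = (a[order] for a in (frames, times, x, y, conf))
    if len(frames) > 1 and np.any(np.diff(frames) == 0):
        dup = int(frames[np.flatnonzero(np.diff(frames) == 0)[0]])
        raise TrackParseError(f"duplicated frame index {dup}")

    valid = (conf >= confidence_threshold) & np.isfinite(x) & np.isfinite(y)
    return Trajectory(
        frames=frames.astype(int), times=times, x=x, y=y, valid=valid,
        frame_rate=frame_rate, units=units, site_id=site_id,
    )


def read_metadata(source: Union[str, io.IOBase]) -> list[SubjectMeta]:
    """Read the subject metadata table (one row per subject)."""
    df = pd.read_csv(source, dtype=str, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"metadata file missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectMeta(
                subject_id=row["subject_id"],
                group=row["group"].strip().upper(),
                sex=row["sex"].strip().lower(),
                age=float(row["age"]),
                weight=float(row["weight"]),
                neutered=row["neutered"].strip().lower() in ("y", "yes", "true", "1"),
            )
        )
    return out


def write_metadata(metas: list[SubjectMeta], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id, "group": m.group, "sex": m.sex,
                "age": m.age, "weight": m.weight,
                "neutered": "y" if m.neutered else "n",
            }
            for m in metas
        ],
        columns=META_COLUMNS,
    )
    df.to_csv(path, index=False)


def calibrate(traj: Trajectory, cal: CalibrationSpec) -> Trajectory:
    """Convert pixel positions to centimetres with the site's scale."""
    if traj.units != "px":
        raise ValueError(f"trajectory already in {traj.units}; calibrate expects px")
    if traj.site_id and cal.site_id and traj.site_id != cal.site_id:
        raise ValueError(f"calibration site {cal.site_id!r} != track site {traj.site_id!r}")
    return replace(traj, x=traj.x * cal.scale, y=traj.y * cal.scale, units="cm")


def window(traj: Trajectory, start: float = 0.0, duration: float = 180.0) -> Trajectory:
    """Restrict the track to the half-open time window [start, start+duration).

    The default is the first three minutes of the recording, the analysis
    window applied to every consultation.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    mask = (traj.times >= start) & (traj.times < start + duration)
    if not mask.any():
        raise EmptyTrackError(f"no samples in window [{start}, {start + duration})")
    return replace(
        traj,
        frames=traj.frames[mask], times=traj.times[mask],
        x=traj.x[mask], y=traj.y[mask], valid=traj.valid[mask],
    )


def missing_fraction(traj: Trajectory) -> float:
    """Fraction of frames in which the subject was not confidently tracked."""
    if len(traj) == 0:
        raise EmptyTrackError("missing_fraction of an empty track")
    return float((~traj.valid).sum()) / len(traj)


def qc_pass(traj: Trajectory, threshold: float = DEFAULT_QC_THRESHOLD) -> bool:
    """True iff the missing fraction does not exceed the threshold.

    The exclusion rule is strictly "more than" the threshold, so a track
    missing exactly 30% of frames still passes at the default.
    """
    return missing_fraction(traj) <= threshold + 1e-12


def fill_gaps(traj: Trajectory, max_gap: int | None = None) -> Trajectory:
    """Linearly interpolate short runs of invalid frames.

    Runs of at most ``max_gap`` consecutive invalid samples (default: two
    seconds' worth of frames) are replaced by linear interpolation in time
    between the flanking valid positions and marked valid.  Longer runs are
    left invalid.  Leading and trailing invalid runs, which have no flank to
    interpolate from, are dropped.  Originally valid samples are untouched.
    """
    if traj.n_valid == 0:
        raise EmptyTrackError("fill_gaps: track has no valid samples")
    if max_gap is None:
        max_gap = int(round(2.0 * traj.frame_rate))
    valid_idx = np.flatnonzero(traj.valid)
    lo, hi = valid_idx[0], valid_idx[-1]
    frames = traj.frames[lo : hi + 1]
    times = traj.times[lo : hi + 1]
    x = traj.x[lo : hi + 1].copy()
    y = traj.y[lo : hi + 1].copy()
    valid = traj.valid[lo : hi + 1].copy()

    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        if j - i <= max_gap:  # flanked run: i-1 and j are valid by construction
            t0, t1 = times[i - 1], times[j]
            w = (times[i:j] - t0) / (t1 - t0)
            x[i:j] = x[i - 1] + w * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + w * (y[j] - y[i - 1])
            valid[i:j] = True
        i = j
    return replace(traj, frames=frames, times=times, x=x, y=y, valid=valid)


def resample(traj: Trajectory, target_rate: float = 5.0) -> Trajectory:
    """Linearly interpolate positions onto a uniform grid at ``target_rate``.

    Resampling to a few Hz before computing turning angles keeps the angle
    distribution a property of locomotion rather than of frame-to-frame
    tracker jitter.  Only the span between the first and last valid sample
    is covered; remaining interior invalid samples are interpolated across.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if target_rate > traj.frame_rate:
        raise ValueError("target_rate must not exceed the native frame rate")
    t = traj.valid_times()
    if len(t) < 2:
        raise EmptyTrackError("resample: need at least 2 valid samples")
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * target_rate)) + 1) / target_rate
    xs = np.interp(grid, t, traj.x[traj.valid])
    ys = np.interp(grid, t, traj.y[traj.valid])
    return Trajectory(
        frames=np.arange(len(grid)), times=grid, x=xs, y=ys,
        valid=np.ones(len(grid), dtype=bool),
        frame_rate=target_rate, units=traj.units, site_id=traj.site_id,
    )
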