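"""The twelve movement parameters computed per subject.

Each metric consumes a calibrated, windowed, gap-filled, resampled
:class:`~dogmotion.trajectory.Trajectory` and returns a scalar.  Beyond the
basic distance and average speed (and their weight-normalized variants),
the set comprises the classic animal-movement indices — intensity of use,
straightness, sinuosity, mean squared displacement, fractal dimension —
plus two descriptors of erratic movement: turn counts binned by sharpness
and the number of vertices surviving polyline simplification.

A metric that is undefined for a given track (e.g. intensity of use when
the animal never left a line, so the hull is degenerate) raises
:class:`UndefinedMetric`; :func:`compute_all` converts that into a NaN
carrying an explicit flag, never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .geometry import (
    TurnCounts,
    bin_turns,
    count_points,
    hull_area,
    path_length,
    turning_angles,
)
from .trajectory import SubjectMeta, Trajectory

__all__ = [
    "UndefinedMetric",
    "MetricParams",
    "MetricVector",
    "FractalDimension",
    "total_distance",
    "normalize_by_weight",
    "average_speed",
    "intensity_of_use",
    "straightness",
    "msd_rate",
    "sinuosity",
    "fractal_dimension",
    "compute_all",
]


class UndefinedMetric(ValueError):
    """The metric has no defined value for this track (e.g. degenerate hull)."""


@dataclass(frozen=True)
class MetricParams:
    """Tunable constants of the metric layer.

    rdp_epsilon : cm
        Simplification tolerance for the approximation-point count.
    min_step : cm
        Displacements shorter than this are merged before turning angles
        are measured, so sub-centimetre tracker noise is not counted as
        turning.
    sinuosity_mode : {"benhamou", "ratio"}
        "ratio" is the literal path-length / net-displacement definition
        (>= 1); "benhamou" is the corrected sinuosity built from mean step
        length and the mean cosine of turning angles, and is the default
        because it remains defined for closed paths and lives on the scale
        the cohort summaries use.
    fd_min_scale : cm / fd_n_scales
        Geometric ladder of box sizes for the fractal-dimension estimate,
        from ``fd_min_scale`` up to a quarter of the hull diameter.
    """

    rdp_epsilon: float = 5.0
    min_step: float = 2.0
    sinuosity_mode: str = "benhamou"
    fd_min_scale: float = 2.0
    fd_n_scales: int = 8

    def __post_init__(self):
        if self.sinuosity_mode not in ("benhamou", "ratio"):
            raise ValueError(f"unknown sinuosity mode {self.sinuosity_mode!r}")
        if self.rdp_epsilon < 0 or self.min_step < 0 or self.fd_min_scale <= 0:
            raise ValueError("geometric tolerances must be non-negative")


class FractalDimension(NamedTuple):
    value: float  # clamped to [1, 2]
    raw: float  # unclamped regression slope


@dataclass(frozen=True)
class MetricVector:
    """All movement parameters for one subject, plus normalized variants.

    Undefined metrics are NaN and named in ``flags``.
    """

    subject_id: str
    group: str
    distance: float  # cm
    n_distance: float  # cm/kg
    average_speed: float  # cm/s
    n_average_speed: float  # cm/(s*kg)
    turns: TurnCounts
    iu: float  # dimensionless
    number_of_points: int
    st: float  # in [0, 1]
    msd_rate: float  # cm^2/s
    si: float  # mode-dependent
    fd: float  # clamped to [1, 2]
    fd_raw: float
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        """Flat mapping for the per-cohort metrics table."""
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "distance": self.distance,
            "n_distance": self.n_distance,
            "average_speed": self.average_speed,
            "n_average_speed": self.n_average_speed,
            "turn30_60": self.turns.t30_60,
            "turn60_90": self.turns.t60_90,
            "turn90_120": self.turns.t90_120,
            "turn120": self.turns.t120,
            "turn_total": self.turns.total,
            "iu": self.iu,
            "number_of_points": self.number_of_points,
            "st": self.st,
            "msd_rate": self.msd_rate,
            "si": self.si,
            "fd": self.fd,
            "fd_raw": self.fd_raw,
            "flags": ";".join(self.flags),
        }


def _positions(traj: Trajectory) -> np.ndarray:
    pts = traj.valid_positions()
    if len(pts) == 0:
        raise UndefinedMetric("track has no valid samples")
    return pts


def total_distance(traj: Trajectory) -> float:
    """Total path length over the valid positions (cm)."""
    return path_length(_positions(traj))


def normalize_by_weight(value: float, weight: float) -> float:
    """Divide a size-sensitive parameter by body weight (kg).

    Larger dogs cover more absolute distance by virtue of their size alone;
    dividing distance and speed by weight is the approximate correction
    applied before group comparison.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0 kg")
    return value / weight


def average_speed(traj: Trajectory) -> float:
    """Path length divided by elapsed tracked time (cm/s)."""
    dur = traj.duration
    if dur <= 0:
        raise UndefinedMetric("average_speed needs positive tracked duration")
    return total_distance(traj) / dur


def intensity_of_use(traj: Trajectory) -> float:
    """Path length over the square root of the area of movement.

    The area of movement is the convex hull of the visited positions; the
    ratio is scale-invariant and indexes how intensively the covered area
    was traversed.
    """
    hull = hull_area(_positions(traj))
    if hull.degenerate:
        raise UndefinedMetric("intensity_of_use: degenerate movement area")
    return total_distance(traj) / math.sqrt(hull.area)


def straightness(traj: Trajectory) -> float:
    """Net displacement over total path length, in [0, 1]."""
    pts = _positions(traj)
    total = path_length(pts)
    if total <= 0:
        raise UndefinedMetric("straightness: zero total path length")
    net = float(np.hypot(*(pts[-1] - pts[0])))
    return net / total


def msd_rate(traj: Trajectory) -> float:
    """Mean squared displacement from the starting position, per unit time.

    The reference position is the first valid position; the mean of
    ||r_i - r_0||^2 over all later samples is divided by the tracked
    duration so the result is a rate (cm^2/s).
    """
    pts = _positions(traj)
    dur = traj.duration
    if len(pts) < 2 or dur <= 0:
        raise UndefinedMetric("msd_rate needs >= 2 valid samples over positive time")
    sq = np.sum((pts[1:] - pts[0]) ** 2, axis=1)
    return float(sq.mean()) / dur


def sinuosity(traj: Trajectory, mode: str = "benhamou", min_step: float = 2.0) -> float:
    """Tortuosity of the path.

    ``ratio`` mode is total path length divided by net displacement
    (the reciprocal of straightness, >= 1, undefined for closed paths).
    ``benhamou`` mode is the corrected sinuosity
    ``2 * [p * (1 + c) / (1 - c)]**(-1/2)`` with ``p`` the mean retained
    step length (cm) and ``c`` the mean cosine of the turning angles; it
    tends to 0 for straight paths and grows with tortuosity per unit
    step length.
    """
    pts = _positions(traj)
    if mode == "ratio":
        total = path_length(pts)
        net = float(np.hypot(*(pts[-1] - pts[0])))
        if net <= 0:
            raise UndefinedMetric("ratio sinuosity: zero net displacement")
        return total / net
    if mode != "benhamou":
        raise ValueError(f"unknown sinuosity mode {mode!r}")
    angles = turning_angles(pts, min_step=min_step)
    if angles.size == 0:
        raise UndefinedMetric("benhamou sinuosity: fewer than 3 retained steps")
    # mean retained step length: same merge rule as the angle construction
    retained = [pts[0]]
    for p in pts[1:]:
        d = float(np.hypot(*(p - retained[-1])))
        if d >= min_step and d > 0.0:
            retained.append(p)
    steps = np.hypot(*np.diff(np.asarray(retained), axis=0).T)
    p_mean = float(steps.mean())
    c = float(np.cos(np.radians(angles)).mean())
    if c >= 1.0:
        return 0.0
    return 2.0 / math.sqrt(p_mean * (1.0 + c) / (1.0 - c))


def fractal_dimension(
    traj: Trajectory, min_scale: float = 2.0, n_scales: int = 8
) -> FractalDimension:
    """Box-counting fractal dimension of the path, between 1 and 2.

    Square grids at a geometric ladder of box sizes (``n_scales`` scales
    from ``min_scale`` cm up to a quarter of the hull diameter) are overlaid
    on the path; the negative slope of log N(s) against log s estimates the
    space-filling capacity: ~1 for a straight transit, approaching 2 for a
    dense confined wander.  Segments are densified before counting so a
    sparsely sampled straight line still fills its boxes.
    """
    pts = _positions(traj)
    if len(pts) < 10:
        raise UndefinedMetric("fractal_dimension needs >= 10 valid samples")
    lo = pts.min(axis=0)
    diam = float(np.hypot(*(pts.max(axis=0) - lo)))
    max_scale = diam / 4.0
    if max_scale <= min_scale:
        raise UndefinedMetric("fractal_dimension: path extent too small for the scale ladder")
    scales = np.geomspace(min_scale, max_scale, n_scales)
    if len(scales) < 3:
        raise UndefinedMetric("fractal_dimension: fewer than 3 usable scales")

    dense = _densify(pts, max_segment=min_scale / 2.0)
    counts = []
    for s in scales:
        cells = np.floor((dense - lo) / s).astype(np.int64)
        counts.append(len(np.unique(cells, axis=0)))
    slope = np.polyfit(np.log(scales), np.log(counts), 1)[0]
    raw = float(-slope)
    return FractalDimension(value=min(max(raw, 1.0), 2.0), raw=raw)


def _densify(pts: np.ndarray, max_segment: float) -> np.ndarray:
    """Insert points along segments so none is longer than max_segment."""
    seg = np.hypot(*np.diff(pts, axis=0).T)
    out = [pts[:1]]
    for i, L in enumerate(seg):
        if L > max_segment:
            k = int(np.ceil(L / max_segment))
            t = np.arange(1, k + 1) / k
            out.append(pts[i] + t[:, None] * (pts[i + 1] - pts[i]))
        else:
            out.append(pts[i + 1 : i + 2])
    return np.vstack(out)


def compute_all(
    traj: Trajectory, meta: SubjectMeta, params: MetricParams = MetricParams()
) -> MetricVector:
    """Fill every metric for one subject's prepared track.

    The track must already be calibrated to cm, windowed to the analysis
    interval, gap-filled, and resampled.  Undefined metrics become NaN with
    a flag naming the metric; computation is deterministic given the track
    and parameters.
    """
    if traj.units != "cm":
        raise ValueError("compute_all expects a calibrated (cm) trajectory")
    flags: list[str] = []

    def guarded(name, fn, default=float("nan")):
        try:
            return fn()
        except UndefinedMetric:
            flags.append(name)
            return default

    pts = _positions(traj)
    dist = total_distance(traj)
    speed = guarded("average_speed", lambda: average_speed(traj))
    angles = turning_angles(pts, min_step=params.min_step)
    turns = bin_turns(angles)
    fd_res = guarded(
        "fd",
        lambda: fractal_dimension(traj, params.fd_min_scale, params.fd_n_scales),
        default=FractalDimension(float("nan"), float("nan")),
    )
    return MetricVector(
        subject_id=meta.subject_id,
        group=meta.group,
        distance=dist,
        n_distance=normalize_by_weight(dist, meta.weight),
        average_speed=speed,
        n_average_speed=normalize_by_weight(speed, meta.weight)
        if not math.isnan(speed)
        else float("nan"),
        turns=turns,
        iu=guarded("iu", lambda: intensity_of_use(traj)),
        number_of_points=count_points(pts, params.rdp_epsilon) if len(pts) >= 2 else 1,
        st=guarded("st", lambda: straightness(traj)),
        msd_rate=guarded("msd_rate", lambda: msd_rate(traj)),
        si=guarded(
            "si", lambda: sinuosity(traj, mode=params.sinuosity_mode, min_step=params.min_step)
        ),
        fd=fd_res.value,
        fd_raw=fd_res.raw,
        flags=tuple(flags),
    )
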