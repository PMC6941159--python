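"""Planar path geometry shared by the movement metrics.

All functions operate on an ``(n, 2)`` float array of positions in
centimetres.  They are deliberately free of any trajectory/time notion so
that each primitive can be tested against an independent geometric oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "TurnCounts",
    "HullResult",
    "as_points",
    "path_length",
    "rdp_simplify",
    "count_points",
    "turning_angles",
    "bin_turns",
    "hull_area",
]


def as_points(points) -> np.ndarray:
    """Coerce input to an ``(n, 2)`` float array and validate finiteness."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) point array, got shape {pts.shape}")
    if pts.shape[0] < 1:
        raise ValueError("polyline needs at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline contains non-finite coordinates")
    return pts


@dataclass(frozen=True)
class TurnCounts:
    """Turn counts by angular sharpness (degrees between successive steps)."""

    t30_60: int = 0
    t60_90: int = 0
    t90_120: int = 0
    t120: int = 0

    @property
    def total(self) -> int:
        return self.t30_60 + self.t60_90 + self.t90_120 + self.t120


@dataclass(frozen=True)
class HullResult:
    """Convex-hull area of the visited positions, in cm^2.

    ``degenerate`` is set when fewer than three non-collinear points exist,
    in which case ``area`` is 0 and downstream ratios are undefined.
    """

    area: float
    degenerate: bool


def path_length(points) -> float:
    """Sum of Euclidean segment lengths along the polyline (cm)."""
    pts = as_points(points)
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def _point_segment_distances(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment a--b (projection clamped)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(*(pts - a).T)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(pts - proj).T)


def rdp_simplify(points, epsilon: float) -> np.ndarray:
    """Ramer-Douglas-Peucker polyline simplification.

    Recursively keeps the point farthest from the chord of the current
    segment whenever that distance exceeds ``epsilon`` (distance measured to
    the chord as a segment, so the guarantee "every dropped point lies
    within epsilon of the simplified polyline" holds exactly).  Endpoints
    are always kept; the output is a subsequence of the input.
    """
    pts = as_points(points)
    if len(pts) < 2:
        raise ValueError("rdp_simplify needs at least 2 points")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    # explicit stack instead of recursion: tracks can be thousands of points
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        interior = pts[i + 1 : j]
        d = _point_segment_distances(interior, pts[i], pts[j])
        k = int(np.argmax(d))
        if d[k] > epsilon:
            split = i + 1 + k
            keep[split] = True
            stack.append((i, split))
            stack.append((split, j))
    return pts[keep]


def count_points(points, epsilon: float) -> int:
    """Number of vertices surviving RDP simplification at tolerance epsilon."""
    return len(rdp_simplify(points, epsilon))


def turning_angles(points, min_step: float = 0.0) -> np.ndarray:
    """Absolute angles (degrees, in [0, 180]) between successive displacements.

    Steps shorter than ``min_step`` are merged into the following
    displacement: a vertex is retained only once the cumulative displacement
    from the previously retained vertex reaches ``min_step``.  This keeps
    sub-resolution tracker jitter from registering as turning.  Zero-length
    steps are always merged.  Fewer than three retained vertices yield an
    empty array.
    """
    pts = as_points(points)
    if min_step < 0:
        raise ValueError("min_step must be >= 0")
    retained = [pts[0]]
    for p in pts[1:]:
        d = float(np.hypot(*(p - retained[-1])))
        if d >= min_step and d > 0.0:
            retained.append(p)
    if len(retained) < 3:
        return np.empty(0, dtype=float)
    vecs = np.diff(np.asarray(retained), axis=0)
    norms = np.hypot(*vecs.T)
    cosang = np.einsum("ij,ij->i", vecs[:-1], vecs[1:]) / (norms[:-1] * norms[1:])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def bin_turns(angles) -> TurnCounts:
    """Bin turning angles into sharpness classes.

    Bins are half-open with an inclusive lower edge: [30, 60), [60, 90),
    [90, 120), and [120, 180] (180 degrees, a full reversal, counts in the
    sharpest class).  Angles below 30 degrees are not counted as turns.
    """
    ang = np.asarray(angles, dtype=float)
    if ang.size and (ang.min() < 0 or ang.max() > 180):
        bad = ang[(ang < 0) | (ang > 180)][0]
        raise ValueError(f"turning angle {bad} outside [0, 180]")
    return TurnCounts(
        t30_60=int(np.sum((ang >= 30) & (ang < 60))),
        t60_90=int(np.sum((ang >= 60) & (ang < 90))),
        t90_120=int(np.sum((ang >= 90) & (ang < 120))),
        t120=int(np.sum(ang >= 120)),
    )


def hull_area(points) -> HullResult:
    """Convex-hull area of the point set (cm^2).

    Collinear or <3-point inputs are degenerate: area 0 with the flag set,
    so that ratio metrics built on the hull can refuse to divide by it.
    """
    pts = as_points(points)
    if len(pts) < 3:
        return HullResult(0.0, True)
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        return HullResult(0.0, True)
    return HullResult(float(hull.area), False)
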