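"""Seeded synthetic cohorts: bounded correlated random walks with tracker noise.

No tracking data were published with the clinic study this pipeline is
built around, so validation runs on simulated consultations: one dog
wandering a rectangular room for three minutes, observed by an imperfect
overhead tracker.  The kinematic model is a correlated random walk —
per-frame von Mises turning noise around the current heading, interrupted
by Poisson-timed large reorientation events and by stationary pause bouts,
with optional drift toward a fixed anchor point (the owner's chair) and
specular reflection at the walls.  An observation layer then adds isotropic
position jitter and Bernoulli per-frame dropout.

Two presets encode the contrast the analysis is meant to detect: the
hyperactive-like preset moves several-fold faster, reorients an order of
magnitude more often, and ignores the anchor; the control preset is slow,
pauses often, and stays near the owner.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectory import SubjectMeta, Trajectory, write_metadata

__all__ = [
    "SimParams",
    "CohortSpec",
    "simulate_track",
    "preset_hyperactive",
    "preset_control",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimParams:
    """Kinematic and observation parameters of one simulated track."""

    room_width: float = 300.0  # cm
    room_height: float = 160.0  # cm
    frame_rate: float = 25.0  # Hz
    duration: float = 180.0  # s
    mean_speed: float = 15.0  # cm/s while moving
    speed_sd: float = 5.0  # cm/s
    turn_concentration: float = 6.0  # von Mises kappa; higher = straighter
    reorient_rate: float = 0.1  # large heading resets per second
    pause_prob: float = 0.1  # per-second probability of starting a pause
    pause_mean_duration: float = 2.0  # s, exponential
    anchor_strength: float = 0.0  # per-second pull of heading toward anchor
    jitter_sd: float = 1.0  # cm of isotropic tracker noise
    dropout_rate: float = 0.05  # per-frame probability of a missed detection
    seed: int = 0

    def __post_init__(self):
        if self.room_width <= 0 or self.room_height <= 0:
            raise ValueError("room dimensions must be > 0")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be > 0")
        for name in (
            "mean_speed", "speed_sd", "turn_concentration", "reorient_rate",
            "pause_prob", "pause_mean_duration", "anchor_strength", "jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """A balanced two-group cohort of simulated subjects."""

    n_per_group: int = 12
    h_params: SimParams | None = None
    c_params: SimParams | None = None
    h_weight: tuple[float, float] = (21.0, 7.0)  # mean, SD kg
    c_weight: tuple[float, float] = (23.0, 7.0)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def preset_hyperactive() -> SimParams:
    """Fast, erratic, room-covering movement: the case-group profile."""
    return SimParams(
        mean_speed=30.0,
        speed_sd=10.0,
        turn_concentration=4.0,
        reorient_rate=0.5,
        pause_prob=0.05,
        pause_mean_duration=1.0,
        anchor_strength=0.0,
    )


def preset_control() -> SimParams:
    """Slow, pausing, owner-anchored movement: the control-group profile."""
    return SimParams(
        mean_speed=8.0,
        speed_sd=3.0,
        turn_concentration=8.0,
        reorient_rate=0.05,
        pause_prob=0.4,
        pause_mean_duration=4.0,
        anchor_strength=0.5,
    )


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by specular reflection."""
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return v + lo


def simulate_track(p: SimParams) -> Trajectory:
    """Simulate one observed track, fully reproducible from ``p.seed``.

    The true path is confined to the room; only the observation layer
    (jitter, dropout) is applied afterwards, so invalid frames correspond
    to missed detections, not teleports.
    """
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.frame_rate
    n = int(round(p.duration * p.frame_rate))
    anchor = np.array([p.room_width * 0.15, p.room_height * 0.5])

    pos = np.empty((n, 2))
    pos[0] = rng.uniform([0, 0], [p.room_width, p.room_height])
    heading = rng.uniform(-np.pi, np.pi)
    pause_left = 0.0

    for i in range(1, n):
        if pause_left > 0:
            pause_left -= dt
            pos[i] = pos[i - 1]
            continue
        if rng.random() < p.pause_prob * dt:
            pause_left = rng.exponential(p.pause_mean_duration)
            pos[i] = pos[i - 1]
            continue
        if rng.random() < p.reorient_rate * dt:
            heading = rng.uniform(-np.pi, np.pi)
        elif p.turn_concentration > 0:
            heading += rng.vonmises(0.0, p.turn_concentration)
        else:
            heading = rng.uniform(-np.pi, np.pi)
        if p.anchor_strength > 0:
            to_anchor = np.arctan2(anchor[1] - pos[i - 1, 1], anchor[0] - pos[i - 1, 0])
            delta = np.angle(np.exp(1j * (to_anchor - heading)))
            heading += p.anchor_strength * delta * dt
        speed = max(rng.normal(p.mean_speed, p.speed_sd), 0.0)
        step = speed * dt
        x = pos[i - 1, 0] + step * np.cos(heading)
        y = pos[i - 1, 1] + step * np.sin(heading)
        # reflect at walls and turn the heading with the bounce
        if not 0 <= x <= p.room_width:
            heading = np.pi - heading
            x = _reflect(x, 0.0, p.room_width)
        if not 0 <= y <= p.room_height:
            heading = -heading
            y = _reflect(y, 0.0, p.room_height)
        pos[i] = (x, y)

    obs = pos + rng.normal(0.0, p.jitter_sd, size=pos.shape)
    valid = rng.random(n) >= p.dropout_rate
    times = np.arange(n) * dt
    return Trajectory(
        frames=np.arange(n), times=times,
        x=obs[:, 0], y=obs[:, 1], valid=valid,
        frame_rate=p.frame_rate, units="cm", site_id="sim",
    )


def _subject_seed(master_seed: int, index: int) -> int:
    """Deterministic, well-separated per-subject seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write a full simulated cohort as track CSVs plus a metadata CSV.

    Per-subject seeds derive deterministically from the master seed, so the
    same spec always produces byte-identical files.  Returns the track
    paths and the metadata path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h_params = spec.h_params or preset_hyperactive()
    c_params = spec.c_params or preset_control()

    track_paths: list[Path] = []
    metas: list[SubjectMeta] = []
    index = 0
    for group, params, (w_mean, w_sd) in (
        ("H", h_params, spec.h_weight),
        ("C", c_params, spec.c_weight),
    ):
        for k in range(spec.n_per_group):
            seed = _subject_seed(spec.master_seed, index)
            rng = np.random.default_rng(seed + 1)  # demographics stream
            subject_id = f"{group.lower()}{k:02d}"
            weight = float(np.clip(rng.normal(w_mean, w_sd), 8.0, 45.0))
            metas.append(
                SubjectMeta(
                    subject_id=subject_id,
                    group=group,
                    sex="m" if rng.random() < 0.5 else "f",
                    age=float(np.round(np.clip(rng.normal(3.0, 2.0), 0.5, 12.0), 2)),
                    weight=round(weight, 1),
                    neutered=bool(rng.random() < 0.8),
                )
            )
            traj = simulate_track(dataclasses.replace(params, seed=seed))
            path = out_dir / f"{subject_id}.csv"
            df = traj.to_dataframe()
            # blank out positions for missed detections, as a tracker would
            df.loc[~traj.valid, ["x", "y"]] = np.nan
            df.to_csv(path, index=False, float_format="%.4f")
            track_paths.append(path)
            index += 1

    meta_path = out_dir / "metadata.csv"
    write_metadata(metas, str(meta_path))
    return track_paths, meta_path
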