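"""Stochastic burst-and-coast swim simulation and cohort generation.

The walker alternates impulsive "bursts" (speed resets to a Gaussian draw,
heading turns by a Gaussian increment) with passive coasting (exponential
speed decay).  Burst events follow a Poisson process, discretised to at
most one event per 1/20 s frame.  An optional attraction point rotates the
mean turn toward a target in proportion to ``attraction_gain``; a lateral
bias term models a persistent preference for one side of the tank.  Walls
reflect specularly, with extra heading jitter inside a repulsion band to
avoid boundary sticking.

Cohort generation reproduces the counterbalanced two-condition design
(36 subjects, 2 batches of 9 per condition, 20 training trials plus tests
before training and after trials 10 and 20) with injectable learning
drift, a social-condition boost, and a side bias, so that downstream
statistics can be validated against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .arena import ArenaGeometry, make_default_arena
from .records import DEFAULT_DT, TIME_LIMIT_S, Trajectory, TrialRecord

__all__ = [
    "SwimParams",
    "CohortDesign",
    "simulate_trajectory",
    "simulate_cohort",
    "render_frames",
    "write_frames",
    "read_frames",
    "CalibrationTransform",
]

#: Heading jitter (rad / sqrt(s)) applied inside the wall-repulsion band.
_WALL_JITTER = 1.5


@dataclass(frozen=True)
class SwimParams:
    """Parameters of the burst-and-coast walker.

    Defaults give realistic speeds of a few body lengths per second; the
    underlying locomotion model of the original apparatus is external to
    this package, so these are configurable stand-ins.
    """

    burst_rate: float = 1.0            # events / s
    burst_speed_mean: float = 10.0     # cm / s
    burst_speed_sd: float = 3.0        # cm / s
    coast_decay_time: float = 0.4      # s
    turn_sd: float = 0.6               # rad per burst
    attraction_gain: float = 0.0       # in [0, 1]
    wall_repulsion_range: float = 2.0  # cm
    dt: float = DEFAULT_DT             # s (20 Hz)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be non-negative")
        if self.coast_decay_time <= 0 or self.dt <= 0:
            raise ValueError("coast_decay_time and dt must be positive")
        if self.burst_speed_mean < 0 or self.burst_speed_sd < 0:
            raise ValueError("burst speed parameters must be non-negative")
        if not 0.0 <= self.attraction_gain <= 1.0:
            raise ValueError("attraction_gain must lie in [0, 1]")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.mod(a + np.pi, 2.0 * np.pi) - np.pi


def _simulate_batch(
    params: SwimParams,
    n_steps: int,
    start: np.ndarray,
    bounds: Tuple[float, float, float, float],
    attraction: Optional[np.ndarray],
    gains: np.ndarray,
    side_gains: np.ndarray,
    side_sign: np.ndarray,
    rng: np.random.Generator,
    initial_speed: float = 0.0,
) -> np.ndarray:
    """Advance N independent walkers in lockstep; returns (n_steps+1, N, 2).

    All random draws have a fixed shape per step, so the output is a
    deterministic function of the generator state regardless of how many
    walkers burst on a given frame.
    """
    start = np.atleast_2d(np.asarray(start, dtype=float))
    n = start.shape[0]
    x0, x1, y0, y1 = bounds
    dt = params.dt
    p_burst = 1.0 - math.exp(-params.burst_rate * dt)
    decay = math.exp(-dt / params.coast_decay_time)

    pos = start.copy()
    heading = rng.uniform(-np.pi, np.pi, size=n)
    speed = np.full(n, float(initial_speed))
    out = np.empty((n_steps + 1, n, 2))
    out[0] = pos

    # y-wall target headings for the lateral bias: +pi/2 pulls toward y1.
    side_heading = side_sign * (np.pi / 2.0)

    for k in range(1, n_steps + 1):
        burst = rng.random(n) < p_burst
        turn_noise = rng.normal(0.0, params.turn_sd, size=n)
        speed_draw = np.clip(
            rng.normal(params.burst_speed_mean, params.burst_speed_sd, size=n),
            0.0, None)

        bias = side_gains * _wrap_angle(side_heading - heading)
        if attraction is not None:
            to_target = attraction - pos
            theta = np.arctan2(to_target[:, 1], to_target[:, 0])
            bias = bias + gains * _wrap_angle(theta - heading)

        heading = np.where(burst, heading + bias + turn_noise, heading)
        speed = np.where(burst, speed_draw, speed * decay)

        # extra heading jitter inside the wall-repulsion band
        near = (
            (pos[:, 0] - x0 < params.wall_repulsion_range)
            | (x1 - pos[:, 0] < params.wall_repulsion_range)
            | (pos[:, 1] - y0 < params.wall_repulsion_range)
            | (y1 - pos[:, 1] < params.wall_repulsion_range)
        )
        jitter = rng.normal(0.0, _WALL_JITTER * math.sqrt(dt), size=n)
        heading = np.where(near, heading + jitter, heading)

        pos = pos + speed[:, None] * dt * np.column_stack(
            (np.cos(heading), np.sin(heading)))

        # specular reflection (single bounce suffices at <= ~1 cm steps)
        lo = pos[:, 0] < x0
        hi = pos[:, 0] > x1
        pos[lo, 0] = 2.0 * x0 - pos[lo, 0]
        pos[hi, 0] = 2.0 * x1 - pos[hi, 0]
        heading = np.where(lo | hi, _wrap_angle(np.pi - heading), heading)
        lo = pos[:, 1] < y0
        hi = pos[:, 1] > y1
        pos[lo, 1] = 2.0 * y0 - pos[lo, 1]
        pos[hi, 1] = 2.0 * y1 - pos[hi, 1]
        heading = np.where(lo | hi, _wrap_angle(-heading), heading)
        pos[:, 0] = np.clip(pos[:, 0], x0, x1)
        pos[:, 1] = np.clip(pos[:, 1], y0, y1)

        out[k] = pos

    return out


def simulate_trajectory(
    params: SwimParams,
    arena: ArenaGeometry,
    duration: float,
    start: Tuple[float, float],
    attraction_point: Optional[Tuple[float, float]] = None,
    *,
    bounds: Optional[Tuple[float, float, float, float]] = None,
    side_bias: float = 0.0,
    side: int = 1,
    initial_speed: float = 0.0,
    identity: str = "subject",
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
) -> Trajectory:
    """Simulate one burst-and-coast trajectory on the 20 Hz grid.

    ``bounds`` restricts motion to a sub-rectangle (default: the whole
    tank); the release phase of a trial uses the focal compartment.  The
    result is bit-identical for a given seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    x0, x1, y0, y1 = bounds if bounds is not None else arena.tank_bounds
    sx, sy = float(start[0]), float(start[1])
    if not (x0 <= sx <= x1 and y0 <= sy <= y1):
        raise ValueError(f"start {start} outside simulation bounds")
    n_steps = int(round(duration / params.dt))
    if rng is None:
        rng = np.random.default_rng(params.seed)
    attraction = None
    gains = np.array([params.attraction_gain])
    if attraction_point is not None:
        attraction = np.array([attraction_point], dtype=float)
    traj = _simulate_batch(
        params, n_steps, np.array([[sx, sy]]), (x0, x1, y0, y1),
        attraction, gains,
        np.array([abs(side_bias)]), np.array([1.0 if side >= 0 else -1.0]),
        rng, initial_speed=initial_speed,
    )
    return Trajectory.from_positions(traj[:, 0, :], dt=params.dt, t0=t0,
                                     identity=identity)


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Counterbalanced two-condition study design with injectable effects.

    ``pref_drift`` raises the per-trial attraction toward the correct door
    linearly with trial number (learning); ``social_boost`` adds extra
    drift in the social condition; ``side_bias`` is a constant lateral
    attraction toward the preferred side (y = 0), exercising the
    correct-door-location factor of the analysis.
    """

    n_subjects: int = 36
    n_training: int = 20
    test_sessions: Tuple[int, ...] = (0, 10, 20)
    batches_per_condition: int = 2
    pref_drift: float = 0.0
    social_boost: float = 0.0
    side_bias: float = 0.0
    release_duration_s: float = TIME_LIMIT_S
    test_duration_s: float = 600.0
    female_ratio: float = 5.0 / 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        groups = 2 * self.batches_per_condition
        if self.n_subjects % groups:
            raise ValueError(
                f"n_subjects={self.n_subjects} not divisible by the "
                f"{groups} condition x batch groups")
        if self.n_subjects // 2 % 1:
            raise ValueError("conditions must receive equal subject counts")
        for f in ("pref_drift", "social_boost", "side_bias"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def batch_size(self) -> int:
        return self.n_subjects // (2 * self.batches_per_condition)


@dataclass(frozen=True)
class _SubjectAssignment:
    subject: int
    condition: str
    batch: int
    correct_door: str
    sex: str


def assign_subjects(design: CohortDesign) -> List[_SubjectAssignment]:
    """Deterministic counterbalanced assignment of condition/batch/door/sex.

    Doors alternate within each (condition, batch) group; with even group
    sizes every group is exactly balanced, and with odd sizes (e.g. 9) the
    imbalance alternates between the two batches so each condition stays
    fully counterbalanced overall.
    """
    out: List[_SubjectAssignment] = []
    sid = 1
    n_f = int(round(design.female_ratio * design.batch_size))
    for ci, condition in enumerate(("individual", "social")):
        for b in range(design.batches_per_condition):
            for i in range(design.batch_size):
                door = ("lower", "upper")[(i + b) % 2]
                sex = "F" if i < n_f else "M"
                out.append(_SubjectAssignment(sid, condition, b + 1, door, sex))
                sid += 1
    return out


def _session_gain(design: CohortDesign, condition: str, trial: int) -> float:
    g = design.pref_drift * trial
    if condition == "social":
        g += design.social_boost * trial
    return min(1.0, g)


def simulate_cohort(
    design: CohortDesign,
    params: SwimParams,
    arena: Optional[ArenaGeometry] = None,
    *,
    chunk: int = 256,
) -> List[TrialRecord]:
    """Generate release-phase trajectories for the full study.

    Returns one :class:`TrialRecord` per subject x session (training trials
    plus closed-door test sessions), with trajectories simulated inside the
    focal compartment, attraction toward the correct door growing with
    trial number, and design labels attached.  ``T`` and censoring are left
    unset; the tracking module's trial session fills them in.
    """
    if arena is None:
        arena = make_default_arena()
    assignments = assign_subjects(design)
    rng = np.random.default_rng(design.seed)
    bounds = arena.focal_bounds
    start = np.array(arena.cylinder_center)

    # flatten subject x session into one batch per phase kind
    specs: List[dict] = []
    for a in assignments:
        for s in design.test_sessions:
            specs.append(dict(assign=a, session=s, is_test=True,
                              gain=_session_gain(design, a.condition, s)))
        for j in range(1, design.n_training + 1):
            specs.append(dict(assign=a, session=j, is_test=False,
                              gain=_session_gain(design, a.condition, j)))

    records: List[TrialRecord] = []
    for is_test, duration in ((False, design.release_duration_s),
                              (True, design.test_duration_s)):
        group = [s for s in specs if s["is_test"] == is_test]
        n_steps = int(round(duration / params.dt))
        for lo in range(0, len(group), chunk):
            part = group[lo:lo + chunk]
            n = len(part)
            targets = np.array([
                _door_target(arena, s["assign"].correct_door) for s in part])
            gains = np.array([s["gain"] for s in part])
            side_gains = np.full(n, design.side_bias)
            side_sign = np.full(n, -1.0)  # preferred side is y = 0
            pos = _simulate_batch(
                params, n_steps, np.tile(start, (n, 1)), bounds,
                targets, gains, side_gains, side_sign, rng)
            for i, s in enumerate(part):
                a = s["assign"]
                traj = Trajectory.from_positions(pos[:, i, :], dt=params.dt)
                records.append(TrialRecord(
                    subject_traj=traj,
                    subject=a.subject,
                    condition=a.condition,
                    batch=a.batch,
                    session=s["session"],
                    is_test=s["is_test"],
                    correct_door=a.correct_door,
                    door_location=("preferred" if a.correct_door == "lower"
                                   else "nonpreferred"),
                    sex=a.sex,
                    time_limit_s=min(TIME_LIMIT_S, duration),
                ))
    records.sort(key=lambda r: (r.subject, r.is_test, r.session))
    return records


def _door_target(arena: ArenaGeometry, door: str) -> Tuple[float, float]:
    """Attraction target for a door: the centre of its trigger zone."""
    z = arena.trigger_zone(door)
    return ((z.x_min + z.x_max) / 2.0, (z.y_min + z.y_max) / 2.0)


# ---------------------------------------------------------------------------
# frame rendering (tracker fixtures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTransform:
    """Affine cm -> pixel mapping for rendered frames.

    Columns increase with arena x, rows with arena y (no vertical flip);
    the scale is isotropic.
    """

    px_per_cm: float
    x0_cm: float
    y0_cm: float
    width_px: int
    height_px: int

    def cm_to_px(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        col = (xy[:, 0] - self.x0_cm) * self.px_per_cm
        row = (xy[:, 1] - self.y0_cm) * self.px_per_cm
        return np.column_stack((row, col))

    def px_to_cm(self, rowcol: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(np.asarray(rowcol, dtype=float))
        x = rc[:, 1] / self.px_per_cm + self.x0_cm
        y = rc[:, 0] / self.px_per_cm + self.y0_cm
        return np.column_stack((x, y))

    def to_dict(self) -> dict:
        return {
            "px_per_cm": self.px_per_cm, "x0_cm": self.x0_cm,
            "y0_cm": self.y0_cm, "width_px": self.width_px,
            "height_px": self.height_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTransform":
        return cls(**d)


def render_frames(
    trajs: Sequence[Trajectory],
    arena: ArenaGeometry,
    resolution: Tuple[int, int] = (640, 480),
    *,
    region: Optional[Tuple[float, float, float, float]] = None,
    noise_sd: float = 0.0,
    fish_value: int = 40,
    background: int = 255,
    aspect_ratio: float = 0.28,
    seed: int = 0,
) -> Tuple[np.ndarray, CalibrationTransform]:
    """Render trajectories as 8-bit grayscale frames with dark ellipse fish.

    The ellipse major axis is one body length, oriented along the current
    displacement.  ``region`` defaults to the focal compartment (the view
    of the tracking camera).  Returns ``(frames, calibration)`` where
    frames has shape (n_frames, height, width).
    """
    from skimage.draw import ellipse as _ellipse

    if not trajs:
        raise ValueError("need at least one trajectory to render")
    t_ref = trajs[0].t
    for tr in trajs[1:]:
        if len(tr.t) != len(t_ref) or not np.allclose(tr.t, t_ref):
            raise ValueError("trajectories must share a common time grid")
    w_px, h_px = int(resolution[0]), int(resolution[1])
    if region is None:
        region = arena.focal_bounds
    x0, x1, y0, y1 = region
    s = min(w_px / (x1 - x0), h_px / (y1 - y0))
    calib = CalibrationTransform(s, x0, y0, w_px, h_px)
    if arena.body_length * s < 2.0:
        raise ValueError(
            f"resolution too low: body length maps to {arena.body_length * s:.2f} px")

    a_px = arena.body_length * s / 2.0          # semi-major
    b_px = max(1.0, a_px * aspect_ratio)        # semi-minor
    n = len(t_ref)
    frames = np.full((n, h_px, w_px), background, dtype=np.uint8)
    rng = np.random.default_rng(seed)

    for tr in trajs:
        rc = calib.cm_to_px(tr.xy)
        disp = np.diff(tr.xy, axis=0)
        angles = np.zeros(n)
        moved = np.linalg.norm(disp, axis=1) > 1e-9
        ang = np.arctan2(disp[:, 1], disp[:, 0])
        last = 0.0
        for k in range(n):
            if k > 0 and moved[k - 1]:
                last = ang[k - 1]
            angles[k] = last
        for k in range(n):
            if not tr.valid[k]:
                continue
            # skimage measures rotation from the row axis, counter-clockwise
            rr, cc = _ellipse(rc[k, 0], rc[k, 1], b_px, a_px,
                              shape=(h_px, w_px), rotation=-angles[k])
            frames[k, rr, cc] = fish_value

    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=frames.shape)
        frames = np.clip(frames.astype(float) + noise, 0, 255).astype(np.uint8)
    return frames, calib


def write_frames(frames: np.ndarray, calib: CalibrationTransform,
                 outdir: str | Path, dt: float = DEFAULT_DT) -> None:
    """Write frames as zero-padded PNGs plus a JSON calibration sidecar."""
    import json

    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(len(frames))))
    for i, fr in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:0{width}d}.png", fr)
    meta = calib.to_dict() | {"dt_s": dt, "n_frames": int(len(frames))}
    (outdir / "calibration.json").write_text(json.dumps(meta, indent=2))


def read_frames(indir: str | Path) -> Tuple[np.ndarray, CalibrationTransform, float]:
    """Read a PNG sequence written by :func:`write_frames`."""
    import json

    import imageio.v3 as iio

    indir = Path(indir)
    meta = json.loads((indir / "calibration.json").read_text())
    dt = float(meta.pop("dt_s"))
    meta.pop("n_frames", None)
    calib = CalibrationTransform.from_dict(meta)
    paths = sorted(indir.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files under {indir}")
    frames = np.stack([iio.imread(p) for p in paths])
    return frames, calib, dt
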