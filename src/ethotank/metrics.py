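"""Per-trial behavioral and learning measures.

All measures are computed over the scoring window of a trial: from the
subject's release up to door opening (or up to the phase time limit on
censored trials and closed-door tests).  Undefined values are returned as
``None`` and written as empty CSV fields, never as zeros.

Conventions (see the module-level options of :class:`MetricOptions`):

* occupancy entropy uses a 10 x 10 uniform grid over the focal
  compartment (100 bins, matching the summation limit of the entropy
  formula);
* heading is the direction of the displacement between consecutive
  samples; samples moving slower than a floor are excluded from heading
  and turn-rate statistics to avoid angles of near-zero vectors;
* freezing uses the net displacement between the endpoints of the 2 s
  window centred on each sample (a path-length variant is available);
* samples flagged interpolated contribute to occupancy and zone timing
  (positions are still best-available estimates) but are excluded from
  kinematic and heading statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, wall_distances, zone_contains_mask
from .records import TrialRecord

__all__ = [
    "MetricOptions",
    "MetricsRecord",
    "door_time_metrics",
    "wall_metrics",
    "trajectory_entropy",
    "heading_error",
    "kinematics",
    "freezing_time",
    "avoidance_score",
    "avoidance_rate",
    "modified_preference",
    "compute_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class MetricOptions:
    entropy_grid: Tuple[int, int] = (10, 10)
    speed_floor_cm_s: float = 0.5
    freezing_window_s: float = 2.0
    freezing_threshold_cm: float = 4.0
    freezing_mode: str = "net"          # "net" | "path"
    avoidance_window_s: float = 15.0
    avoidance_threshold_bl: float = 2.0
    truncate_at_door: bool = True


@dataclass
class MetricsRecord:
    """All per-trial measures; ``None`` marks undefined values."""

    T: Optional[float] = None
    censored: Optional[bool] = None
    tau_C: float = 0.0
    tau_I: float = 0.0
    T_wall: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    PI: Optional[float] = None
    RI: Optional[float] = None
    H: Optional[float] = None
    theta_C_mean: Optional[float] = None
    v_mean: Optional[float] = None
    a_mean: Optional[float] = None
    omega_mean: Optional[float] = None
    F: float = 0.0
    A: Optional[bool] = None
    PI_m: Optional[float] = None
    labels: Dict = field(default_factory=dict)

    def to_row(self) -> Dict:
        row = dict(self.labels)
        row.update({
            "T": self.T, "censored": self.censored,
            "tau_C": self.tau_C, "tau_I": self.tau_I,
            "T_wall1": self.T_wall[0], "T_wall2": self.T_wall[1],
            "T_wall3": self.T_wall[2], "T_wall4": self.T_wall[3],
            "PI": self.PI, "RI": self.RI, "H": self.H,
            "theta_C_mean": self.theta_C_mean,
            "v_mean": self.v_mean, "a_mean": self.a_mean,
            "omega_mean": self.omega_mean,
            "F": self.F, "A": self.A, "PI_m": self.PI_m,
        })
        return row


def _scored(rec: TrialRecord, opts: MetricOptions):
    """Scoring-window sub-trajectory of the subject."""
    if opts.truncate_at_door:
        t0, t1 = rec.scoring_window()
    else:
        t0, t1 = rec.release_time, float(rec.subject_traj.t[-1])
    return rec.subject_traj.slice_time(t0, t1)


def door_time_metrics(rec: TrialRecord, arena: ArenaGeometry,
                      opts: MetricOptions = MetricOptions()
                      ) -> Tuple[float, float, Optional[float]]:
    """Time near the correct/incorrect door and the preference index.

    ``PI = tau_C / (tau_C + tau_I)``, undefined (``None``) when the fish
    never visited either trigger zone.
    """
    traj = _scored(rec, opts)
    dt = traj.dt
    zc = arena.trigger_zone(rec.correct_door)
    zi = arena.trigger_zone(arena.other_door(rec.correct_door))
    ok = traj.valid
    tau_c = float(np.sum(zone_contains_mask(zc, traj.xy) & ok) * dt)
    tau_i = float(np.sum(zone_contains_mask(zi, traj.xy) & ok) * dt)
    pi = tau_c / (tau_c + tau_i) if tau_c + tau_i > 0 else None
    return tau_c, tau_i, pi


def wall_metrics(rec: TrialRecord, arena: ArenaGeometry,
                 opts: MetricOptions = MetricOptions()
                 ) -> Tuple[Tuple[float, float, float, float], Optional[float]]:
    """Per-wall band times and the reward index ``T1 / sum(Ti)``.

    Each sample within the band width of at least one wall is assigned to
    its nearest wall (ties to the lowest index, as corners overlap).
    """
    traj = _scored(rec, opts)
    dt = traj.dt
    d = wall_distances(arena, traj.xy)
    near = d.min(axis=1) <= arena.wall_band
    which = d.argmin(axis=1)
    times = tuple(
        float(np.sum(near & (which == i) & traj.valid) * dt) for i in range(4))
    total = sum(times)
    ri = times[0] / total if total > 0 else None
    return times, ri


def trajectory_entropy(rec: TrialRecord, arena: ArenaGeometry,
                       opts: MetricOptions = MetricOptions()) -> Optional[float]:
    """Shannon entropy (bits) of the occupancy over the focal-compartment grid."""
    traj = _scored(rec, opts)
    xy = traj.xy[traj.valid]
    if len(xy) == 0:
        return None
    nx, ny = opts.entropy_grid
    x0, x1, y0, y1 = arena.focal_bounds
    ix = np.clip(((xy[:, 0] - x0) / (x1 - x0) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((xy[:, 1] - y0) / (y1 - y0) * ny).astype(int), 0, ny - 1)
    counts = np.bincount(ix * ny + iy, minlength=nx * ny)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _displacement_headings(traj, floor: float):
    """Displacement vectors, speeds, and a usability mask per step."""
    xy = traj.xy
    dt = traj.dt
    disp = np.diff(xy, axis=0)
    speed = np.linalg.norm(disp, axis=1) / dt
    measured = traj.valid & ~traj.interpolated
    usable = measured[:-1] & measured[1:] & (speed >= floor)
    return disp, speed, usable


def heading_error(rec: TrialRecord, arena: ArenaGeometry,
                  opts: MetricOptions = MetricOptions()
                  ) -> Tuple[np.ndarray, Optional[float]]:
    """Absolute angle (deg) between heading and the correct-door direction.

    Returns the per-step series (NaN where excluded) and its mean, or
    ``None`` if no step clears the speed floor.
    """
    traj = _scored(rec, opts)
    if len(traj) < 2:
        return np.empty(0), None
    disp, _, usable = _displacement_headings(traj, opts.speed_floor_cm_s)
    door = np.asarray(arena.door_centers[rec.correct_door])
    to_door = door - traj.xy[:-1]
    dot = np.einsum("ij,ij->i", disp, to_door)
    den = np.linalg.norm(disp, axis=1) * np.linalg.norm(to_door, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.degrees(np.arccos(np.clip(dot / den, -1.0, 1.0)))
    series = np.where(usable & (den > 0), ang, np.nan)
    if not np.any(~np.isnan(series)):
        return series, None
    return series, float(np.nanmean(series))


def kinematics(rec: TrialRecord,
               opts: MetricOptions = MetricOptions()
               ) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Mean speed, acceleration magnitude, and turn rate by finite differences.

    ``v_t = |x_{t+1} - x_t| / dt``, ``a_t = |v_{t+1} - v_t| / dt`` (vector
    difference), ``w_t = arccos(v_{t+1} . v_t / |v_{t+1}||v_t|) / dt``.
    Turn-rate samples with either speed below the floor are excluded, as
    are interpolated samples.
    """
    traj = _scored(rec, opts)
    if len(traj) < 3:
        return None, None, None
    dt = traj.dt
    disp = np.diff(traj.xy, axis=0)
    v = disp / dt                                   # (n-1, 2)
    speed = np.linalg.norm(v, axis=1)
    measured = traj.valid & ~traj.interpolated
    v_ok = measured[:-1] & measured[1:]

    v_mean = float(speed[v_ok].mean()) if np.any(v_ok) else None

    dv = np.diff(v, axis=0)                         # (n-2, 2)
    a = np.linalg.norm(dv, axis=1) / dt
    a_ok = v_ok[:-1] & v_ok[1:]
    a_mean = float(a[a_ok].mean()) if np.any(a_ok) else None

    dot = np.einsum("ij,ij->i", v[1:], v[:-1])
    den = speed[1:] * speed[:-1]
    w_ok = a_ok & (speed[:-1] >= opts.speed_floor_cm_s) \
        & (speed[1:] >= opts.speed_floor_cm_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.arccos(np.clip(dot / den, -1.0, 1.0)) / dt
    omega_mean = float(w[w_ok].mean()) if np.any(w_ok) else None
    return v_mean, a_mean, omega_mean


def freezing_time(rec: TrialRecord,
                  opts: MetricOptions = MetricOptions()) -> float:
    """Total time the fish moved less than the threshold per rolling window.

    A sample is frozen when the displacement over the 2 s window centred
    on it (endpoints clipped at the trajectory edges) is below 4 cm; in
    ``path`` mode the summed step length over the window is used instead.
    """
    traj = _scored(rec, opts)
    n = len(traj)
    if n < 2:
        return 0.0
    dt = traj.dt
    half = int(round(opts.freezing_window_s / 2.0 / dt))
    idx = np.arange(n)
    j1 = np.clip(idx - half, 0, n - 1)
    j2 = np.clip(idx + half, 0, n - 1)
    if opts.freezing_mode == "net":
        moved = np.linalg.norm(traj.xy[j2] - traj.xy[j1], axis=1)
    elif opts.freezing_mode == "path":
        steps = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1)
        c = np.concatenate(([0.0], np.cumsum(steps)))
        moved = c[j2] - c[j1]
    else:
        raise ValueError(f"unknown freezing_mode {opts.freezing_mode!r}")
    frozen = (moved < opts.freezing_threshold_cm) & traj.valid
    return float(np.sum(frozen) * dt)


def avoidance_score(rec: TrialRecord, arena: ArenaGeometry,
                    opts: MetricOptions = MetricOptions()) -> Optional[bool]:
    """Whether the fish retreated beyond 2 BL of the door after it opened.

    True iff the distance to the correct-door centre exceeds two body
    lengths at some sample within the 15 s following door opening.
    Undefined on censored trials and closed-door tests.
    """
    if rec.T is None or rec.censored:
        return None
    t_open = rec.release_time + rec.T
    seg = rec.subject_traj.slice_time(t_open, t_open + opts.avoidance_window_s)
    seg_xy = seg.xy[seg.valid]
    if len(seg_xy) == 0:
        return None
    door = np.asarray(arena.door_centers[rec.correct_door])
    dist = np.linalg.norm(seg_xy - door, axis=1)
    return bool(dist.max() > opts.avoidance_threshold_bl * arena.body_length)


def avoidance_rate(flags) -> Optional[float]:
    """Percentage of scored trials with an avoidance response.

    ``None`` flags (unscored trials) are ignored; returns ``None`` when
    nothing was scored.
    """
    scored = [bool(f) for f in flags if f is not None]
    if not scored:
        return None
    return 100.0 * sum(scored) / len(scored)


def modified_preference(rec: TrialRecord, arena: ArenaGeometry,
                        opts: MetricOptions = MetricOptions()) -> Optional[float]:
    """Fraction of valid time spent in the middle width-third of the tank."""
    traj = _scored(rec, opts)
    xy = traj.xy[traj.valid]
    if len(xy) == 0:
        return None
    h = arena.width / 3.0
    third = np.clip((xy[:, 1] / h).astype(int), 0, 2)
    return float(np.mean(third == 1))


def compute_metrics(rec: TrialRecord, arena: ArenaGeometry,
                    opts: MetricOptions = MetricOptions()) -> MetricsRecord:
    """Compute the full measure set for one trial."""
    tau_c, tau_i, pi = door_time_metrics(rec, arena, opts)
    t_wall, ri = wall_metrics(rec, arena, opts)
    h = trajectory_entropy(rec, arena, opts)
    _, theta = heading_error(rec, arena, opts)
    v, a, w = kinematics(rec, opts)
    return MetricsRecord(
        T=rec.T, censored=rec.censored,
        tau_C=tau_c, tau_I=tau_i, T_wall=t_wall,
        PI=pi, RI=ri, H=h, theta_C_mean=theta,
        v_mean=v, a_mean=a, omega_mean=w,
        F=freezing_time(rec, opts),
        A=avoidance_score(rec, arena, opts),
        PI_m=modified_preference(rec, arena, opts),
        labels=rec.labels,
    )


def metrics_table(records: List[TrialRecord], arena: ArenaGeometry,
                  opts: MetricOptions = MetricOptions()) -> pd.DataFrame:
    """One-row-per-trial table of all measures plus design labels."""
    rows = [compute_metrics(r, arena, opts).to_row() for r in records]
    return pd.DataFrame(rows)
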