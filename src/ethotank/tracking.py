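"""Frame-differencing tracker, trigger monitor, and trial state machine.

Detection subtracts consecutive grayscale frames, thresholds the absolute
difference, closes and hole-fills the outlines, and takes connected-
component centroids.  A constant-velocity Kalman filter per identity fills
detection gaps; extrapolation beyond a configurable horizon holds the last
estimate and marks samples invalid.

The door trigger implements the "3 s out of any 5 s" rule as a trailing
window count at 20 Hz: the door opens at the first sample whose trailing
5 s window (clipped at series start) contains at least 60 presence
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .arena import ArenaGeometry, zone_contains_mask
from .records import DEFAULT_DT, DoorEvent, Trajectory, TrialRecord
from .swim_sim import CalibrationTransform

__all__ = [
    "TrackerConfig",
    "Detection",
    "KalmanTrack",
    "TrackState",
    "detect_blobs",
    "assign_identities",
    "track_video",
    "evaluate_trigger",
    "run_trial_session",
    "TRIGGER_WINDOW_S",
    "TRIGGER_DWELL_S",
]

#: Trigger rule: at least 3 s of presence within any trailing 5 s window.
TRIGGER_WINDOW_S = 5.0
TRIGGER_DWELL_S = 3.0

#: Reward period after door opening (2 min).
REWARD_S = 120.0


@dataclass(frozen=True)
class TrackerConfig:
    threshold: int = 10             # grey levels on the absolute difference
    min_area_px: int = 6            # reject smaller components
    close_radius_px: int = 2
    merge_radius_cm: float = 4.0    # fuse nose/tail motion crescents of one fish
    gate_cm: float = 6.0            # assignment gating radius
    process_noise: float = 20.0     # cm/s^2 white acceleration
    measurement_noise_cm: float = 0.2
    velocity_damping: float = 0.88  # per-frame decay, matches coasting
    max_extrapolation_s: float = 1.0
    dt: float = DEFAULT_DT


@dataclass
class Detection:
    """Centroids found on one frame pair."""

    t: float
    centroids_cm: np.ndarray     # (k, 2)
    centroids_px: np.ndarray     # (k, 2) row/col
    areas_px: np.ndarray         # (k,)

    @property
    def count(self) -> int:
        return len(self.areas_px)


class KalmanTrack:
    """Damped constant-velocity Kalman filter over [x, y, vx, vy] in cm.

    The velocity decays geometrically between updates, mirroring the
    burst-and-coast style: between tail beats the target slows toward a
    stop, so extrapolated positions converge instead of sailing away.
    """

    def __init__(self, cfg: TrackerConfig, xy0: np.ndarray, t0: float) -> None:
        dt = cfg.dt
        lam = cfg.velocity_damping
        self.F = np.array([[1, 0, dt, 0],
                           [0, 1, 0, dt],
                           [0, 0, lam, 0],
                           [0, 0, 0, lam]], dtype=float)
        q = cfg.process_noise ** 2
        g = np.array([[dt ** 2 / 2, 0], [0, dt ** 2 / 2], [dt, 0], [0, dt]])
        self.Q = g @ g.T * q
        self.H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
        self.R = np.eye(2) * cfg.measurement_noise_cm ** 2
        self.x = np.array([xy0[0], xy0[1], 0.0, 0.0])
        self.P = np.diag([1.0, 1.0, 25.0, 25.0])
        self.last_seen = t0

    def predict(self) -> np.ndarray:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.x[:2].copy()

    def update(self, z: np.ndarray, t: float) -> None:
        # the frame-difference centroid estimates the midpoint of the two
        # frame positions; advance it half a step to de-bias the lag
        z = z + 0.5 * self.F[0, 2] * self.x[2:4]
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(4) - K @ self.H) @ self.P
        self.last_seen = t

    @property
    def position(self) -> np.ndarray:
        return self.x[:2].copy()


@dataclass
class TrackState:
    """Per-identity filters plus the assignment history of the last step."""

    cfg: TrackerConfig
    tracks: Dict[str, KalmanTrack] = field(default_factory=dict)
    history: List[Tuple[float, Dict[str, int]]] = field(default_factory=list)


def detect_blobs(frame_a: np.ndarray, frame_b: np.ndarray,
                 cfg: TrackerConfig, calib: CalibrationTransform,
                 t: float = 0.0) -> Detection:
    """Detect moving targets between two consecutive grayscale frames."""
    from skimage.measure import label, regionprops
    from skimage.morphology import closing, disk

    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2D grayscale")
    diff = np.abs(b.astype(np.int16) - a.astype(np.int16))
    mask = diff > cfg.threshold
    cents: list = []
    areas: list = []
    rows = np.flatnonzero(mask.any(axis=1))
    if len(rows):
        # crop morphology to the active region for speed
        cols = np.flatnonzero(mask.any(axis=0))
        pad = 2 * cfg.close_radius_px + 2
        r0 = max(0, rows[0] - pad)
        r1 = min(mask.shape[0], rows[-1] + pad + 1)
        c0 = max(0, cols[0] - pad)
        c1 = min(mask.shape[1], cols[-1] + pad + 1)
        sub = mask[r0:r1, c0:c1]
        if cfg.close_radius_px > 0:
            sub = closing(sub, disk(cfg.close_radius_px))
        sub = ndimage.binary_fill_holes(sub)
        for rp in regionprops(label(sub)):
            if rp.area >= cfg.min_area_px:
                cents.append((rp.centroid[0] + r0, rp.centroid[1] + c0))
                areas.append(rp.area)
    if cents:
        px, ar = _merge_components(
            np.asarray(cents, dtype=float), np.asarray(areas, dtype=float),
            cfg.merge_radius_cm * calib.px_per_cm)
        cm = calib.px_to_cm(px)
    else:
        px = np.empty((0, 2))
        cm = np.empty((0, 2))
        ar = np.empty(0)
    return Detection(t, cm, px, ar)


def _merge_components(cents_px: np.ndarray, areas: np.ndarray,
                      radius_px: float) -> Tuple[np.ndarray, np.ndarray]:
    """Fuse components closer than ``radius_px`` (area-weighted centroids).

    A small fish differenced against itself one frame later splits into a
    nose and a tail crescent roughly one body length apart; both belong
    to the same animal.
    """
    n = len(areas)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(cents_px[i] - cents_px[j]) <= radius_px:
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    cents, ars = [], []
    for members in groups.values():
        w = areas[members]
        cents.append(np.average(cents_px[members], axis=0, weights=w))
        ars.append(w.sum())
    order = np.argsort([-a for a in ars])
    return (np.asarray(cents)[order].reshape(-1, 2),
            np.asarray(ars)[order])


def assign_identities(det: Detection, state: TrackState, t: float,
                      replica_command: Optional[np.ndarray] = None
                      ) -> Dict[str, Tuple[np.ndarray, bool, bool]]:
    """Assign detections to identities and advance the Kalman filters.

    The detection nearest the commanded replica position (within the
    gating radius) is the replica; the remaining detection nearest the
    subject's prediction is the subject.  Unmatched identities are
    extrapolated and flagged ``interpolated``; beyond the extrapolation
    horizon the estimate is held and flagged invalid.

    Returns ``{identity: (xy_cm, valid, interpolated)}``.
    """
    cfg = state.cfg
    remaining = list(range(det.count))
    out: Dict[str, Tuple[np.ndarray, bool, bool]] = {}
    assigned: Dict[str, int] = {}

    # advance every existing filter one step before matching
    predictions = {ident: tr.predict() for ident, tr in state.tracks.items()}

    # replica first: anchored to the command rather than to appearance
    if replica_command is not None and remaining:
        d = np.linalg.norm(det.centroids_cm[remaining] - replica_command, axis=1)
        j = int(np.argmin(d))
        if d[j] <= cfg.gate_cm:
            assigned["replica"] = remaining.pop(j)
        if "replica" not in state.tracks and "replica" in assigned:
            state.tracks["replica"] = KalmanTrack(
                cfg, det.centroids_cm[assigned["replica"]], t)

    # subject (and a command-less replica) match nearest-to-prediction
    for ident in ("subject", "replica"):
        if ident in assigned:
            continue
        track = state.tracks.get(ident)
        if track is None:
            if ident == "subject" and remaining:
                idx = remaining.pop(0)
                state.tracks[ident] = KalmanTrack(cfg, det.centroids_cm[idx], t)
                assigned[ident] = idx
            continue
        if remaining:
            d = np.linalg.norm(
                det.centroids_cm[remaining] - predictions[ident], axis=1)
            j = int(np.argmin(d))
            if d[j] <= cfg.gate_cm:
                assigned[ident] = remaining.pop(j)

    for ident, track in state.tracks.items():
        if ident in assigned:
            track.update(det.centroids_cm[assigned[ident]], t)
            out[ident] = (track.position, True, False)
        else:
            gap = t - track.last_seen
            if gap <= cfg.max_extrapolation_s + 1e-9:
                out[ident] = (track.position, True, True)
            else:
                out[ident] = (track.position, False, True)

    state.history.append((t, assigned))
    return out


def track_video(frames: np.ndarray, cfg: TrackerConfig,
                calib: CalibrationTransform,
                replica_commands: Optional[np.ndarray] = None
                ) -> Dict[str, Trajectory]:
    """Track a frame sequence; returns per-identity trajectories.

    Output trajectories live on the uniform 20 Hz grid with one sample per
    frame; the first sample (which has no preceding frame to difference)
    repeats the first estimate and is flagged interpolated.
    """
    frames = np.asarray(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    n = len(frames)
    dt = cfg.dt
    state = TrackState(cfg)
    results: Dict[str, List[Tuple[np.ndarray, bool, bool]]] = {}

    for i in range(1, n):
        t = i * dt
        det = detect_blobs(frames[i - 1], frames[i], cfg, calib, t=t)
        cmd = None
        if replica_commands is not None:
            cmd = np.asarray(replica_commands[i], dtype=float)
        step = assign_identities(det, state, t, replica_command=cmd)
        for ident, item in step.items():
            results.setdefault(ident, [])
            # backfill identities that appeared late
            while len(results[ident]) < i - 1:
                results[ident].append((item[0], False, True))
            results[ident].append(item)

    out: Dict[str, Trajectory] = {}
    t_grid = dt * np.arange(n)
    for ident, items in results.items():
        while len(items) < n - 1:
            items.append((items[-1][0], False, True))
        xy = np.vstack([items[0][0]] + [it[0] for it in items])
        valid = np.array([items[0][1]] + [it[1] for it in items])
        interp = np.array([True] + [it[2] for it in items])
        out[ident] = Trajectory(t_grid, xy, valid, interp, identity=ident)
    if not out:
        raise ValueError("no targets detected in the frame sequence")
    return out


def evaluate_trigger(presence: np.ndarray, dt: float = DEFAULT_DT,
                     *, window_s: float = TRIGGER_WINDOW_S,
                     dwell_s: float = TRIGGER_DWELL_S) -> Optional[float]:
    """Earliest trigger time for a 20 Hz boolean presence series.

    A sample at index ``i`` fires when the trailing window covering the
    last ``window_s`` seconds (clipped to the elapsed series) contains at
    least ``dwell_s`` worth of presence samples; the returned time is the
    end of that sample's interval, ``(i + 1) * dt`` from series start.
    Returns ``None`` if the rule is never satisfied.
    """
    presence = np.asarray(presence)
    if presence.dtype != bool:
        if not np.all((presence == 0) | (presence == 1)):
            raise ValueError("presence series must be boolean")
        presence = presence.astype(bool)
    if dt <= 0:
        raise ValueError("dt must be positive")
    win = int(round(window_s / dt))
    need = int(round(dwell_s / dt))
    if len(presence) == 0:
        return None
    c = np.cumsum(presence.astype(np.int64))
    trailing = c.copy()
    if len(c) > win:
        trailing[win:] = c[win:] - c[:-win]
    hit = np.nonzero(trailing >= need)[0]
    if len(hit) == 0:
        return None
    return float((hit[0] + 1) * dt)


def run_trial_session(subject_traj: Trajectory, arena: ArenaGeometry,
                      labels: dict, release_time: float = 0.0,
                      *, time_limit_s: float = 1800.0,
                      dt: Optional[float] = None) -> TrialRecord:
    """Score one trial: trigger detection, door events, and censoring.

    Builds the presence series over the correct door's trigger zone from
    ``release_time`` on, applies the trigger rule, and records ``T`` (from
    release) or right-censors at the time limit.  Raises if the trajectory
    ends before the limit without a trigger, since censoring could not be
    established.
    """
    dt = dt if dt is not None else subject_traj.dt
    correct = labels.get("correct_door", "lower")
    is_test = bool(labels.get("is_test", False))
    rel = subject_traj.slice_time(release_time, np.inf)
    if len(rel) == 0:
        raise ValueError("trajectory does not cover the release phase")

    record = TrialRecord(
        subject_traj=subject_traj,
        subject=labels.get("subject", 0),
        condition=labels.get("condition", "individual"),
        batch=labels.get("batch", 1),
        session=labels.get("session", 1),
        is_test=is_test,
        correct_door=correct,
        door_location=labels.get("door_location", "preferred"),
        sex=labels.get("sex", "F"),
        release_time=release_time,
        time_limit_s=time_limit_s,
    )
    if is_test:
        # doors stay closed; no trigger is possible
        record.T = None
        record.censored = None
        return record

    zone = arena.trigger_zone(correct)
    presence = zone_contains_mask(zone, rel.xy) & rel.valid
    # clip the search to the time limit
    n_limit = min(len(presence), int(round(time_limit_s / dt)))
    trig = evaluate_trigger(presence[:n_limit], dt)
    if trig is not None:
        record.T = trig
        record.censored = False
        t_open = release_time + trig
        record.door_events.append(DoorEvent(t_open, correct, "open"))
        record.door_events.append(DoorEvent(t_open + REWARD_S, correct, "close"))
    else:
        if rel.duration + dt < time_limit_s - 1e-9:
            raise ValueError(
                f"trajectory covers only {rel.duration:.1f} s of a "
                f"{time_limit_s:.0f} s untriggered release phase; cannot censor")
        record.T = float(time_limit_s)
        record.censored = True
    return record
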