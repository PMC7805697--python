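"""Deterministic demonstration script for the replica demonstrator.

During the 10-minute confinement phase of a social-training trial the
replica repeats a fixed cycle: 30 s of interaction near the confinement
cylinder, a straight transit to the correct door, 3 s of tail-beating
(which opens that door), a pass through the door, a 5 s pause beyond it, a
two-leg return to the focal region, another 30 s interaction, then an
approach to the incorrect door with 3 s of tail-beating to no effect.
After six cycles the replica transits through the correct door to a final
station facing the stimulus shoal, where it stays until the phase ends.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .arena import ArenaGeometry
from .records import Trajectory
from .swim_sim import SwimParams, simulate_trajectory

__all__ = [
    "Segment",
    "DemonstrationSchedule",
    "build_demo_schedule",
    "replica_position_at",
    "sample_replica_trajectory",
    "PHASE_DURATION_S",
    "InfeasibleScheduleError",
]

#: Length of the confinement/demonstration phase (10 min).
PHASE_DURATION_S = 600.0

#: Fixed dwell durations (s) within each cycle.
INTERACT_S = 30.0
TAILBEAT_S = 3.0
PAUSE_S = 5.0

#: Number of demonstration cycles per session.
CYCLES_PER_SESSION = 6

_HOLD_KINDS = frozenset({"tailbeat_correct", "tailbeat_incorrect",
                         "pause_beyond", "final_station"})
_MOVE_KINDS = frozenset({"transit", "pass_through", "return"})


class InfeasibleScheduleError(ValueError):
    """Raised when the requested cycles do not fit in the phase duration."""


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    kind: str
    target: Tuple[float, float]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DemonstrationSchedule:
    segments: Tuple[Segment, ...]
    cycle_count: int
    phase_duration: float = PHASE_DURATION_S

    def __post_init__(self) -> None:
        segs = self.segments
        if abs(segs[0].start) > 1e-9 or abs(segs[-1].end - self.phase_duration) > 1e-9:
            raise ValueError("segments must tile [0, phase_duration]")
        for a, b in zip(segs, segs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError(f"gap/overlap between segments at t={a.end}")

    def count(self, kind: str) -> int:
        return sum(1 for s in self.segments if s.kind == kind)

    def door_open_events(self) -> int:
        """Passages through the correct door implied by the schedule."""
        return self.count("pass_through")

    def segment_at(self, t: float) -> Segment:
        if not (0.0 <= t <= self.phase_duration):
            raise ValueError(f"t={t} outside [0, {self.phase_duration}]")
        for s in self.segments:
            if s.start <= t < s.end:
                return s
        return self.segments[-1]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_s", "end_s", "kind", "target_x_cm", "target_y_cm"])
            for s in self.segments:
                w.writerow([f"{s.start:.6g}", f"{s.end:.6g}", s.kind,
                            f"{s.target[0]:.6g}", f"{s.target[1]:.6g}"])


def _zone_center(arena: ArenaGeometry, door: str) -> Tuple[float, float]:
    z = arena.trigger_zone(door)
    return ((z.x_min + z.x_max) / 2.0, (z.y_min + z.y_max) / 2.0)


def _dist(a, b) -> float:
    return float(np.hypot(b[0] - a[0], b[1] - a[1]))


def build_demo_schedule(
    arena: ArenaGeometry,
    correct_door: str,
    transit_speed: float = 10.0,
    *,
    phase_duration: float = PHASE_DURATION_S,
    cycles: int = CYCLES_PER_SESSION,
) -> DemonstrationSchedule:
    """Build the demonstration schedule for one session.

    Transit durations are nominal waypoint distance / ``transit_speed``;
    any slack after the last cycle is absorbed into the final station
    segment so that the schedule spans exactly ``phase_duration`` seconds.
    """
    if transit_speed <= 0:
        raise ValueError("transit_speed must be positive")
    incorrect_door = arena.other_door(correct_door)
    cyl = arena.cylinder_center
    p1 = _zone_center(arena, correct_door)                  # focal-side approach
    door_c = arena.door_centers[correct_door]
    depth = arena.trigger_zone_side / 2.0
    p2 = (door_c[0] + depth, door_c[1])                     # beyond the door
    p3 = p1                                                 # back through the door
    p4 = cyl                                                # focal-region return
    p_wrong = _zone_center(arena, incorrect_door)
    p_final = (door_c[0] + 2.0 * arena.trigger_zone_side, door_c[1])

    def transit(kind: str, a, b) -> Tuple[str, float, Tuple[float, float]]:
        return (kind, _dist(a, b) / transit_speed, b)

    cycle_plan = [
        ("interact", INTERACT_S, cyl),
        transit("transit", cyl, p1),
        ("tailbeat_correct", TAILBEAT_S, p1),
        transit("pass_through", p1, p2),
        ("pause_beyond", PAUSE_S, p2),
        transit("return", p2, p3),
        transit("return", p3, p4),
        ("interact", INTERACT_S, cyl),
        transit("transit", cyl, p_wrong),
        ("tailbeat_incorrect", TAILBEAT_S, p_wrong),
    ]
    final_transit = transit("pass_through", p_wrong, p_final)

    cycle_time = sum(d for _, d, _ in cycle_plan)
    needed = cycles * cycle_time + final_transit[1]
    if needed > phase_duration:
        raise InfeasibleScheduleError(
            f"{cycles} cycles need {needed:.1f} s > phase duration "
            f"{phase_duration:.1f} s at transit speed {transit_speed} cm/s")

    segments: List[Segment] = []
    t = 0.0
    for _ in range(cycles):
        for kind, dur, target in cycle_plan:
            segments.append(Segment(t, t + dur, kind, target))
            t += dur
    kind, dur, target = final_transit
    segments.append(Segment(t, t + dur, kind, target))
    t += dur
    segments.append(Segment(t, phase_duration, "final_station", p_final))
    return DemonstrationSchedule(tuple(segments), cycles, phase_duration)


def replica_position_at(
    schedule: DemonstrationSchedule,
    t: float,
    params: SwimParams,
    arena: ArenaGeometry,
) -> Tuple[float, float]:
    """Replica position at time ``t`` (convenience scalar wrapper)."""
    traj = sample_replica_trajectory(schedule, params, arena)
    if not (0.0 <= t <= schedule.phase_duration):
        raise ValueError(f"t={t} outside the demonstration phase")
    k = int(round(t / params.dt))
    k = min(k, len(traj) - 1)
    return (float(traj.xy[k, 0]), float(traj.xy[k, 1]))


def sample_replica_trajectory(
    schedule: DemonstrationSchedule,
    params: SwimParams,
    arena: ArenaGeometry,
) -> Trajectory:
    """Sample the whole schedule on the 20 Hz grid.

    Hold segments keep position; transit segments move linearly from the
    actual position at segment start to the segment target (continuous at
    boundaries); interact segments delegate to the stochastic swim model
    with an attraction point at the confinement-cylinder centre, then snap
    back onto the schedule with a closing linear blend inside the segment.
    Fully reproducible from ``params.seed``.
    """
    dt = params.dt
    n = int(round(schedule.phase_duration / dt))
    t_grid = dt * np.arange(n + 1)
    xy = np.empty((n + 1, 2))
    rng = np.random.default_rng(params.seed)
    pos = np.array(schedule.segments[0].target, dtype=float)
    cyl = np.array(arena.cylinder_center, dtype=float)

    for seg in schedule.segments:
        k0 = int(round(seg.start / dt))
        k1 = int(round(seg.end / dt)) if seg is not schedule.segments[-1] else n
        if k1 < k0:
            continue
        target = np.asarray(seg.target, dtype=float)
        m = k1 - k0
        if seg.kind == "interact":
            sub = simulate_trajectory(
                params, arena, max(m, 1) * dt, tuple(pos),
                attraction_point=tuple(cyl), bounds=arena.focal_bounds,
                rng=rng)
            path = sub.xy[: m + 1].copy()
            # blend the tail back to the scheduled hand-off point so the
            # following transit stays within its nominal duration
            blend = min(m, int(round(2.0 / dt)))
            if blend > 0:
                w = np.linspace(0.0, 1.0, blend + 1)[:, None]
                path[m - blend:] = (1 - w) * path[m - blend:] + w * target
            xy[k0:k1 + 1] = path
        elif seg.kind in _MOVE_KINDS:
            w = np.linspace(0.0, 1.0, m + 1)[:, None] if m else np.ones((1, 1))
            xy[k0:k1 + 1] = (1 - w) * pos + w * target
        elif seg.kind in _HOLD_KINDS:
            xy[k0:k1 + 1] = target
        else:  # pragma: no cover - enumerated kinds
            raise ValueError(f"unknown segment kind {seg.kind!r}")
        pos = xy[k1].copy()

    flags = np.zeros(n + 1, bool)
    return Trajectory(t_grid, xy, ~flags, flags, identity="replica")
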