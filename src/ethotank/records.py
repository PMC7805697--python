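"""Shared data records: trajectories, door events, and per-trial records."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = ["Trajectory", "DoorEvent", "TrialRecord", "DEFAULT_DT", "TIME_LIMIT_S"]

#: Tracking rate is 20 Hz.
DEFAULT_DT = 0.05

#: Release-phase time limit (30 min); unsuccessful trials are right-censored here.
TIME_LIMIT_S = 1800.0


@dataclass
class Trajectory:
    """Uniformly sampled 2D positions for one tracked identity.

    ``valid`` marks samples carrying a usable position estimate;
    ``interpolated`` marks samples filled by prediction rather than
    measurement.  Interpolated samples are still ``valid`` unless the
    predictor gave up.
    """

    t: np.ndarray                 # (n,) seconds, uniform grid
    xy: np.ndarray                # (n, 2) cm
    valid: np.ndarray             # (n,) bool
    interpolated: np.ndarray      # (n,) bool
    identity: str = "subject"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.t)
        if self.xy.shape != (n, 2):
            raise ValueError(f"xy shape {self.xy.shape} does not match {n} timestamps")
        if self.valid.shape != (n,) or self.interpolated.shape != (n,):
            raise ValueError("flag arrays must match the time grid length")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("time grid must be uniform")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            return DEFAULT_DT
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory with t0 <= t <= t1 (boundary-inclusive)."""
        m = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        return Trajectory(self.t[m], self.xy[m], self.valid[m],
                          self.interpolated[m], self.identity)

    @classmethod
    def from_positions(cls, xy: np.ndarray, dt: float = DEFAULT_DT,
                       t0: float = 0.0, identity: str = "subject") -> "Trajectory":
        """Build a fully-valid, non-interpolated trajectory from positions."""
        xy = np.asarray(xy, dtype=float)
        n = len(xy)
        t = t0 + dt * np.arange(n)
        return cls(t, xy, np.ones(n, bool), np.zeros(n, bool), identity)


@dataclass(frozen=True)
class DoorEvent:
    t: float
    door: str                     # "lower" | "upper"
    event: str                    # "open" | "close" | "reward_start" | "reward_end"


@dataclass
class TrialRecord:
    """One trial: release-phase trajectories, design labels, and door events.

    ``T`` is measured from the subject's release, not from trial start.
    ``censored`` implies ``T == time_limit_s`` and no open event for the
    correct door.  Test sessions (doors closed) have ``T is None``.
    """

    subject_traj: Trajectory
    replica_traj: Optional[Trajectory] = None
    subject: int = 0
    condition: str = "individual"     # "individual" | "social"
    batch: int = 1
    session: int = 1                  # training trial 1..20, or test index
    is_test: bool = False
    correct_door: str = "lower"
    door_location: str = "preferred"  # "preferred" | "nonpreferred"
    sex: str = "F"
    release_time: float = 0.0
    time_limit_s: float = TIME_LIMIT_S
    T: Optional[float] = None
    censored: Optional[bool] = None
    door_events: List[DoorEvent] = field(default_factory=list)

    @property
    def labels(self) -> dict:
        return {
            "subject": self.subject,
            "condition": self.condition,
            "batch": self.batch,
            "session": self.session,
            "is_test": self.is_test,
            "correct_door": self.correct_door,
            "door_location": self.door_location,
            "sex": self.sex,
        }

    def scoring_window(self) -> Tuple[float, float]:
        """[release, door opening] window over which metrics are scored.

        Censored trials and test sessions score up to release + limit
        (clipped to the available trajectory).
        """
        t0 = self.release_time
        if self.T is not None and not self.censored:
            return t0, t0 + self.T
        t_end = min(t0 + self.time_limit_s, float(self.subject_traj.t[-1]))
        return t0, t_end
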