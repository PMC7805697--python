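"""Configuration, trajectory I/O, and the end-to-end virtual experiment.

The virtual experiment is a pure function of its configuration: the
master seed determines all child seeds, so re-running the same config
reproduces every trajectory, metric, and statistics table byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, make_default_arena
from .metrics import MetricOptions, metrics_table
from .records import Trajectory, TrialRecord
from .stats import summarize_study
from .swim_sim import CohortDesign, SwimParams, render_frames, simulate_cohort
from .tracking import TrackerConfig, run_trial_session, track_video

__all__ = [
    "ExperimentConfig",
    "run_virtual_experiment",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "TrajectoryParseError",
    "derive_seed",
]

_CSV_COLUMNS = ["t_s", "x_cm", "y_cm", "identity", "valid", "interpolated"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory CSV; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None) -> None:
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


def derive_seed(master: int, *parts) -> int:
    """Stable child seed from the master seed and arbitrary labels."""
    h = hashlib.sha256(repr((master,) + tuple(parts)).encode()).digest()
    return int.from_bytes(h[:8], "little") % (2 ** 63)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run a virtual experiment."""

    arena: ArenaGeometry = field(default_factory=make_default_arena)
    swim: SwimParams = field(default_factory=SwimParams)
    design: CohortDesign = field(default_factory=CohortDesign)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    metric_options: MetricOptions = field(default_factory=MetricOptions)
    mode: str = "ground-truth"          # "ground-truth" | "tracked"
    resolution: Tuple[int, int] = (640, 480)
    master_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("ground-truth", "tracked"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(
            self, master_seed=seed,
            swim=replace(self.swim, seed=derive_seed(seed, "swim")),
            design=replace(self.design, seed=derive_seed(seed, "design")),
        )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "arena": self.arena.to_dict(),
            "swim": asdict(self.swim),
            "design": {**asdict(self.design),
                       "test_sessions": list(self.design.test_sessions)},
            "tracker": asdict(self.tracker),
            "metric_options": {**asdict(self.metric_options),
                               "entropy_grid": list(self.metric_options.entropy_grid)},
            "mode": self.mode,
            "resolution": list(self.resolution),
            "master_seed": self.master_seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = {}
        if "arena" in d:
            kw["arena"] = ArenaGeometry.from_dict(d["arena"])
        if "swim" in d:
            kw["swim"] = SwimParams(**d["swim"])
        if "design" in d:
            dd = dict(d["design"])
            if "test_sessions" in dd:
                dd["test_sessions"] = tuple(dd["test_sessions"])
            kw["design"] = CohortDesign(**dd)
        if "tracker" in d:
            kw["tracker"] = TrackerConfig(**d["tracker"])
        if "metric_options" in d:
            mo = dict(d["metric_options"])
            if "entropy_grid" in mo:
                mo["entropy_grid"] = tuple(mo["entropy_grid"])
            kw["metric_options"] = MetricOptions(**mo)
        for key in ("mode", "master_seed", "out_dir"):
            if key in d:
                kw[key] = d[key]
        if "resolution" in d:
            kw["resolution"] = tuple(d["resolution"])
        return cls(**kw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# trajectory CSV dialect
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write the trajectory CSV dialect (header mandatory, 6 sig digits)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for i in range(len(traj)):
            w.writerow([
                f"{traj.t[i]:.6g}", f"{traj.xy[i, 0]:.6g}", f"{traj.xy[i, 1]:.6g}",
                traj.identity, int(traj.valid[i]), int(traj.interpolated[i]),
            ])


def read_trajectory_csv(path: str | Path,
                        arena: Optional[ArenaGeometry] = None,
                        expected_dt: Optional[float] = None) -> Trajectory:
    """Read the trajectory CSV dialect, validating rows with line numbers."""
    rows: List[tuple] = []
    identity = "subject"
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrajectoryParseError("empty file", line=1)
        if header != _CSV_COLUMNS:
            raise TrajectoryParseError(
                f"bad header {header!r}; expected {_CSV_COLUMNS!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_CSV_COLUMNS):
                raise TrajectoryParseError(
                    f"expected {len(_CSV_COLUMNS)} fields, got {len(row)}",
                    line=lineno)
            try:
                t, x, y = float(row[0]), float(row[1]), float(row[2])
                valid, interp = bool(int(row[4])), bool(int(row[5]))
            except ValueError as exc:
                raise TrajectoryParseError(f"unparseable field: {exc}", line=lineno)
            identity = row[3]
            if arena is not None and valid:
                x0, x1, y0, y1 = arena.tank_bounds
                if not (x0 <= x <= x1 and y0 <= y <= y1):
                    raise TrajectoryParseError(
                        f"position ({x}, {y}) outside the tank", line=lineno)
            rows.append((t, x, y, valid, interp, lineno))
    if not rows:
        raise TrajectoryParseError("no data rows", line=2)
    t = np.array([r[0] for r in rows])
    if len(t) >= 2:
        steps = np.diff(t)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0))
            raise TrajectoryParseError("non-monotone time step",
                                       line=rows[bad + 1][5])
        ref = expected_dt if expected_dt is not None else steps[0]
        off = np.abs(steps - ref) > 1e-6
        if np.any(off):
            bad = int(np.argmax(off))
            raise TrajectoryParseError(
                f"time step {steps[bad]:.6g} != {ref:.6g}", line=rows[bad + 1][5])
    xy = np.array([(r[1], r[2]) for r in rows])
    valid = np.array([r[3] for r in rows])
    interp = np.array([r[4] for r in rows])
    return Trajectory(t, xy, valid, interp, identity=identity)


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

def _track_record(rec: TrialRecord, cfg: ExperimentConfig) -> TrialRecord:
    """Replace the ground-truth trajectory with a tracked reconstruction."""
    frames, calib = render_frames(
        [rec.subject_traj], cfg.arena, cfg.resolution,
        seed=derive_seed(cfg.master_seed, "render", rec.subject, rec.session))
    trajs = track_video(frames, cfg.tracker, calib)
    tracked = trajs["subject"]
    return replace_traj(rec, tracked)


def replace_traj(rec: TrialRecord, traj: Trajectory) -> TrialRecord:
    import copy

    new = copy.copy(rec)
    new.subject_traj = traj
    return new


def run_virtual_experiment(cfg: ExperimentConfig,
                           out_dir: Optional[str | Path] = None,
                           *, write_trajectories: bool = False,
                           analyze: bool = True) -> dict:
    """Simulate the cohort, score every trial, and run the analysis stage.

    Writes ``metrics.csv``, ``events.csv``, ``stats_report.json`` and a
    ``manifest.json`` under the output directory; returns a bundle with
    the in-memory records, metrics table, and stats report.  Pass
    ``analyze=False`` for metric-only runs (e.g. tracker validation on
    cohorts too small for the mixed models).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        records = simulate_cohort(cfg.design, cfg.swim, cfg.arena)
        if cfg.mode == "tracked":
            stage = "track"
            records = [_track_record(r, cfg) for r in records]
        stage = "score"
        scored: List[TrialRecord] = []
        for rec in records:
            out_rec = run_trial_session(
                rec.subject_traj, cfg.arena, rec.labels,
                release_time=rec.release_time, time_limit_s=rec.time_limit_s)
            out_rec.replica_traj = rec.replica_traj
            scored.append(out_rec)
        stage = "metrics"
        table = metrics_table(scored, cfg.arena, cfg.metric_options)
        report = None
        if analyze:
            stage = "analyze"
            training = table[~table["is_test"]]
            tests = table[table["is_test"]]
            report = summarize_study(training, tests)
    except Exception as exc:
        # partial outputs (if any) stay on disk for inspection
        raise RuntimeError(f"virtual experiment failed at stage "
                           f"{stage!r}: {exc}") from exc

    table.to_csv(out / "metrics.csv", index=False, float_format="%.6g")
    with open(out / "events.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "session", "t_s", "door_id", "event"])
        for rec in scored:
            for ev in rec.door_events:
                w.writerow([rec.subject, rec.session, f"{ev.t:.6g}",
                            ev.door, ev.event])
    if report is not None:
        (out / "stats_report.json").write_text(json.dumps(report, indent=2))
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_records": len(scored),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if write_trajectories:
        tdir = out / "trajectories"
        tdir.mkdir(exist_ok=True)
        for rec in scored:
            kind = "test" if rec.is_test else "trial"
            write_trajectory_csv(
                rec.subject_traj,
                tdir / f"s{rec.subject:02d}_{kind}{rec.session:02d}.csv")
    return {"records": scored, "metrics": table, "report": report,
            "out_dir": str(out)}
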