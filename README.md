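# ethotank

A virtual laboratory for a two-door fish choice assay with a robotic
demonstrator. The package simulates burst-and-coast fish swimming in a
74 × 30 cm tank, scripts the demonstrator's door-opening routine, tracks
rendered video by frame differencing with Kalman gap-filling, applies the
"3 s out of any 5 s" door-trigger rule, computes the full set of per-trial
behavioral measures (preference index, reward index, trajectory entropy,
heading error, kinematics, freezing, avoidance, and more), and analyses a
counterbalanced cohort with linear mixed models (type II Wald chi-square
tables, interaction pruning, Bonferroni-corrected alpha, and the
Brown–Forsythe variability test). Learning and side-bias effects can be
injected into the synthetic cohort so that the whole pipeline can be
validated against known ground truth.

## Layout

| module | contents |
| --- | --- |
| `ethotank.arena` | tank geometry, trigger zones, wall bands, width thirds |
| `ethotank.records` | `Trajectory`, `TrialRecord`, door events |
| `ethotank.swim_sim` | burst-and-coast walker, cohort generator, frame renderer |
| `ethotank.replica_protocol` | demonstration schedule and replica sampling |
| `ethotank.tracking` | blob detection, Kalman tracks, trigger rule, trial session |
| `ethotank.metrics` | all per-trial measures and the metrics table |
| `ethotank.stats` | mixed models, type II tables, alpha correction, Levene |
| `ethotank.pipeline` | config, trajectory CSV dialect, end-to-end runner |

## CLI

```sh
ethotank simulate --seed 3 --duration 600 --out traj.csv
ethotank render --traj traj.csv --out frames/
ethotank track --frames frames/ --out tracked/
ethotank score --traj traj.csv --correct-door lower --out metrics.csv
ethotank schedule --correct-door lower --out schedule.csv
ethotank run-experiment --config config.json --seed 1 --out results/
```

`run-experiment` simulates the full counterbalanced cohort (36 subjects,
20 training trials plus tests before training and after trials 10 and
20 by default), scores every trial, and writes `metrics.csv`,
`events.csv`, `stats_report.json`, and a manifest. `--mode tracked`
routes trajectories through the renderer and the video tracker instead of
using simulation ground truth. Configurations are plain JSON; every
geometry, swim, design, tracker, metric, and stats option can be
overridden, and the master seed makes the whole run reproducible byte for
byte.

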