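"""Naive per-sample oracles, independent of the vectorised implementations.

Everything here is deliberately written as plain Python loops over samples
so that it shares no code path with the package.
"""

import math

import numpy as np


def in_rect(p, x_min, x_max, y_min, y_max):
    return x_min <= p[0] <= x_max and y_min <= p[1] <= y_max


def door_times(traj, arena, correct_door, t_end):
    dt = traj.dt
    zc = arena.trigger_zone(correct_door)
    zi = arena.trigger_zone(arena.other_door(correct_door))
    tau_c = tau_i = 0.0
    for i in range(len(traj)):
        if traj.t[i] > t_end + 1e-9 or not traj.valid[i]:
            continue
        p = traj.xy[i]
        if in_rect(p, *zc.as_tuple()):
            tau_c += dt
        if in_rect(p, *zi.as_tuple()):
            tau_i += dt
    pi = tau_c / (tau_c + tau_i) if tau_c + tau_i > 0 else None
    return tau_c, tau_i, pi


def wall_times(traj, arena, t_end):
    dt = traj.dt
    times = [0.0, 0.0, 0.0, 0.0]
    for i in range(len(traj)):
        if traj.t[i] > t_end + 1e-9 or not traj.valid[i]:
            continue
        x, y = traj.xy[i]
        d = [30.0 - x, y, x, 30.0 - y]
        j = min(range(4), key=lambda k: (d[k], k))
        if d[j] <= arena.wall_band:
            times[j] += dt
    total = sum(times)
    ri = times[0] / total if total > 0 else None
    return tuple(times), ri


def entropy_bits(traj, arena, t_end, grid=10):
    counts = {}
    n = 0
    for i in range(len(traj)):
        if traj.t[i] > t_end + 1e-9 or not traj.valid[i]:
            continue
        x, y = traj.xy[i]
        ix = min(grid - 1, max(0, int(x / (30.0 / grid))))
        iy = min(grid - 1, max(0, int(y / (30.0 / grid))))
        counts[(ix, iy)] = counts.get((ix, iy), 0) + 1
        n += 1
    if n == 0:
        return None
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def heading_mean_deg(traj, arena, correct_door, t_end, floor=0.5):
    dt = traj.dt
    door = arena.door_centers[correct_door]
    vals = []
    for i in range(len(traj) - 1):
        if traj.t[i + 1] > t_end + 1e-9:
            break
        if not traj.valid[i] or not traj.valid[i + 1]:
            continue
        if traj.interpolated[i] or traj.interpolated[i + 1]:
            continue
        dx = traj.xy[i + 1] - traj.xy[i]
        speed = math.hypot(dx[0], dx[1]) / dt
        if speed < floor:
            continue
        to_door = (door[0] - traj.xy[i][0], door[1] - traj.xy[i][1])
        nd = math.hypot(*to_door)
        nh = math.hypot(dx[0], dx[1])
        if nd == 0 or nh == 0:
            continue
        c = (dx[0] * to_door[0] + dx[1] * to_door[1]) / (nd * nh)
        vals.append(math.degrees(math.acos(max(-1.0, min(1.0, c)))))
    return (sum(vals) / len(vals)) if vals else None


def kinematics_means(traj, t_end, floor=0.5):
    dt = traj.dt
    v = []
    ok = []
    for i in range(len(traj) - 1):
        dx = traj.xy[i + 1] - traj.xy[i]
        v.append((dx[0] / dt, dx[1] / dt))
        usable = (traj.t[i + 1] <= t_end + 1e-9
                  and traj.valid[i] and traj.valid[i + 1]
                  and not traj.interpolated[i] and not traj.interpolated[i + 1])
        ok.append(usable)
    speeds = [math.hypot(*vi) for vi in v]
    v_vals = [s for s, o in zip(speeds, ok) if o]
    a_vals, w_vals = [], []
    for i in range(len(v) - 1):
        if not (ok[i] and ok[i + 1]):
            continue
        dv = (v[i + 1][0] - v[i][0], v[i + 1][1] - v[i][1])
        a_vals.append(math.hypot(*dv) / dt)
        if speeds[i] >= floor and speeds[i + 1] >= floor:
            c = (v[i][0] * v[i + 1][0] + v[i][1] * v[i + 1][1]) \
                / (speeds[i] * speeds[i + 1])
            w_vals.append(math.acos(max(-1.0, min(1.0, c))) / dt)
    mean = lambda xs: (sum(xs) / len(xs)) if xs else None
    return mean(v_vals), mean(a_vals), mean(w_vals)


def freezing_seconds(traj, t_end, window=2.0, threshold=4.0):
    dt = traj.dt
    n = sum(1 for i in range(len(traj)) if traj.t[i] <= t_end + 1e-9)
    half = int(round(window / 2.0 / dt))
    total = 0.0
    for i in range(n):
        j1 = max(0, i - half)
        j2 = min(n - 1, i + half)
        moved = math.hypot(*(traj.xy[j2] - traj.xy[j1]))
        if moved < threshold and traj.valid[i]:
            total += dt
    return total


def middle_third_fraction(traj, t_end):
    inside = 0
    n = 0
    for i in range(len(traj)):
        if traj.t[i] > t_end + 1e-9 or not traj.valid[i]:
            continue
        y = traj.xy[i][1]
        third = min(2, max(0, int(y / 10.0)))
        inside += third == 1
        n += 1
    return inside / n if n else None
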