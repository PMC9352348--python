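"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int, int]]]:
    """Exhaustive component enumeration on a boolean (T, H, W) grid."""
    offsets = []
    for dt in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dt, dy, dx) == (0, 0, 0):
                    continue
                manhattan = abs(dt) + abs(dy) + abs(dx)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dt, dy, dx))
    T, H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for t in range(T):
        for y in range(H):
            for x in range(W):
                if not mask[t, y, x] or seen[t, y, x]:
                    continue
                comp = set()
                stack = [(t, y, x)]
                seen[t, y, x] = True
                while stack:
                    ct, cy, cx = stack.pop()
                    comp.add((ct, cy, cx))
                    for dt, dy, dx in offsets:
                        nt, ny, nx = ct + dt, cy + dy, cx + dx
                        if 0 <= nt < T and 0 <= ny < H and 0 <= nx < W:
                            if mask[nt, ny, nx] and not seen[nt, ny, nx]:
                                seen[nt, ny, nx] = True
                                stack.append((nt, ny, nx))
                components.append(comp)
    return components


def scan_epochs(
    t: np.ndarray,
    speed: np.ndarray,
    puff_times: list[float],
    kind: str,
) -> list[tuple[float, float]]:
    """Brute-force behavioral segmentation, mirroring the published criteria.

    Scans every sample with explicit python loops: maximal qualifying
    segments, trial-start clamping so the full lookback history exists,
    lookback disqualification, minimum duration, and puff exclusion.
    """
    if kind == "run":
        qualifies = lambda s: s > 30.0
        bad_lookback = lambda s: abs(s) > 20.0
        lookback_s, min_dur = 10.0, 4.0
    elif kind == "quiet":
        qualifies = lambda s: abs(s) < 2.0
        bad_lookback = lambda s: abs(s) > 2.0
        lookback_s, min_dur = 15.0, 10.0
    else:
        raise ValueError(kind)
    dt = t[1] - t[0]
    n = len(t)
    out = []
    i = 0
    while i < n:
        if not qualifies(speed[i]):
            i += 1
            continue
        j = i
        while j < n and qualifies(speed[j]):
            j += 1
        # clamp the start so a full lookback window is sampled
        start = i
        while start < j and t[start] - lookback_s < t[0] - 1e-9:
            start += 1
        ok = start < j and (j - start) * dt >= min_dur - 1e-9
        if ok:
            for s in range(n):
                if t[start] - lookback_s - 1e-9 <= t[s] < t[start] - 1e-9 and bad_lookback(speed[s]):
                    ok = False
                    break
        if ok:
            for tp in puff_times:
                if tp - 1e-9 <= t[start] < tp + 30.0 - 1e-9:
                    ok = False
                    break
        if ok:
            out.append((float(t[start]), float(t[j - 1] + dt)))
        i = j
    return out


def brute_rise_rate(d: np.ndarray, max_window: int) -> float:
    """Exhaustive pair max of D(t2) - D(t1), t1 < t2 <= t1 + window."""
    best = -math.inf
    n = len(d)
    for i in range(n):
        for j in range(i + 1, min(i + max_window, n - 1) + 1):
            best = max(best, d[j] - d[i])
    return best


def brute_nearest_distance(
    point_xyz_um: tuple[float, float, float],
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> float:
    """Exhaustive min distance from a point to true-voxel centers."""
    dx, dy, dz = voxel_size
    px, py, pz = point_xyz_um
    best = math.inf
    Z, H, W = mask.shape
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                if mask[z, y, x]:
                    d = math.sqrt((x * dx - px) ** 2 + (y * dy - py) ** 2 + (z * dz - pz) ** 2)
                    best = min(best, d)
    return best


def random_wheel_trace(rng: np.random.Generator, duration_s: float = 300.0, fs: float = 10.0):
    """Piecewise-constant speed trace straddling the behavioral thresholds."""
    speeds = np.array([0.0, 0.0, 0.0, 1.9, 2.0, 2.5, 10.0, 19.0, 21.0, 25.0, 29.0, 31.0, 35.0, 50.0, -5.0, -25.0])
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    speed = np.zeros(n)
    i = 0
    while i < n:
        seg = int(rng.integers(5, int(20 * fs)))
        speed[i : i + seg] = rng.choice(speeds)
        i += seg
    return t, speed
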