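"""Behavioral-state segmentation from wheel-encoder traces.

Running: a maximal contiguous segment of forward motion above 30°/s lasting
at least 4 s, with no movement above 20°/s (in either direction) during the
10 s before segment start, and not starting within 30 s after an air puff.

Quiet wakefulness: a maximal contiguous segment with |speed| below 2°/s
lasting at least 10 s, preceded by 15 s with no movement above 2°/s, and
not starting within 30 s after an air puff.

At the start of a trial the required lookback history may not exist; an
epoch is then clamped so that its start has the full lookback available
(a segment beginning at t=0 can start, at the earliest, one lookback into
the trial). This conservative rule prevents spurious trial-edge epochs.

Each sample is taken to cover [t_i, t_i + dt), so a segment of n samples
has duration n*dt and the epoch is half-open in seconds.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import AirPuff, Epoch, WheelTrace

__all__ = [
    "detect_runs",
    "detect_quiet",
    "startle_window",
    "startle_trial_valid",
    "max_speed",
    "resample_to_frames",
]

RUN_SPEED_DEG_S = 30.0
RUN_MIN_DURATION_S = 4.0
RUN_LOOKBACK_S = 10.0
RUN_LOOKBACK_SPEED_DEG_S = 20.0
QUIET_SPEED_DEG_S = 2.0
QUIET_MIN_DURATION_S = 10.0
QUIET_LOOKBACK_S = 15.0
PUFF_EXCLUSION_S = 30.0
STARTLE_FRAMES = 600


def _maximal_segments(qualifying: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    q = np.asarray(qualifying, dtype=bool)
    if not q.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], q, [False])).astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _detect_epochs(
    wheel: WheelTrace,
    puffs: list[AirPuff],
    kind: str,
    qualifying: np.ndarray,
    lookback_s: float,
    lookback_bad: np.ndarray,
    min_duration_s: float,
) -> list[Epoch]:
    dt = wheel.dt
    t0 = wheel.t[0]
    epochs: list[Epoch] = []
    for i, j in _maximal_segments(qualifying):
        # clamp start so the full lookback window is sampled
        start = i
        while wheel.t[start] - lookback_s < t0 - 1e-9:
            start += 1
            if start >= j:
                break
        if start >= j:
            continue
        if (j - start) * dt < min_duration_s - 1e-9:
            continue
        t_start = wheel.t[start]
        look = (wheel.t >= t_start - lookback_s - 1e-9) & (wheel.t < t_start - 1e-9)
        if lookback_bad[look].any():
            continue
        if any(p.t_puff - 1e-9 <= t_start < p.t_puff + PUFF_EXCLUSION_S - 1e-9 for p in puffs):
            continue
        epochs.append(Epoch(kind, t_start, wheel.t[j - 1] + dt))
    return epochs


def detect_runs(wheel: WheelTrace, puffs: list[AirPuff] | None = None) -> list[Epoch]:
    """Spontaneous-running epochs (see module docstring for the criteria)."""
    puffs = puffs or []
    return _detect_epochs(
        wheel,
        puffs,
        "run",
        qualifying=wheel.speed > RUN_SPEED_DEG_S,
        lookback_s=RUN_LOOKBACK_S,
        lookback_bad=np.abs(wheel.speed) > RUN_LOOKBACK_SPEED_DEG_S,
        min_duration_s=RUN_MIN_DURATION_S,
    )


def detect_quiet(wheel: WheelTrace, puffs: list[AirPuff] | None = None) -> list[Epoch]:
    """Quiet-wakefulness epochs (see module docstring for the criteria)."""
    puffs = puffs or []
    return _detect_epochs(
        wheel,
        puffs,
        "quiet",
        qualifying=np.abs(wheel.speed) < QUIET_SPEED_DEG_S,
        lookback_s=QUIET_LOOKBACK_S,
        lookback_bad=np.abs(wheel.speed) > QUIET_SPEED_DEG_S,
        min_duration_s=QUIET_MIN_DURATION_S,
    )


def startle_window(puff: AirPuff, fps: float, trial_end: float | None = None) -> Epoch:
    """Startle analysis window: 600 frames (~20 s at 30 Hz) from the puff."""
    end = puff.t_puff + STARTLE_FRAMES / fps
    if trial_end is not None and end > trial_end:
        warnings.warn(
            f"startle window truncated at trial end ({trial_end} s)", stacklevel=2
        )
        end = trial_end
    return Epoch("startle", puff.t_puff, end)


def startle_trial_valid(
    wheel: WheelTrace, puff: AirPuff, lookback: float = 10.0
) -> bool:
    """False if the mouse was running at, or within ``lookback`` s before, the puff."""
    runs = detect_runs(wheel, puffs=[])
    a, b = puff.t_puff - lookback, puff.t_puff
    return not any(ep.start <= b and ep.end > a for ep in runs)


def max_speed(wheel: WheelTrace, epoch: Epoch) -> float:
    """Maximum absolute wheel speed inside the epoch."""
    sel = (wheel.t >= epoch.start - 1e-9) & (wheel.t < epoch.end - 1e-9)
    if not sel.any():
        raise ValueError("epoch contains no wheel samples")
    return float(np.max(np.abs(wheel.speed[sel])))


def resample_to_frames(wheel: WheelTrace, fps: float, n_frames: int) -> np.ndarray:
    """Nearest-neighbor resampling of the speed trace onto the movie frame grid."""
    frame_t = np.arange(n_frames) / fps
    idx = np.clip(np.round((frame_t - wheel.t[0]) / wheel.dt).astype(int), 0, wheel.t.size - 1)
    return wheel.speed[idx]
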