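"""Pupillometry: pupil/eye ratio and the event-locked dilation statistic.

Pupil dilation is the relative increase in the pupil-to-eye diameter ratio
across two 6.67 s windows flanking an event (air-puff or run onset): the
mean ratio after minus the mean ratio before, divided by the mean before.
The statistic is an indirect readout of noradrenergic arousal; it is
invariant to any common rescaling of the two diameters.

Pupil videos are sampled more coarsely than the movies; window means are
taken over the native samples, without interpolation, and the event sample
itself belongs to the "after" window (half-open convention). A window with
no defined sample yields NaN, and such trials are dropped downstream.
"""

from __future__ import annotations

import numpy as np

from .datatypes import PupilTrace

__all__ = ["pupil_ratio", "pupil_dilation", "DILATION_HALF_WINDOW_S"]

DILATION_HALF_WINDOW_S = 6.67


def pupil_ratio(pupil_diam: np.ndarray, eye_diam: np.ndarray) -> np.ndarray:
    """Element-wise pupil/eye ratio; NaN wherever either input is missing."""
    pupil_diam = np.asarray(pupil_diam, dtype=float)
    eye_diam = np.asarray(eye_diam, dtype=float)
    if pupil_diam.shape != eye_diam.shape:
        raise ValueError("pupil and eye traces must have equal shapes")
    defined = ~np.isnan(eye_diam)
    if np.any(eye_diam[defined] <= 0):
        raise ValueError("eye diameter must be positive where defined")
    out = np.full(pupil_diam.shape, np.nan)
    ok = defined & ~np.isnan(pupil_diam)
    out[ok] = pupil_diam[ok] / eye_diam[ok]
    return out


def pupil_dilation(
    trace: PupilTrace | tuple[np.ndarray, np.ndarray],
    event_time: float,
    half_window: float = DILATION_HALF_WINDOW_S,
) -> float:
    """Relative ratio increase across the windows flanking ``event_time``.

    Parameters
    ----------
    trace : a :class:`PupilTrace`, or a ``(t, ratio)`` pair.
    event_time : event onset in seconds (air puff or start of running).
    half_window : window length on each side, seconds.

    Returns NaN when either window has no defined sample.
    """
    if isinstance(trace, PupilTrace):
        t, ratio = trace.t, trace.ratio
    else:
        t, ratio = (np.asarray(a, dtype=float) for a in trace)
    before = (t >= event_time - half_window - 1e-9) & (t < event_time - 1e-9)
    after = (t >= event_time - 1e-9) & (t < event_time + half_window - 1e-9)
    mean_before = np.nanmean(ratio[before]) if np.any(~np.isnan(ratio[before])) else np.nan
    mean_after = np.nanmean(ratio[after]) if np.any(~np.isnan(ratio[after])) else np.nan
    if np.isnan(mean_before) or np.isnan(mean_after) or mean_before == 0:
        return float("nan")
    return float((mean_after - mean_before) / mean_before)
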