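"""Per-epoch response statistics and hierarchical summaries.

The response variables modeled downstream are computed here from the ROA
density trace of a compartment within a behavioral epoch:

* rise rate — the maximal increase in ROA density between any two frames at
  most 50 frames apart inside the epoch (the "maximum acceleration" of the
  Ca2+ response; may be negative for decreasing traces),
* max and mean ROA density over the epoch,
* norepinephrine (GRAB_NE) change — median dF/F0 during the epoch minus the
  median over the 10 s immediately before it, on a ~5 Hz downsampled trace.

Trials with several runs are reduced to their median, and hierarchical
summaries take medians per trial, then per mouse, then per genotype (the
three levels of the hierarchical plots). Medians use the midpoint
convention for even counts throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import DensityTrace, Epoch, NETrace

__all__ = [
    "correct_vascular_artifacts",
    "rise_rate",
    "max_density",
    "mean_density",
    "trial_reduce",
    "hierarchical_medians",
    "downsample_ne",
    "dff",
    "ne_change",
    "RISE_RATE_WINDOW_FRAMES",
    "NE_BASELINE_S",
    "NE_DOWNSAMPLE_FACTOR",
]

RISE_RATE_WINDOW_FRAMES = 50
NE_BASELINE_S = 10.0
NE_DOWNSAMPLE_FACTOR = 6


def correct_vascular_artifacts(raw: np.ndarray, corrector=None) -> np.ndarray:
    """Hook for removing blood-flow dips from norepinephrine-sensor traces.

    Correcting fluorescence dips caused by vessel dilation requires
    vessel-aware software outside this package's scope; pass a callable to
    plug one in. With no corrector the trace passes through unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    return raw if corrector is None else np.asarray(corrector(raw), dtype=float)


def _epoch_values(density: DensityTrace, epoch: Epoch) -> np.ndarray:
    frames = epoch.frames(density.fps, density.values.size)
    return density.values[frames]


def rise_rate(
    density: DensityTrace, epoch: Epoch, max_window_frames: int = RISE_RATE_WINDOW_FRAMES
) -> float:
    """Maximal density increase over at most ``max_window_frames`` frames.

    max over frame pairs t1 < t2 within the epoch, t2 - t1 <= window, of
    D(t2) - D(t1). For a nondecreasing trace on an epoch no longer than the
    window this is exactly D(end) - D(start).
    """
    d = _epoch_values(density, epoch)
    if d.size < 2:
        raise ValueError("rise rate needs an epoch of at least 2 frames")
    best = -np.inf
    for lag in range(1, min(max_window_frames, d.size - 1) + 1):
        best = max(best, float(np.max(d[lag:] - d[:-lag])))
    return best


def max_density(density: DensityTrace, epoch: Epoch) -> float:
    d = _epoch_values(density, epoch)
    if d.size < 1:
        raise ValueError("epoch contains no frames")
    return float(d.max())


def mean_density(density: DensityTrace, epoch: Epoch) -> float:
    d = _epoch_values(density, epoch)
    if d.size < 1:
        raise ValueError("epoch contains no frames")
    return float(d.mean())


def trial_reduce(values) -> float:
    """Per-trial value from multiple runs in one trial: their median."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no values to reduce")
    return float(np.median(values))


def hierarchical_medians(
    table: pd.DataFrame, value: str = "response"
) -> dict[str, pd.DataFrame]:
    """Three-level median summary: trial -> mouse -> genotype.

    ``table`` needs columns ``genotype``, ``mouse``, ``trial`` and ``value``.
    The trial level is the median across rows of a trial (one point per
    trial, e.g. the median over runs), the mouse value is the median of its
    trial values, and the genotype value is the median of its mouse values.
    Empty groups are excluded with a warning.
    """
    for col in ("genotype", "mouse", "trial", value):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    clean = table.dropna(subset=[value])
    if len(clean) < len(table):
        warnings.warn(f"dropped {len(table) - len(clean)} rows with missing {value}", stacklevel=2)
    trial = (
        clean.groupby(["genotype", "mouse", "trial"], sort=True)[value]
        .median()
        .reset_index()
    )
    mouse = trial.groupby(["genotype", "mouse"], sort=True)[value].median().reset_index()
    genotype = mouse.groupby("genotype", sort=True)[value].median().reset_index()
    return {"trial": trial, "mouse": mouse, "genotype": genotype}


def dff(raw: np.ndarray, f0_percentile: float = 10.0) -> np.ndarray:
    """dF/F0 with F0 the per-trace 10th percentile of raw fluorescence."""
    raw = np.asarray(raw, dtype=float)
    f0 = np.percentile(raw, f0_percentile)
    if f0 <= 0:
        raise ValueError("F0 must be positive; trace too dim for a ratio baseline")
    return (raw - f0) / f0


def downsample_ne(
    raw: np.ndarray, fps: float = 30.0, factor: int = NE_DOWNSAMPLE_FACTOR
) -> NETrace:
    """Downsample a ~30 Hz trace to ~5 Hz by non-overlapping bin means.

    A trailing partial bin is discarded. Bin timestamps are the start of
    each bin on the original clock.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size // factor
    if n == 0:
        raise ValueError(f"trace shorter than one {factor}-frame bin")
    binned = raw[: n * factor].reshape(n, factor).mean(axis=1)
    fps_eff = fps / factor
    t = np.arange(n) / fps_eff
    return NETrace(t=t, dff=binned, fps_effective=fps_eff)


def ne_change(trace: NETrace, epoch: Epoch, baseline_s: float = NE_BASELINE_S) -> float:
    """Median dF/F0 inside the epoch minus the median over the preceding baseline.

    The baseline is the ``baseline_s`` seconds immediately before epoch
    start. Responses are positive when fluorescence rises during the epoch.
    Returns NaN when the baseline window is truncated by the trace start.
    """
    if epoch.start - baseline_s < trace.t[0] - 1e-9:
        return float("nan")
    in_epoch = (trace.t >= epoch.start - 1e-9) & (trace.t < epoch.end - 1e-9)
    in_base = (trace.t >= epoch.start - baseline_s - 1e-9) & (trace.t < epoch.start - 1e-9)
    if not in_epoch.any() or not in_base.any():
        return float("nan")
    return float(np.median(trace.dff[in_epoch]) - np.median(trace.dff[in_base]))
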