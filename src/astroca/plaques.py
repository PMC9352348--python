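"""3-D amyloid-plaque mapping and distance-to-activity analysis.

Plaques labeled by methoxy-X04 are imaged as z-stacks at 5 µm steps. The
stack is binarized at a manually chosen threshold, small specks are
removed, and each ROI is assigned the Euclidean distance (µm) from its
centroid to the nearest plaque voxel center,

    RP = sqrt((x_roi - x_plq)^2 + (y_roi - y_plq)^2 + (z_roi - z_plq)^2).

The relation between quiet-wakefulness Ca2+ activity and plaque proximity
is summarized by a linear mixed model: mean ROA density per ROI as the
response, a fixed effect of distance, and a random intercept and slope per
episode (each imaging episode contributes its own fitted line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import morphology

from .datatypes import PlaqueVolume

__all__ = [
    "binarize_stack",
    "remove_small",
    "nearest_plaque_distance",
    "distance_activity_model",
    "DistanceModelFit",
]


def binarize_stack(
    stack: np.ndarray, threshold: float, voxel_size: tuple[float, float, float] = (0.42, 0.42, 5.0)
) -> PlaqueVolume:
    """Binarize a (Z, H, W) intensity stack: voxel true iff intensity > threshold."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (Z, H, W)")
    return PlaqueVolume(mask=stack > threshold, voxel_size=voxel_size)


def remove_small(volume: PlaqueVolume, min_voxels: int = 27) -> PlaqueVolume:
    """Remove 26-connected 3-D components smaller than ``min_voxels``.

    The default (27 voxels, about one 3x3x3 block) discards staining specks
    while keeping dense-core plaques.
    """
    # skimage >= 0.26 spells the threshold max_size and removes size <= max_size
    cleaned = morphology.remove_small_objects(volume.mask, max_size=min_voxels - 1, connectivity=3)
    return PlaqueVolume(mask=cleaned, voxel_size=volume.voxel_size)


def nearest_plaque_distance(roi_um: tuple[float, float, float], volume: PlaqueVolume) -> float:
    """Distance (µm) from an ROI point to the nearest plaque voxel center.

    ``roi_um`` is (x, y, z) in µm in the plaque-volume coordinate frame;
    voxel centers sit at index * voxel_size along each axis. Returns NaN for
    an empty volume (no plaques — distance undefined).
    """
    if not volume.mask.any():
        return float("nan")
    dx, dy, dz = volume.voxel_size
    zyx = np.argwhere(volume.mask)
    centers = np.column_stack((zyx[:, 2] * dx, zyx[:, 1] * dy, zyx[:, 0] * dz))
    dist, _ = cKDTree(centers).query(np.asarray(roi_um, dtype=float))
    return float(dist)


@dataclass
class DistanceModelFit:
    """Fixed-effect distance slope plus per-episode fitted lines."""

    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    episode_lines: pd.DataFrame  # episode, intercept, slope (fixed + random)
    converged: bool
    n_obs: int
    n_episodes: int


def distance_activity_model(table: pd.DataFrame) -> DistanceModelFit:
    """Mixed model of mean ROA density vs. nearest-plaque distance.

    ``table`` needs columns ``episode_id``, ``distance_um`` and
    ``mean_density`` (one row per ROI). Fits
    ``mean_density ~ distance_um`` with a random intercept and random
    distance slope per episode (statsmodels MixedLM, REML). Distance is
    rescaled to 100 µm internally so the random-effect covariance is well
    conditioned; the returned slope is per µm. A singular or non-converged
    fit is reported through ``converged=False``, never silently dropped.
    """
    import statsmodels.formula.api as smf

    for col in ("episode_id", "distance_um", "mean_density"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    counts = table.groupby("episode_id").size()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need at least 2 episodes with at least 3 ROIs each")
    scale = 100.0
    data = table.assign(distance_scaled=table["distance_um"] / scale)
    model = smf.mixedlm(
        "mean_density ~ distance_scaled",
        data=data,
        groups=data["episode_id"],
        re_formula="~distance_scaled",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = model.fit(reml=True)
        if any("failed to converge" in str(w.message).lower() or "singular" in str(w.message).lower()
               for w in caught):
            converged = False
    if not getattr(fit, "converged", True):
        converged = False
    try:
        random_effects = fit.random_effects
    except ValueError:  # singular covariance: no predictable deviations
        converged = False
        zero = pd.Series([0.0, 0.0])
        random_effects = {ep: zero for ep in counts.index}
    lines = []
    for ep, re in random_effects.items():
        lines.append(
            {
                "episode": ep,
                "intercept": float(fit.params["Intercept"] + re.iloc[0]),
                "slope": float(fit.params["distance_scaled"] + re.iloc[1]) / scale,
            }
        )
    return DistanceModelFit(
        slope=float(fit.params["distance_scaled"]) / scale,
        slope_se=float(fit.bse["distance_scaled"]) / scale,
        slope_p=float(fit.pvalues["distance_scaled"]),
        intercept=float(fit.params["Intercept"]),
        episode_lines=pd.DataFrame(lines),
        converged=converged,
        n_obs=len(table),
        n_episodes=len(counts),
    )
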