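"""Event-based Ca2+ signal detection (the ROA method).

The detector turns a registered two-photon movie into regions of activity
(ROAs): connected sets of supra-threshold (x, y, t) voxels. The stages are

1. variance stabilization (square-root transform),
2. boxcar smoothing in time (14 frames ~ 0.47 s at 30 Hz) and space (2 px),
3. a per-pixel threshold: temporal-median baseline plus four times the
   median (across pixels) of the per-pixel temporal standard deviation,
4. strict-greater binarization,
5. spatiotemporal connected-component labeling on the (x, y, t) grid,
6. removal of events shorter than 3 frames or never reaching 3 pixels in a
   single frame,

followed by compartment-wise ROA density traces (percent of a compartment's
pixels active per frame) and event frequencies.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import DetectionParams
from .datatypes import CompartmentMap, DensityTrace, Movie, ROAEvent, ROASet

__all__ = [
    "variance_stabilize",
    "smooth",
    "estimate_thresholds",
    "binarize",
    "label_events",
    "filter_events",
    "roa_density",
    "roa_frequency",
    "detect",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def variance_stabilize(movie: Movie) -> Movie:
    """Square-root transform, stabilizing Poisson-like photon noise."""
    bad = np.where((movie.data < 0).any(axis=(1, 2)))[0]
    if bad.size:
        raise ValueError(f"negative fluorescence in frame(s) {bad[:5].tolist()}; cannot take square root")
    return movie.with_data(np.sqrt(movie.data))


def _truncated_boxcar(data: np.ndarray, size: int, axis: int) -> np.ndarray:
    """Boxcar mean along ``axis`` with truncated-window renormalization.

    Near the array boundary the mean is taken over the samples that exist
    (zero-padded sum divided by the in-bounds window fraction), so constant
    inputs stay constant everywhere.
    """
    if size <= 1:
        return data
    num = ndimage.uniform_filter1d(data, size, axis=axis, mode="constant", cval=0.0)
    den = ndimage.uniform_filter1d(np.ones(data.shape[axis]), size, mode="constant", cval=0.0)
    shape = [1] * data.ndim
    shape[axis] = data.shape[axis]
    return num / den.reshape(shape)


def smooth(movie: Movie, params: DetectionParams) -> Movie:
    """Separable boxcar smoothing: temporal then spatial."""
    if params.t_smooth_frames > movie.n_frames:
        raise ValueError("temporal smoothing window exceeds movie length")
    data = np.asarray(movie.data, dtype=np.float64)
    data = _truncated_boxcar(data, params.t_smooth_frames, axis=0)
    spatial = 2 * params.s_smooth_pixels + 1
    data = _truncated_boxcar(data, spatial, axis=1)
    data = _truncated_boxcar(data, spatial, axis=2)
    return movie.with_data(data)


def estimate_thresholds(smoothed: Movie, params: DetectionParams) -> np.ndarray:
    """Per-pixel detection threshold image.

    baseline_p = temporal median of pixel p's (stabilized, smoothed) trace;
    the noise scale is the median over pixels of the per-pixel temporal SD
    (sample SD, ddof=1), or each pixel's own SD when ``per_pixel_sigma``;
    threshold_p = baseline_p + k * sigma.
    """
    if smoothed.n_frames < 3:
        raise ValueError("need at least 3 frames to estimate noise")
    baseline = np.median(smoothed.data, axis=0)
    sd = np.std(smoothed.data, axis=0, ddof=1)
    sigma = sd if params.per_pixel_sigma else np.median(sd)
    return baseline + params.k_threshold * sigma


def binarize(smoothed: Movie, thresholds: np.ndarray) -> np.ndarray:
    """Activity mask: strictly above threshold (a tie is inactive)."""
    thresholds = np.asarray(thresholds)
    if thresholds.shape != smoothed.frame_shape:
        raise ValueError(
            f"threshold image shape {thresholds.shape} does not match frame shape {smoothed.frame_shape}"
        )
    return smoothed.data > thresholds[None, :, :]


def label_events(mask: np.ndarray, connectivity: int = 26) -> ROASet:
    """Connected components of the activity mask on the (x, y, t) grid."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    events = []
    if n:
        # one pass: gather voxel coordinates per component
        coords = np.argwhere(labeled > 0)
        ids = labeled[coords[:, 0], coords[:, 1], coords[:, 2]]
        order = np.argsort(ids, kind="stable")
        coords, ids = coords[order], ids[order]
        splits = np.searchsorted(ids, np.arange(2, n + 1))
        for vox in np.split(coords, splits):
            events.append(ROAEvent(vox))
    return ROASet(events=events, shape=mask.shape, connectivity=connectivity)


def filter_events(roas: ROASet, params: DetectionParams) -> ROASet:
    """Drop events that are too brief or never large enough in one frame.

    The two criteria are independent exclusion rules: an event is removed if
    its duration is below ``min_duration_frames`` OR its maximum single-frame
    area is below ``min_area_px``. Both thresholds are inclusive (an event of
    exactly 3 frames and 3 pixels in its largest frame is retained).
    """
    kept = [
        ev
        for ev in roas.events
        if ev.duration >= params.min_duration_frames and ev.max_frame_area >= params.min_area_px
    ]
    return ROASet(events=kept, shape=roas.shape, connectivity=roas.connectivity)


def roa_density(
    roas: ROASet | np.ndarray,
    compartments: CompartmentMap,
    region: str,
    fps: float = 30.0,
) -> DensityTrace:
    """Percent of a compartment's pixels active at each frame."""
    region_mask = compartments.region_mask(region)
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError(f"region {region!r} contains no pixels")
    mask = roas.mask() if isinstance(roas, ROASet) else np.asarray(roas, dtype=bool)
    active = mask[:, region_mask].sum(axis=1)
    values = 100.0 * active / n_region
    return DensityTrace(values=values, region_label=region, n_region_pixels=n_region, fps=fps)


def roa_frequency(
    roas: ROASet,
    compartments: CompartmentMap,
    region: str,
    window: tuple[float, float],
    fps: float = 30.0,
    um_per_pixel: float = 0.42,
) -> float:
    """Event rate in a region, in events per 100 µm² per minute.

    Counts events whose onset frame falls inside ``window`` (seconds,
    half-open) and whose voxels intersect the region.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    region_mask = compartments.region_mask(region)
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError(f"region {region!r} contains no pixels")
    count = 0
    for ev in roas:
        if not t0 <= ev.t_onset / fps < t1:
            continue
        if region_mask[ev.voxels[:, 1], ev.voxels[:, 2]].any():
            count += 1
    area_100um2 = n_region * um_per_pixel**2 / 100.0
    minutes = (t1 - t0) / 60.0
    return count / area_100um2 / minutes


def detect(
    movie: Movie,
    compartments: CompartmentMap,
    params: DetectionParams | None = None,
) -> tuple[ROASet, dict[str, DensityTrace]]:
    """Full ROA detection: stabilize, smooth, threshold, label, filter.

    Returns the post-filter event set and one density trace per compartment
    class present in the map (always including the full field of view).
    """
    params = params or DetectionParams()
    stabilized = variance_stabilize(movie)
    smoothed = smooth(stabilized, params)
    thresholds = estimate_thresholds(smoothed, params)
    mask = binarize(smoothed, thresholds)
    roas = filter_events(label_events(mask, params.connectivity), params)
    event_mask = roas.mask()
    densities = {
        cls: roa_density(event_mask, compartments, cls, fps=movie.fps)
        for cls in compartments.present_classes()
    }
    return roas, densities
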