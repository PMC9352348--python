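"""Core in-memory containers shared by the pipeline stages.

Conventions
-----------
* Movies are ``(T, H, W)`` arrays; frame/pixel indices are 0-based.
* Voxel coordinates are stored ``(t, y, x)``.
* Time intervals (epochs) are half-open ``[start, end)`` in seconds on the
  trial clock; frame ``f`` belongs to an epoch iff ``f / fps`` lies in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Movie",
    "CompartmentMap",
    "ROAEvent",
    "ROASet",
    "DensityTrace",
    "Epoch",
    "AirPuff",
    "WheelTrace",
    "PupilTrace",
    "NETrace",
    "PlaqueVolume",
    "COMPARTMENT_CLASSES",
]

#: Recognised compartment classes. ``fov`` denotes all analyzable pixels.
COMPARTMENT_CLASSES = ("fov", "soma", "process", "endfoot")


@dataclass
class Movie:
    """A fluorescence time series: ``data[t, y, x]`` at ``fps`` frames/s."""

    data: np.ndarray
    fps: float = 30.0
    um_per_pixel: float = 0.42
    depth_um: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"movie data must be (T, H, W) with T >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie data contains non-finite values")
        if self.fps <= 0 or self.um_per_pixel <= 0:
            raise ValueError("fps and um_per_pixel must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def with_data(self, data: np.ndarray) -> "Movie":
        """Return a new movie with the same metadata but different data."""
        return Movie(data, fps=self.fps, um_per_pixel=self.um_per_pixel, depth_um=self.depth_um)


@dataclass
class CompartmentMap:
    """Label image plus a class for every nonzero label.

    The field of view ("fov") is defined as the union of all nonzero labels;
    the other classes are unions of the labels assigned to them.
    """

    labels: np.ndarray
    classes: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.classes)
        if missing:
            raise ValueError(f"labels without a class assignment: {sorted(missing)}")
        bad = set(self.classes.values()) - set(COMPARTMENT_CLASSES)
        if bad:
            raise ValueError(f"unknown compartment classes: {sorted(bad)}")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean pixel mask of a compartment class.

        ``fov`` covers every labeled (analyzable) pixel regardless of class.
        """
        if region == "fov":
            return self.labels > 0
        labels = [lab for lab, cls in self.classes.items() if cls == region]
        return np.isin(self.labels, labels)

    def present_classes(self) -> list[str]:
        present = {self.classes[lab] for lab in np.unique(self.labels) if lab != 0}
        out = ["fov"] if (self.labels > 0).any() else []
        out += [c for c in COMPARTMENT_CLASSES if c != "fov" and c in present]
        return out


@dataclass
class ROAEvent:
    """One region of activity: a connected set of supra-threshold voxels."""

    voxels: np.ndarray  # (n, 3) int array of (t, y, x)
    t_onset: int = field(init=False)
    t_offset: int = field(init=False)
    duration: int = field(init=False)
    frame_areas: np.ndarray = field(init=False)  # pixel count per frame, t_onset..t_offset
    max_frame_area: int = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.intp)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise ValueError("voxels must be a non-empty (n, 3) array of (t, y, x)")
        self.voxels = v
        t = v[:, 0]
        self.t_onset = int(t.min())
        self.t_offset = int(t.max())
        self.duration = self.t_offset - self.t_onset + 1
        self.frame_areas = np.bincount(t - self.t_onset, minlength=self.duration)
        self.max_frame_area = int(self.frame_areas.max())

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def centroid(self) -> tuple[float, float]:
        """(y, x) centroid over all voxels."""
        return float(self.voxels[:, 1].mean()), float(self.voxels[:, 2].mean())


@dataclass
class ROASet:
    """Collection of detected events on a movie grid of known shape."""

    events: list[ROAEvent]
    shape: tuple[int, int, int]
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def mask(self) -> np.ndarray:
        """Boolean (T, H, W) activity mask of all events."""
        out = np.zeros(self.shape, dtype=bool)
        for ev in self.events:
            out[ev.voxels[:, 0], ev.voxels[:, 1], ev.voxels[:, 2]] = True
        return out


@dataclass
class DensityTrace:
    """Per-frame percent of a region's pixels that are active."""

    values: np.ndarray
    region_label: str
    n_region_pixels: int
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("density values must be 1-D (one per frame)")
        if self.n_region_pixels <= 0:
            raise ValueError("region must contain at least one pixel")
        if np.any(self.values < -1e-9) or np.any(self.values > 100 + 1e-9):
            raise ValueError("density values must lie in [0, 100]")


EPOCH_KINDS = ("run", "quiet", "startle", "baseline")


@dataclass(frozen=True)
class Epoch:
    """Labeled half-open interval [start, end) in seconds."""

    kind: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if not self.end > self.start:
            raise ValueError("epoch end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def frames(self, fps: float, n_frames: int | None = None) -> np.ndarray:
        """Frame indices whose time f/fps falls inside the epoch."""
        lo = int(np.ceil(self.start * fps - 1e-9))
        hi = int(np.ceil(self.end * fps - 1e-9))  # exclusive
        lo = max(lo, 0)
        if n_frames is not None:
            hi = min(hi, n_frames)
        return np.arange(lo, max(hi, lo))

    def shift(self, dt: float) -> "Epoch":
        return Epoch(self.kind, self.start + dt, self.end + dt)


@dataclass(frozen=True)
class AirPuff:
    """Air-puff stimulus onset (a 1 s train of 10 puffs at 10 Hz in vivo)."""

    t_puff: float = 150.0
    n_puffs: int = 10
    rate_hz: float = 10.0


@dataclass
class WheelTrace:
    """Wheel-encoder speed trace on a uniform time grid (forward positive)."""

    t: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.t.shape != self.speed.shape or self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("t and speed must be equal-length 1-D arrays (>= 2 samples)")
        if not np.all(np.isfinite(self.speed)):
            raise ValueError("speed contains non-finite values")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("wheel trace must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class PupilTrace:
    """Pupil and eye diameters (pixels); NaN marks missing samples."""

    t: np.ndarray
    pupil_diam: np.ndarray
    eye_diam: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pupil_diam = np.asarray(self.pupil_diam, dtype=float)
        self.eye_diam = np.asarray(self.eye_diam, dtype=float)
        if not (self.t.shape == self.pupil_diam.shape == self.eye_diam.shape):
            raise ValueError("t, pupil_diam and eye_diam must have equal shapes")
        defined = ~np.isnan(self.eye_diam)
        if np.any(self.eye_diam[defined] <= 0):
            raise ValueError("eye diameter must be positive where defined")

    @property
    def ratio(self) -> np.ndarray:
        """Pupil/eye ratio; NaN wherever either diameter is missing."""
        out = np.full_like(self.pupil_diam, np.nan)
        ok = ~np.isnan(self.pupil_diam) & ~np.isnan(self.eye_diam)
        out[ok] = self.pupil_diam[ok] / self.eye_diam[ok]
        return out


@dataclass
class NETrace:
    """Norepinephrine sensor dF/F0 trace, typically downsampled to ~5 Hz."""

    t: np.ndarray
    dff: np.ndarray
    fps_effective: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape:
            raise ValueError("t and dff must have equal shapes")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")


@dataclass
class PlaqueVolume:
    """Binary plaque mask on a (Z, H, W) grid with anisotropic voxels (µm)."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.42, 0.42, 5.0)  # (dx, dy, dz)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("plaque mask must be (Z, H, W)")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
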