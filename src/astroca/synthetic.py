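"""Synthetic two-photon data with known ground truth.

Everything downstream — ROA detection, behavioral segmentation, pupil
coupling, the mixed models — is exercised on data generated here, so each
generator emits both the observable (movie, trace, cohort table) and the
ground truth it was built from.

Movies are a constant baseline plus GCaMP6f-like transients (difference of
exponentials, 0.1 s rise / 0.6 s decay) on contiguous disk-shaped pixel
patches, plus i.i.d. Gaussian noise, clipped at zero. A voxel belongs to an
event's ground truth iff its noiseless event contribution reaches half the
event amplitude; the kernel is truncated at that same half-amplitude level,
so an implanted event's support coincides with its declared ground truth
and voxel-level recall/precision are well defined.

Each generator is a pure function of its configuration: a fixed seed gives
byte-identical output. Generators draw from independent child streams of
the configured seed, so they are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortCoefficients, SimulationConfig
from .datatypes import AirPuff, CompartmentMap, Epoch, Movie, PupilTrace, WheelTrace

__all__ = [
    "GroundTruth",
    "generate_movie",
    "generate_wheel_trace",
    "generate_pupil_trace",
    "generate_cohort",
    "generate_plaque_stack",
    "generate_compartments",
    "generate_ne_trace",
]

# fixed child-stream tags so each generator has its own reproducible stream
_STREAMS = {"movie": 1, "wheel": 2, "pupil": 3, "cohort": 4, "plaque": 5, "ne": 6}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


@dataclass
class GroundTruth:
    """What the generators actually put in: the targets for every stage."""

    event_voxels: list[np.ndarray] = field(default_factory=list)  # (n, 3) (t, y, x) per event
    epoch_labels: list[Epoch] = field(default_factory=list)
    true_coeffs: CohortCoefficients | None = None
    plaque_centers_um: list[tuple[float, float, float]] = field(default_factory=list)
    mouse_intercepts: dict[str, float] = field(default_factory=dict)

    def event_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for vox in self.event_voxels:
            out[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        return out


def _event_kernel(config: SimulationConfig) -> np.ndarray:
    """Normalized transient sampled on the frame grid, truncated at the
    half-amplitude (ground-truth membership) level."""
    tr, td = config.event_rise_tau, config.event_decay_tau
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    # sample generously past the decay, then truncate to the support
    t = np.arange(0.0, t_peak + td * 12, 1.0 / config.fps)
    k = (np.exp(-t / td) - np.exp(-t / tr)) / (
        np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    )
    return k[k >= config.event_support_frac]


def generate_movie(config: SimulationConfig) -> tuple[Movie, GroundTruth]:
    """Baseline + implanted transients + Gaussian noise, clipped at zero.

    Events are placed with disjoint space-time footprints (padded so that
    detector smoothing cannot merge neighbours); a configuration whose
    event patch cannot fit the frame is rejected.
    """
    rng = _rng(config, "movie")
    H, W = config.frame_shape
    T = int(round(config.duration * config.fps))
    r = config.event_radius_px
    if 2 * r + 1 > min(H, W):
        raise ValueError("event patch larger than frame; reduce event_radius_px")
    kernel = _event_kernel(config)
    if kernel.size + 1 > T:
        raise ValueError("movie too short for one event transient")

    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    disk = yy**2 + xx**2 <= r**2
    pad_xy = r + 2 * 3 + 2  # spatial footprint + smoothing halo margin
    pad_t = kernel.size + 21  # temporal footprint + smoothing halo margin

    data = np.full((T, H, W), float(config.baseline_level))
    truth = GroundTruth()
    placed: list[tuple[int, int, int]] = []  # (t0, cy, cx)
    for _ in range(config.n_events):
        for _attempt in range(2000):
            t0 = int(rng.integers(0, T - kernel.size))
            cy = int(rng.integers(r, H - r))
            cx = int(rng.integers(r, W - r))
            if all(
                abs(t0 - p[0]) >= pad_t or abs(cy - p[1]) >= pad_xy or abs(cx - p[2]) >= pad_xy
                for p in placed
            ):
                break
        else:
            raise ValueError(
                f"could not place {config.n_events} non-overlapping events; "
                "reduce n_events or enlarge the movie"
            )
        placed.append((t0, cy, cx))
        ys, xs = np.nonzero(disk)
        ys, xs = ys + cy - r, xs + cx - r
        for i, kv in enumerate(kernel):
            data[t0 + i, ys, xs] += config.event_amplitude * kv
        tt = np.repeat(np.arange(t0, t0 + kernel.size), ys.size)
        truth.event_voxels.append(
            np.column_stack((tt, np.tile(ys, kernel.size), np.tile(xs, kernel.size)))
        )
    if config.noise_sigma > 0:
        data += config.noise_sigma * rng.standard_normal(data.shape)
        np.clip(data, 0.0, None, out=data)
    movie = Movie(data, fps=config.fps, um_per_pixel=config.um_per_pixel)
    return movie, truth


def generate_wheel_trace(
    config: SimulationConfig, run_spec: list[tuple[float, float, float]]
) -> WheelTrace:
    """Piecewise-constant speed trace: zero outside the requested runs.

    ``run_spec`` rows are (start s, duration s, speed °/s); runs must not
    overlap.
    """
    T = int(round(config.duration * config.fps))
    t = np.arange(T) / config.fps
    speed = np.zeros(T)
    ordered = sorted(run_spec, key=lambda r: r[0])
    for (s0, d0, _), (s1, _, _) in zip(ordered, ordered[1:]):
        if s0 + d0 > s1 + 1e-9:
            raise ValueError("run specifications overlap")
    for start, dur, sp in ordered:
        if dur <= 0:
            raise ValueError("run duration must be positive")
        speed[(t >= start - 1e-9) & (t < start + dur - 1e-9)] = sp
    return WheelTrace(t=t, speed=speed)


def generate_pupil_trace(
    config: SimulationConfig,
    epochs: list[Epoch],
    coupling_slope: float,
    arousal: list[float] | None = None,
    sustained: bool = False,
) -> PupilTrace:
    """Pupil/eye ratio trace with dilation responses at epoch onsets.

    Each epoch onset adds a relative ratio increase of
    ``coupling_slope * arousal + noise`` that decays exponentially
    (``pupil_decay_tau``), mimicking the sharp rise and gradual decline of
    arousal-evoked dilations. With ``sustained=True`` the response is a step
    (no decay), convenient for exact window arithmetic.
    """
    rng = _rng(config, "pupil")
    n = int(round(config.duration * config.pupil_fps))
    t = np.arange(n) / config.pupil_fps
    ratio = np.full(n, config.pupil_baseline_ratio)
    arousal = arousal if arousal is not None else [1.0] * len(epochs)
    if len(arousal) != len(epochs):
        raise ValueError("need one arousal magnitude per epoch")
    for ep, a in zip(epochs, arousal):
        amp = coupling_slope * a + (
            config.pupil_noise_sd * rng.standard_normal() if config.pupil_noise_sd > 0 else 0.0
        )
        after = t >= ep.start - 1e-9
        shape = 1.0 if sustained else np.exp(-(t[after] - ep.start) / config.pupil_decay_tau)
        ratio[after] += config.pupil_baseline_ratio * amp * shape
    eye = np.full(n, config.pupil_eye_diam_px)
    return PupilTrace(t=t, pupil_diam=ratio * eye, eye_diam=eye)


def generate_cohort(
    config: SimulationConfig, n_episodes: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Hierarchical trial table from the mixed-model data-generating process.

    Mice get random intercepts N(0, sigma_mouse^2); each episode draws its
    covariates (pupil dilation, depth, magnification, max speed) uniformly
    from the study's recording ranges and its response from the linear
    predictor plus mouse intercept plus genotype-specific residual noise.
    ``n_episodes`` (total, spread as evenly as possible across mice)
    overrides ``trials_per_mouse``.
    """
    if config.n_mice_per_genotype < 2:
        raise ValueError("need at least 2 mice per genotype for an identifiable model")
    rng = _rng(config, "cohort")
    c = config.coeffs
    mice = [(f"{g}{i}", g) for g in ("TG", "WT") for i in range(config.n_mice_per_genotype)]
    n_mice = len(mice)
    if n_episodes is None:
        counts = [config.trials_per_mouse] * n_mice
    else:
        base, extra = divmod(n_episodes, n_mice)
        counts = [base + (1 if i < extra else 0) for i in range(n_mice)]
    truth = GroundTruth(true_coeffs=c)
    rows = []
    trial = 0
    for (mouse, geno), k in zip(mice, counts):
        b = rng.normal(0.0, c.sigma_mouse) if c.sigma_mouse > 0 else 0.0
        truth.mouse_intercepts[mouse] = b
        for _ in range(k):
            pupil = rng.uniform(*config.pupil_dilation_range)
            depth = rng.uniform(*config.depth_range_um)
            umpp = float(rng.choice(config.um_per_pixel_levels))
            speed = rng.uniform(*config.max_speed_range)
            wt = 1.0 if geno == "WT" else 0.0
            umpp_high = 1.0 if umpp == max(config.um_per_pixel_levels) else 0.0
            mu = (
                c.intercept_tg
                + c.beta_genotype_wt * wt
                + c.beta_pupil_tg * pupil
                + c.beta_interaction_wt * pupil * wt
                + c.beta_umpp * umpp_high
                + c.beta_depth * depth
                + c.beta_maxspeed * speed
            )
            sigma = c.sigma_resid_wt if geno == "WT" else c.sigma_resid_tg
            resp = mu + b + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            rows.append(
                {
                    "trial": f"t{trial:04d}",
                    "mouse": mouse,
                    "genotype": geno,
                    "pupil_dilation": pupil,
                    "depth_um": depth,
                    "um_per_pixel": umpp,
                    "max_speed": speed,
                    "response": resp,
                    "linear_predictor": mu,
                }
            )
            trial += 1
    return pd.DataFrame(rows), truth


def generate_plaque_stack(
    config: SimulationConfig,
    centers_um: list[tuple[float, float, float]],
    radii_um: list[float],
    n_slices: int = 40,
) -> np.ndarray:
    """Boolean (Z, H, W) volume of spherical plaques.

    Voxel size is (um_per_pixel, um_per_pixel, 5 µm); a voxel is true when
    its center lies within a sphere. Centers outside the volume are
    rejected.
    """
    H, W = config.frame_shape
    dx = dy = config.um_per_pixel
    dz = 5.0
    extent = (W * dx, H * dy, n_slices * dz)
    for cx, cy, cz in centers_um:
        if not (0 <= cx <= extent[0] and 0 <= cy <= extent[1] and 0 <= cz <= extent[2]):
            raise ValueError(f"plaque center {(cx, cy, cz)} outside volume extent {extent}")
    if len(radii_um) != len(centers_um):
        raise ValueError("need one radius per center")
    z = np.arange(n_slices)[:, None, None] * dz
    y = np.arange(H)[None, :, None] * dy
    x = np.arange(W)[None, None, :] * dx
    mask = np.zeros((n_slices, H, W), dtype=bool)
    for (cx, cy, cz), rad in zip(centers_um, radii_um):
        mask |= (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= rad**2
    return mask


def generate_compartments(
    frame_shape: tuple[int, int] = (128, 128), n_cells: int = 4
) -> CompartmentMap:
    """Deterministic astrocyte-territory layout for synthetic movies.

    Somata (disks) surrounded by process annuli with one endfoot patch
    each, on a regular grid; remaining pixels form a neuropil region of
    class ``fov`` so the full frame is analyzable.
    """
    H, W = frame_shape
    labels = np.ones((H, W), dtype=np.int32)  # label 1 = neuropil (fov)
    classes = {1: "fov"}
    grid = int(np.ceil(np.sqrt(n_cells)))
    soma_r, proc_r, endfoot_r = 6, 12, 3
    lab = 2
    yy, xx = np.mgrid[0:H, 0:W]
    for i in range(n_cells):
        gy, gx = divmod(i, grid)
        cy = int((gy + 0.5) * H / grid)
        cx = int((gx + 0.5) * W / grid)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        labels[d2 <= proc_r**2] = lab
        classes[lab] = "process"
        labels[d2 <= soma_r**2] = lab + 1
        classes[lab + 1] = "soma"
        ey, ex = cy + proc_r + endfoot_r, cx
        if ey + endfoot_r < H:
            labels[(yy - ey) ** 2 + (xx - ex) ** 2 <= endfoot_r**2] = lab + 2
            classes[lab + 2] = "endfoot"
        lab += 3
    return CompartmentMap(labels=labels, classes=classes)


def generate_ne_trace(
    config: SimulationConfig,
    epochs: list[Epoch],
    amplitudes: list[float] | None = None,
    f0: float = 100.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Raw ~30 Hz norepinephrine-sensor fluorescence with epoch responses.

    Fluorescence steps up by ``amplitude * f0`` during each epoch and
    relaxes back outside it; meant to be passed through ``dff`` and
    ``downsample_ne``.
    """
    rng = _rng(config, "ne")
    T = int(round(config.duration * config.fps))
    t = np.arange(T) / config.fps
    f = np.full(T, f0)
    amplitudes = amplitudes if amplitudes is not None else [0.05] * len(epochs)
    for ep, a in zip(epochs, amplitudes):
        f[(t >= ep.start - 1e-9) & (t < ep.end - 1e-9)] += a * f0
    if noise_sd > 0:
        f += noise_sd * rng.standard_normal(T)
    return f


def default_puff(config: SimulationConfig) -> AirPuff:
    """The study's stimulus: an air puff at 150 s of a 300 s trial."""
    return AirPuff(t_puff=min(150.0, config.duration / 2))
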