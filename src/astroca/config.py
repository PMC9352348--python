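"""Parameter containers for detection and simulation.

Defaults mirror the acquisition and analysis settings of the study design
this package implements: 30 Hz two-photon movies at 0.42 or 0.67 µm/pixel,
14-frame/2-pixel smoothing, a 4x median-SD detection threshold, and
3-pixel/3-frame event filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["DetectionParams", "CohortCoefficients", "SimulationConfig"]


@dataclass
class DetectionParams:
    """Tunable parameters of the ROA (region of activity) detector.

    Attributes
    ----------
    t_smooth_frames : temporal boxcar width in frames (14 ≈ 0.47 s at 30 Hz).
    s_smooth_pixels : spatial half-width; the boxcar is (2s+1) x (2s+1).
    k_threshold : noise multiplier; threshold = baseline + k * sigma.
    min_area_px : smallest acceptable maximum single-frame area of an event.
    min_duration_frames : smallest acceptable event duration.
    connectivity : voxel adjacency on the (x, y, t) grid: 6, 18 or 26.
    per_pixel_sigma : use each pixel's own temporal SD instead of the global
        median SD (both readings of "median standard deviation" are offered).
    snr_target : informational; the smoothing widths above were chosen to
        reach a signal-to-noise ratio of about this value, they are not
        adapted at run time.
    """

    t_smooth_frames: int = 14
    s_smooth_pixels: int = 2
    k_threshold: float = 4.0
    min_area_px: int = 3
    min_duration_frames: int = 3
    connectivity: int = 26
    per_pixel_sigma: bool = False
    snr_target: float = 9.0

    def __post_init__(self) -> None:
        if self.t_smooth_frames < 1 or self.s_smooth_pixels < 0:
            raise ValueError("smoothing widths must be positive")
        if self.k_threshold <= 0 or self.min_area_px < 1 or self.min_duration_frames < 1:
            raise ValueError("threshold multiplier and filter sizes must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortCoefficients:
    """Fixed and random effects of the trial-level data-generating process.

    The linear predictor (TG is the reference genotype) is::

        response = intercept_tg
                 + beta_genotype_wt * [WT]
                 + beta_pupil_tg * pupil
                 + beta_interaction_wt * pupil * [WT]
                 + beta_umpp * [um_per_pixel == high]
                 + beta_depth * depth_um
                 + beta_maxspeed * max_speed

    plus a per-mouse random intercept N(0, sigma_mouse^2) and residual noise
    whose SD may differ by genotype. Default magnitudes follow the published
    running-trial model for ROA density rise rate in the field of view
    (interaction 1.1562, genotype -0.1245, etc.; depth enters per µm).
    """

    intercept_tg: float = 0.2297
    beta_genotype_wt: float = -0.1245
    beta_pupil_tg: float = -0.3537
    beta_interaction_wt: float = 1.1562
    beta_umpp: float = 0.0306
    beta_depth: float = -0.000409
    beta_maxspeed: float = -0.0011
    sigma_mouse: float = 0.05
    sigma_resid_tg: float = 0.10
    sigma_resid_wt: float = 0.10

    def __post_init__(self) -> None:
        if min(self.sigma_mouse, self.sigma_resid_tg, self.sigma_resid_wt) < 0:
            raise ValueError("standard deviations must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationConfig:
    """Study-conditions configuration for the synthetic-data generators.

    A fixed ``seed`` makes every generator byte-identical between runs.
    Frame geometry defaults to 128x128 (a test-scale crop of the 512x512
    acquisitions); timing and optics match the in-vivo recordings (30 Hz,
    0.42 or 0.67 µm/pixel, 300 s trials with an air puff at 150 s).
    """

    seed: int = 0
    fps: float = 30.0
    frame_shape: tuple[int, int] = (128, 128)
    um_per_pixel: float = 0.42
    duration: float = 60.0
    # --- Ca2+ events ---
    n_events: int = 5
    event_amplitude: float = 10.0
    event_rise_tau: float = 0.1
    event_decay_tau: float = 0.6
    event_radius_px: int = 3
    event_support_frac: float = 0.5  # kernel truncated at the half-amplitude
    # ground-truth membership level, so implanted support == ground truth
    noise_sigma: float = 1.0
    baseline_level: float = 100.0
    # --- pupil ---
    pupil_fps: float = 7.5
    pupil_baseline_ratio: float = 0.30
    pupil_eye_diam_px: float = 100.0
    pupil_decay_tau: float = 4.0
    pupil_noise_sd: float = 0.0
    # --- cohort ---
    n_mice_per_genotype: int = 5
    trials_per_mouse: int = 4
    depth_range_um: tuple[float, float] = (20.0, 200.0)
    um_per_pixel_levels: tuple[float, float] = (0.42, 0.67)
    pupil_dilation_range: tuple[float, float] = (0.0, 0.6)
    max_speed_range: tuple[float, float] = (30.0, 90.0)
    coeffs: CohortCoefficients = field(default_factory=CohortCoefficients)

    def __post_init__(self) -> None:
        positive = (
            self.fps, self.duration, self.event_amplitude, self.event_rise_tau,
            self.event_decay_tau, self.pupil_fps, self.pupil_baseline_ratio,
            self.pupil_eye_diam_px, self.pupil_decay_tau,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("rates and durations must be positive")
        if self.noise_sigma < 0 or self.baseline_level < 0 or self.pupil_noise_sd < 0:
            raise ValueError("noise and baseline levels must be non-negative")
        if not 0 < self.event_support_frac < 1:
            raise ValueError("event_support_frac must lie in (0, 1)")
        if self.event_rise_tau >= self.event_decay_tau:
            raise ValueError("event rise tau must be shorter than decay tau")
        if self.n_events < 0 or self.event_radius_px < 0:
            raise ValueError("n_events and event_radius_px must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)
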