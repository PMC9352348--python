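"""End-to-end orchestration: simulate -> detect -> segment -> summarize -> model.

A run is driven by a :class:`PipelineConfig` and is deterministic given its
seed: the global seed fans out to fixed per-stage child seeds so any stage
can be re-run in isolation and reproduce its outputs. Every stage writes
its products into the output directory, and ``run_pipeline`` finishes by
writing ``manifest.json`` listing parameters (including every design
toggle), child seeds, and output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, epoch_stats, io, mixed, pupil as pupil_mod, roa, synthetic
from .config import DetectionParams, SimulationConfig
from .datatypes import AirPuff, Epoch

__all__ = ["PipelineConfig", "run_pipeline", "make_figures"]

_STAGE_SEEDS = {"simulate": 11, "cohort": 13}


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for one pipeline run.

    Exactly one input mode is active: simulation (``simulation`` set) or
    real files (``movie_path`` etc. set).
    """

    outdir: str | Path = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    # real-input mode
    movie_path: str | None = None
    mask_path: str | None = None
    classes_path: str | None = None
    wheel_path: str | None = None
    pupil_path: str | None = None
    puff_time_s: float | None = 150.0
    cohort_episodes: int = 44

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        real = self.movie_path is not None
        if sim == real:
            raise ValueError("exactly one of simulation config or real input paths must be set")


def _child_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + _STAGE_SEEDS[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "detection_params": config.detection.to_dict(),
        "files": {},
        "stages": [],
    }

    # --- stage: inputs (simulate or load) -------------------------------
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation.to_dict(), "seed": _child_seed(config.seed, "simulate")})
        sim.coeffs = config.simulation.coeffs
        manifest["simulation"] = sim.to_dict()
        movie, truth = synthetic.generate_movie(sim)
        cmap = synthetic.generate_compartments(sim.frame_shape)
        puff = synthetic.default_puff(sim)
        run_start = min(20.0, sim.duration / 3)
        wheel = synthetic.generate_wheel_trace(sim, [(run_start, 5.0, 50.0)])
        run_epochs_true = [Epoch("run", run_start, run_start + 5.0)]
        pupil_trace = synthetic.generate_pupil_trace(sim, run_epochs_true, coupling_slope=0.25)
        io.write_movie(out / "movie.tif", movie)
        io.write_compartments(out / "mask.tif", out / "classes.csv", cmap)
        io.write_wheel(out / "wheel.csv", wheel)
        io.write_pupil(out / "pupil.csv", pupil_trace)
        io.write_json(
            out / "ground_truth.json",
            {
                "seed": sim.seed,
                "n_events": len(truth.event_voxels),
                "event_onsets": [int(v[:, 0].min()) for v in truth.event_voxels],
            },
        )
        manifest["files"].update(
            movie="movie.tif", mask="mask.tif", classes="classes.csv",
            wheel="wheel.csv", pupil="pupil.csv", ground_truth="ground_truth.json",
        )
    else:
        for name, p in [("movie", config.movie_path), ("mask", config.mask_path),
                        ("classes", config.classes_path)]:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        movie = io.read_movie(config.movie_path)
        cmap = io.read_compartments(config.mask_path, config.classes_path)
        wheel = io.read_wheel(config.wheel_path) if config.wheel_path else None
        pupil_trace = io.read_pupil(config.pupil_path) if config.pupil_path else None
        puff = AirPuff(t_puff=config.puff_time_s) if config.puff_time_s is not None else None
    manifest["stages"].append("inputs")

    # --- stage: detection ----------------------------------------------
    roas, densities = roa.detect(movie, cmap, config.detection)
    io.write_events(out / "events.csv", roas)
    io.write_densities(out / "density.csv", densities)
    manifest["files"].update(events="events.csv", density="density.csv")
    manifest["stages"].append("detect")

    # --- stage: behavior ------------------------------------------------
    epochs: list[Epoch] = []
    if wheel is not None:
        puffs = [puff] if puff is not None else []
        epochs = behavior.detect_runs(wheel, puffs) + behavior.detect_quiet(wheel, puffs)
        if puff is not None and puff.t_puff < wheel.t[-1]:
            epochs.append(behavior.startle_window(puff, movie.fps, trial_end=float(wheel.t[-1] + wheel.dt)))
        io.write_epochs(out / "epochs.csv", epochs,
                        [behavior.max_speed(wheel, e) for e in epochs])
        manifest["files"]["epochs"] = "epochs.csv"
    manifest["stages"].append("behavior")

    # --- stage: per-episode statistics ----------------------------------
    rows = []
    for i, ep in enumerate(epochs):
        dil = (
            pupil_mod.pupil_dilation(pupil_trace, ep.start) if pupil_trace is not None else np.nan
        )
        for cls, dens in densities.items():
            frames = ep.frames(movie.fps, movie.n_frames)
            if frames.size < 2:
                continue
            rows.append(
                {
                    "trial": "trial0",
                    "epoch_id": i,
                    "mouse": "m0",
                    "genotype": "WT",
                    "epoch_kind": ep.kind,
                    "compartment": cls,
                    "rise_rate": epoch_stats.rise_rate(dens, ep),
                    "max_density": epoch_stats.max_density(dens, ep),
                    "mean_density": epoch_stats.mean_density(dens, ep),
                    "pupil_dilation": dil,
                    "depth_um": movie.depth_um,
                    "um_per_pixel": movie.um_per_pixel,
                    "max_speed": behavior.max_speed(wheel, ep) if wheel is not None else np.nan,
                }
            )
    episode_table = pd.DataFrame(rows)
    episode_table.to_csv(out / "episodes.csv", index=False)
    manifest["files"]["episodes"] = "episodes.csv"
    manifest["stages"].append("stats")

    # --- stage: mixed models (on a simulated hierarchical cohort) -------
    if config.simulation is not None:
        cohort_cfg = SimulationConfig(
            **{**config.simulation.to_dict(), "seed": _child_seed(config.seed, "cohort")}
        )
        cohort_cfg.coeffs = config.simulation.coeffs
        cohort, cohort_truth = synthetic.generate_cohort(cohort_cfg, n_episodes=config.cohort_episodes)
        cohort.to_csv(out / "cohort.csv", index=False)
        fit = mixed.fit_pupil_model(cohort, mixed.ModelSpec(include_pupil=True))
        fit.coefficients.to_csv(out / "model_coefficients.csv", index=False)
        io.write_json(
            out / "model_summary.json",
            {
                "wt_slope": mixed.wt_slope(fit),
                "sigma_mouse": fit.sigma_mouse,
                "sigma_resid": fit.sigma_resid,
                "n_obs": fit.n_obs,
                "n_mice": fit.n_mice,
                "converged": fit.converged,
                "true_interaction": cohort_truth.true_coeffs.beta_interaction_wt,
            },
        )
        manifest["files"].update(
            cohort="cohort.csv",
            model_coefficients="model_coefficients.csv",
            model_summary="model_summary.json",
        )
    manifest["stages"].append("model")

    io.write_json(out / "manifest.json", manifest)
    return manifest


def make_figures(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Emit the data behind the hierarchical and scatter plots.

    Reads the cohort table of a finished run and writes the three-level
    median tables (trial -> mouse -> genotype) and the dilation-vs-response
    scatter table. Returns the tables keyed by name.
    """
    out = Path(outdir)
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"no cohort table in {out}; run the pipeline first")
    cohort = pd.read_csv(cohort_path)
    present = cohort["genotype"].unique()
    for g in ("TG", "WT"):
        if g not in present:
            warnings.warn(f"genotype {g} absent from cohort; omitted from summaries", stacklevel=2)
    levels = epoch_stats.hierarchical_medians(cohort, value="response")
    tables: dict[str, pd.DataFrame] = {}
    for name, tab in levels.items():
        path = out / f"hierarchy_{name}.csv"
        tab.to_csv(path, index=False)
        tables[f"hierarchy_{name}"] = tab
    scatter = cohort[["genotype", "mouse", "pupil_dilation", "response"]].dropna()
    scatter.to_csv(out / "scatter_pupil_response.csv", index=False)
    tables["scatter"] = scatter
    return tables
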