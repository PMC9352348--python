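"""Readers and writers for the pipeline's file formats.

Movies and label masks travel as multi-page TIFF (tifffile); traces,
epochs, events and cohort tables as headered CSV (pandas); ground truth
and run manifests as JSON sidecars carrying the generating seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import AirPuff, CompartmentMap, Epoch, Movie, PupilTrace, ROASet, WheelTrace

__all__ = [
    "write_movie",
    "read_movie",
    "write_compartments",
    "read_compartments",
    "write_wheel",
    "read_wheel",
    "write_pupil",
    "read_pupil",
    "write_epochs",
    "read_epochs",
    "write_events",
    "write_densities",
    "write_json",
    "read_json",
]


def write_movie(path: str | Path, movie: Movie) -> None:
    tifffile.imwrite(
        path,
        np.asarray(movie.data, dtype=np.float32),
        metadata={"fps": movie.fps, "um_per_pixel": movie.um_per_pixel, "depth_um": movie.depth_um},
    )


def read_movie(path: str | Path, fps: float = 30.0, um_per_pixel: float = 0.42) -> Movie:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return Movie(
        np.asarray(data, dtype=np.float64),
        fps=float(meta.get("fps", fps)),
        um_per_pixel=float(meta.get("um_per_pixel", um_per_pixel)),
        depth_um=float(meta.get("depth_um", 0.0)),
    )


def write_compartments(label_path: str | Path, class_path: str | Path, cmap: CompartmentMap) -> None:
    tifffile.imwrite(label_path, cmap.labels.astype(np.int32))
    pd.DataFrame(
        {"label": list(cmap.classes), "class": list(cmap.classes.values())}
    ).to_csv(class_path, index=False)


def read_compartments(label_path: str | Path, class_path: str | Path) -> CompartmentMap:
    for p in (label_path, class_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"compartment file not found: {p}")
    labels = tifffile.imread(label_path)
    table = pd.read_csv(class_path)
    return CompartmentMap(labels=labels, classes=dict(zip(table["label"], table["class"])))


def write_wheel(path: str | Path, wheel: WheelTrace) -> None:
    pd.DataFrame({"t_s": wheel.t, "speed_deg_s": wheel.speed}).to_csv(path, index=False)


def read_wheel(path: str | Path) -> WheelTrace:
    df = pd.read_csv(path)
    return WheelTrace(t=df["t_s"].to_numpy(), speed=df["speed_deg_s"].to_numpy())


def write_pupil(path: str | Path, pupil: PupilTrace) -> None:
    pd.DataFrame(
        {"t_s": pupil.t, "pupil_px": pupil.pupil_diam, "eye_px": pupil.eye_diam}
    ).to_csv(path, index=False)


def read_pupil(path: str | Path) -> PupilTrace:
    df = pd.read_csv(path)
    return PupilTrace(
        t=df["t_s"].to_numpy(), pupil_diam=df["pupil_px"].to_numpy(), eye_diam=df["eye_px"].to_numpy()
    )


def write_epochs(path: str | Path, epochs: list[Epoch], max_speeds: list[float] | None = None) -> None:
    rows = [{"kind": e.kind, "start_s": e.start, "end_s": e.end} for e in epochs]
    if max_speeds is not None:
        for row, ms in zip(rows, max_speeds):
            row["max_speed"] = ms
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s"] + (["max_speed"] if max_speeds else [])).to_csv(
        path, index=False
    )


def read_epochs(path: str | Path) -> list[Epoch]:
    df = pd.read_csv(path)
    return [Epoch(r.kind, r.start_s, r.end_s) for r in df.itertuples()]


def write_events(path: str | Path, roas: ROASet) -> None:
    """One row per ROA: onset, duration, voxel count, largest frame, centroid."""
    rows = []
    for ev in roas:
        cy, cx = ev.centroid()
        rows.append(
            {
                "t_onset": ev.t_onset,
                "duration_frames": ev.duration,
                "n_voxels": ev.n_voxels,
                "max_frame_area_px": ev.max_frame_area,
                "centroid_x": cx,
                "centroid_y": cy,
            }
        )
    pd.DataFrame(
        rows,
        columns=["t_onset", "duration_frames", "n_voxels", "max_frame_area_px", "centroid_x", "centroid_y"],
    ).to_csv(path, index=False)


def write_densities(path: str | Path, densities: dict) -> None:
    """Frame-by-compartment density table, in percent."""
    cols = {"frame": np.arange(next(iter(densities.values())).values.size)}
    cols.update({name: tr.values for name, tr in densities.items()})
    pd.DataFrame(cols).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
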