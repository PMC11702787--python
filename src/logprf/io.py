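"""Serialization: NIfTI stimulus movies with JSON sidecars, TSV tables
for time series and estimates, JSON for HRF parameters and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import apply_retention_filters, FitConfig
from .hemodynamics import HRFParams
from .model import PRFEstimate
from .stimulus import StimulusMovie, VisualFieldGrid

__all__ = [
    "save_movie",
    "load_movie",
    "save_movie_npz",
    "load_movie_npz",
    "estimates_to_frame",
    "save_estimates",
    "load_estimates",
    "save_timecourses",
    "load_timecourses",
    "save_hrf",
    "load_hrf",
]

ESTIMATE_COLUMNS = [
    "unit_id",
    "mu_x",
    "mu_y",
    "sigma",
    "polar_angle",
    "eccentricity",
    "correlation",
    "variance_explained",
    "retained",
    "rejection_reasons",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_movie(movie: StimulusMovie, path, metadata: dict | None = None) -> Path:
    """Write a movie as NIfTI (x, y, t) plus a JSON sidecar holding the
    grid geometry, frame times and any extra metadata (schedule, warp,
    seed)."""
    path = Path(path)
    affine = np.diag([movie.grid.pixel_size_deg, movie.grid.pixel_size_deg, 1.0, 1.0])
    nib.save(nib.Nifti1Image(movie.frames.astype(np.uint8), affine), str(path))
    sidecar = {
        "n_pixels_per_side": movie.grid.n_pixels_per_side,
        "aperture_radius_deg": movie.grid.aperture_radius_deg,
        "frame_times_s": movie.frame_times_s.tolist(),
    }
    if metadata:
        sidecar["metadata"] = metadata
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_movie(path) -> StimulusMovie:
    path = Path(path)
    img = nib.load(str(path))
    frames = np.asarray(img.dataobj).astype(np.uint8)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing JSON sidecar for movie: {side}")
    meta = json.loads(side.read_text())
    for key in ("n_pixels_per_side", "aperture_radius_deg", "frame_times_s"):
        if key not in meta:
            raise ValueError(f"movie sidecar {side} is missing field '{key}'")
    grid = VisualFieldGrid(
        n_pixels_per_side=int(meta["n_pixels_per_side"]),
        aperture_radius_deg=float(meta["aperture_radius_deg"]),
    )
    return StimulusMovie(
        frames=frames, grid=grid, frame_times_s=np.asarray(meta["frame_times_s"])
    )


def save_movie_npz(movie: StimulusMovie, path) -> Path:
    """Compressed numpy container alternative to NIfTI (self-contained)."""
    path = Path(path)
    np.savez_compressed(
        path,
        frames=movie.frames.astype(np.uint8),
        frame_times_s=movie.frame_times_s,
        n_pixels_per_side=movie.grid.n_pixels_per_side,
        aperture_radius_deg=movie.grid.aperture_radius_deg,
    )
    return path


def load_movie_npz(path) -> StimulusMovie:
    with np.load(path) as z:
        grid = VisualFieldGrid(
            n_pixels_per_side=int(z["n_pixels_per_side"]),
            aperture_radius_deg=float(z["aperture_radius_deg"]),
        )
        return StimulusMovie(
            frames=z["frames"], grid=grid, frame_times_s=z["frame_times_s"]
        )


def estimates_to_frame(
    estimates: list[PRFEstimate], config: FitConfig | None = None
) -> pd.DataFrame:
    """Estimate table in the declared schema, including retention flags."""
    _, log = apply_retention_filters(estimates, config)
    return pd.DataFrame(
        {
            "unit_id": np.arange(len(estimates)),
            "mu_x": [e.params.mu_x for e in estimates],
            "mu_y": [e.params.mu_y for e in estimates],
            "sigma": [e.params.sigma for e in estimates],
            "polar_angle": [e.polar_angle for e in estimates],
            "eccentricity": [e.eccentricity for e in estimates],
            "correlation": [e.fit_correlation for e in estimates],
            "variance_explained": [e.variance_explained for e in estimates],
            "retained": log["retained"],
            "rejection_reasons": log["rejection_reasons"],
        }
    )


def save_estimates(estimates, path, config: FitConfig | None = None) -> Path:
    path = Path(path)
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates_to_frame(estimates, config)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"estimates table {path} is missing columns: {missing}")
    df["rejection_reasons"] = df["rejection_reasons"].fillna("")
    return df


def save_timecourses(data: np.ndarray, path) -> Path:
    """TSV export: one column per unit, one row per volume."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(data).T)
    df.columns = [f"unit_{i}" for i in range(df.shape[1])]
    df.to_csv(path, sep="\t", index=False)
    return path


def load_timecourses(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy().T


def save_hrf(hrf: HRFParams, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(hrf.as_dict(), indent=1))
    return path


def load_hrf(path) -> HRFParams:
    return HRFParams(**json.loads(Path(path).read_text()))
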