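"""Gaussian pRF forward model.

A voxel/vertex's population receptive field is an isotropic 2-D Gaussian
G(x, y) = exp(-((x-mu_x)^2 + (y-mu_y)^2) / (2 sigma^2)) over the visual
field. The predicted BOLD time course is the per-frame overlap (dot
product over pixels) of the binary stimulus movie with G, convolved with
the HRF at movie temporal resolution and resampled to the scanner's TR
grid. No amplitude or baseline parameters exist: the fit criterion is
correlation, which is invariant to positive affine transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hemodynamics import HRFParams, evaluate_hrf
from .stimulus import StimulusMovie, VisualFieldGrid

__all__ = [
    "PRFParams",
    "PRFEstimate",
    "TimecourseSet",
    "gaussian_field",
    "stimulus_overlap",
    "predict_timecourse",
    "n_volumes",
    "volume_times",
]


@dataclass(frozen=True)
class PRFParams:
    """pRF center (mu_x, mu_y) and size sigma, degrees of visual angle."""

    mu_x: float
    mu_y: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("pRF size sigma must be > 0")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.mu_x, self.mu_y))

    @property
    def polar_angle(self) -> float:
        """Radians, atan2 convention (0 = right horizontal meridian)."""
        return float(np.arctan2(self.mu_y, self.mu_x))


@dataclass(frozen=True)
class PRFEstimate:
    """A fitted pRF with its goodness of fit.

    ``variance_explained`` is the square of the prediction-data Pearson
    correlation.
    """

    params: PRFParams
    fit_correlation: float
    converged: bool = True

    @property
    def polar_angle(self) -> float:
        return self.params.polar_angle

    @property
    def eccentricity(self) -> float:
        return self.params.eccentricity

    @property
    def variance_explained(self) -> float:
        return float(self.fit_correlation**2)


@dataclass
class TimecourseSet:
    """Matrix of per-unit time series aligned to a movie's TR grid.

    ``data`` has shape (n_units, n_volumes).
    """

    data: np.ndarray
    tr_s: float = 1.2
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.data.shape[0])

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def gaussian_field(grid: VisualFieldGrid, params: PRFParams) -> np.ndarray:
    """Evaluate the unnormalized pRF Gaussian on the grid (value 1 at its
    center when the center falls on a pixel)."""
    xx, yy = grid.mesh
    return np.exp(
        -((xx - params.mu_x) ** 2 + (yy - params.mu_y) ** 2) / (2.0 * params.sigma**2)
    )


def stimulus_overlap(movie: StimulusMovie, params: PRFParams) -> np.ndarray:
    """Per-frame dot product of the movie with the pRF Gaussian."""
    g = gaussian_field(movie.grid, params)
    return np.tensordot(g, movie.frames.astype(np.float32), axes=([0, 1], [0, 1]))


def n_volumes(movie: StimulusMovie, tr_s: float) -> int:
    """Number of TR-spaced volumes that fit within the movie's time span
    (366 frames at 1 frame/s with TR 1.2 s gives 305)."""
    return int(np.floor(movie.frame_times_s[-1] / tr_s)) + 1


def volume_times(movie: StimulusMovie, tr_s: float) -> np.ndarray:
    return np.arange(n_volumes(movie, tr_s)) * tr_s


def hrf_kernel(hrf: HRFParams, dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """HRF sampled at the movie's frame interval for discrete convolution."""
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    return evaluate_hrf(t, hrf)


def predict_timecourse(
    movie: StimulusMovie, params: PRFParams, hrf: HRFParams, tr_s: float
) -> np.ndarray:
    """Predicted BOLD time course for one pRF.

    Overlap is convolved with the HRF at movie resolution (zero-padded
    before stimulus onset, truncated to causal support) and linearly
    interpolated to the TR sample times. Output length equals the number
    of volumes.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if movie.n_frames == 0:
        raise ValueError("empty stimulus movie")
    overlap = stimulus_overlap(movie, params)
    dt = float(np.median(np.diff(movie.frame_times_s)))
    kernel = hrf_kernel(hrf, dt)
    conv = np.convolve(overlap, kernel)[: movie.n_frames]
    return np.interp(volume_times(movie, tr_s), movie.frame_times_s, conv)
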