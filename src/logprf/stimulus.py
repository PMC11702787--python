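"""Drifting-bar aperture movies and the log-eccentricity warp.

The classic retinotopic mapping stimulus is a bar of fixed width sweeping
across the visual field at constant speed. Because cortical magnification
shrinks receptive fields toward the fovea, such a bar crosses foveal pRFs
far too quickly to constrain their size. The log-bar stimulus fixes this by
warping every frame along the eccentricity axis with

    r' = c * log(1 + k * r),        c = r_max / log(1 + k * r_max)

so the bar appears thin and slow near fixation and wide and fast in the
periphery, approximating a constant-width, constant-speed wave on cortex.

All coordinates are degrees of visual angle, origin at fixation, x
rightward, y upward; pixel centers (not edges) carry coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import resize

__all__ = [
    "VisualFieldGrid",
    "WarpParams",
    "SweepSchedule",
    "StimulusMovie",
    "source_eccentricity",
    "apparent_eccentricity",
    "warp_frame",
    "generate_fixed_bar_movie",
    "generate_log_bar_movie",
    "preprocess_movie",
]

#: Sweep motion directions (degrees): 4 cardinal + 4 diagonal, the
#: Dumoulin–Wandell convention.
DEFAULT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square pixel grid over the stimulated visual field.

    Pixel centers are symmetric about fixation and never exceed the
    aperture radius in absolute value.
    """

    n_pixels_per_side: int
    aperture_radius_deg: float = 8.0

    def __post_init__(self) -> None:
        if self.n_pixels_per_side < 1:
            raise ValueError("n_pixels_per_side must be positive")
        if self.aperture_radius_deg <= 0:
            raise ValueError("aperture_radius_deg must be positive")

    @property
    def pixel_size_deg(self) -> float:
        return 2.0 * self.aperture_radius_deg / self.n_pixels_per_side

    @cached_property
    def pixel_centers(self) -> np.ndarray:
        """1-D pixel-center coordinates (degrees), ascending."""
        r, n = self.aperture_radius_deg, self.n_pixels_per_side
        step = 2.0 * r / n
        return -r + step / 2.0 + step * np.arange(n)

    @cached_property
    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate meshes; rows index y ascending, columns x."""
        x = self.pixel_centers
        return np.meshgrid(x, x)

    @cached_property
    def eccentricity(self) -> np.ndarray:
        xx, yy = self.mesh
        return np.hypot(xx, yy)

    @cached_property
    def aperture_mask(self) -> np.ndarray:
        """Boolean mask of pixels inside the circular aperture."""
        return self.eccentricity <= self.aperture_radius_deg


@dataclass(frozen=True)
class WarpParams:
    """Parameters of the log-eccentricity warp.

    ``c`` is always derived as ``r_max / log(1 + k * r_max)`` so the warp
    maps the aperture edge onto itself; it is not independently settable.
    """

    k: float = 5.0
    r_max: float = 8.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("distortion factor k must be > 0")
        if self.r_max <= 0:
            raise ValueError("r_max must be > 0")

    @property
    def c(self) -> float:
        return self.r_max / np.log1p(self.k * self.r_max)


@dataclass(frozen=True)
class SweepSchedule:
    """Timing of a drifting-bar run.

    Defaults reproduce the standard protocol: 2 s blank, eight 45 s sweeps
    of a 2°-wide bar at 0.4°/s, 4 s blank — 366 s total at 1 frame/s.
    """

    bar_width_deg: float = 2.0
    bar_speed_deg_per_s: float = 0.4
    sweep_duration_s: float = 45.0
    n_sweeps: int = 8
    directions: tuple[float, ...] = DEFAULT_DIRECTIONS
    pre_blank_s: float = 2.0
    post_blank_s: float = 4.0
    frame_rate_hz: float = 1.0

    @property
    def total_duration_s(self) -> float:
        return self.pre_blank_s + self.n_sweeps * self.sweep_duration_s + self.post_blank_s

    @property
    def travel_distance_deg(self) -> float:
        """Distance the bar center travels during one sweep."""
        return self.bar_speed_deg_per_s * self.sweep_duration_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s * self.frame_rate_hz))


@dataclass
class StimulusMovie:
    """Binary aperture movie: ``frames[row, col, t]`` with rows indexing y.

    Values are 0/1; 1 marks the presence of the bar. ``frame_times_s``
    holds the start time of each frame.
    """

    frames: np.ndarray
    grid: VisualFieldGrid
    frame_times_s: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        n = self.grid.n_pixels_per_side
        if self.frames.shape[:2] != (n, n):
            raise ValueError(
                f"frame shape {self.frames.shape[:2]} does not match grid ({n}, {n})"
            )
        if self.frames.shape[2] != self.frame_times_s.size:
            raise ValueError("frame count does not match frame_times_s length")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    def is_binary(self) -> bool:
        return bool(np.isin(self.frames, (0, 1)).all())


# ---------------------------------------------------------------------------
# the warp


def source_eccentricity(r, warp: WarpParams):
    """Map an output (log-bar) eccentricity to the fixed-bar eccentricity
    it samples: ``r' = c * log(1 + k * r)``.

    Strictly increasing, fixes 0 and ``r_max``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity must be non-negative")
    out = warp.c * np.log1p(warp.k * r)
    return out if out.ndim else float(out)


def apparent_eccentricity(e, warp: WarpParams):
    """Exact inverse of :func:`source_eccentricity`.

    Answers: at what eccentricity does fixed-bar content originally at
    eccentricity ``e`` appear in the log-bar frame?
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0) or np.any(e > warp.r_max + 1e-12):
        raise ValueError(f"eccentricity must lie in [0, {warp.r_max}]")
    out = np.expm1(e / warp.c) / warp.k
    return out if out.ndim else float(out)


def _warp_coordinates(grid: VisualFieldGrid, warp: WarpParams):
    """Fractional (row, col) source coordinates for the pull-map warp."""
    xx, yy = grid.mesh
    r = grid.eccentricity
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, warp.c * np.log1p(warp.k * r) / np.where(r > 0, r, 1.0), 0.0)
    xs = xx * scale
    ys = yy * scale
    # convert degrees -> fractional pixel index
    centers = grid.pixel_centers
    step = grid.pixel_size_deg
    col = (xs - centers[0]) / step
    row = (ys - centers[0]) / step
    invalid = warp.c * np.log1p(warp.k * r) > warp.r_max  # samples beyond the aperture
    return row, col, invalid


def warp_frame(frame: np.ndarray, grid: VisualFieldGrid, warp: WarpParams) -> np.ndarray:
    """Warp one binary frame into log-eccentricity space.

    The output pixel at polar coordinates (r, θ) takes the input value at
    (c·log(1+k·r), θ): polar angle is preserved, eccentricity is remapped.
    Bilinear interpolation followed by re-binarization at 0.5.
    """
    frame = np.asarray(frame)
    n = grid.n_pixels_per_side
    if frame.shape != (n, n):
        raise ValueError(f"frame shape {frame.shape} does not match grid ({n}, {n})")
    row, col, invalid = _warp_coordinates(grid, warp)
    sampled = map_coordinates(
        frame.astype(np.float32), [row, col], order=1, mode="constant", cval=0.0
    )
    out = (sampled >= 0.5).astype(np.uint8)
    out[invalid] = 0
    return out


# ---------------------------------------------------------------------------
# movie generation


def _bar_center_at(schedule: SweepSchedule, t_mid: float) -> tuple[float, float] | None:
    """(sweep index, signed bar-center position) at time ``t_mid``, or None in blanks."""
    t = t_mid - schedule.pre_blank_s
    if t < 0 or t >= schedule.n_sweeps * schedule.sweep_duration_s:
        return None
    sweep = int(t // schedule.sweep_duration_s)
    tau = t - sweep * schedule.sweep_duration_s
    d = -schedule.travel_distance_deg / 2.0 + schedule.bar_speed_deg_per_s * tau
    return sweep, d


def generate_fixed_bar_movie(
    schedule: SweepSchedule, grid: VisualFieldGrid, seed: int
) -> StimulusMovie:
    """Render a fixed-bar run: blank, n_sweeps bar sweeps, blank.

    Each sweep's motion direction is a seeded pseudorandom draw from
    ``schedule.directions``; when the direction set has exactly ``n_sweeps``
    entries a seeded permutation is used so every direction occurs once.
    The bar travels ``bar_speed * sweep_duration`` centered on fixation and
    its position is evaluated at each frame's temporal midpoint.
    """
    coverage = schedule.travel_distance_deg
    needed = 2 * grid.aperture_radius_deg + schedule.bar_width_deg
    if coverage < needed - 1e-9:
        warnings.warn(
            f"bar travel {coverage:.2f}° < aperture diameter + bar width "
            f"({needed:.2f}°): incomplete coverage",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    dirs = np.asarray(schedule.directions, dtype=float)
    if dirs.size == schedule.n_sweeps:
        sweep_dirs = rng.permutation(dirs)
    else:
        sweep_dirs = rng.choice(dirs, size=schedule.n_sweeps, replace=True)

    n = grid.n_pixels_per_side
    n_frames = schedule.n_frames
    dt = 1.0 / schedule.frame_rate_hz
    frame_times = np.arange(n_frames) * dt
    xx, yy = grid.mesh
    aperture = grid.aperture_mask
    frames = np.zeros((n, n, n_frames), dtype=np.uint8)
    half_w = schedule.bar_width_deg / 2.0
    for i, t0 in enumerate(frame_times):
        pos = _bar_center_at(schedule, t0 + dt / 2.0)
        if pos is None:
            continue
        sweep, d = pos
        phi = np.deg2rad(sweep_dirs[sweep])
        u = xx * np.cos(phi) + yy * np.sin(phi)  # coordinate along motion axis
        frames[:, :, i] = (np.abs(u - d) <= half_w) & aperture
    return StimulusMovie(frames=frames, grid=grid, frame_times_s=frame_times)


def generate_log_bar_movie(fixed_movie: StimulusMovie, warp: WarpParams) -> StimulusMovie:
    """Warp every frame of a fixed-bar movie into a log-bar movie.

    Frame count and frame times are unchanged; the movie grid radius must
    equal the warp's ``r_max`` so the aperture maps onto itself.
    """
    grid = fixed_movie.grid
    if abs(grid.aperture_radius_deg - warp.r_max) > 1e-9:
        raise ValueError(
            f"grid radius {grid.aperture_radius_deg}° != warp r_max {warp.r_max}°"
        )
    row, col, invalid = _warp_coordinates(grid, warp)
    out = np.empty_like(fixed_movie.frames)
    for t in range(fixed_movie.n_frames):
        sampled = map_coordinates(
            fixed_movie.frames[:, :, t].astype(np.float32),
            [row, col],
            order=1,
            mode="constant",
            cval=0.0,
        )
        f = (sampled >= 0.5).astype(np.uint8)
        f[invalid] = 0
        out[:, :, t] = f
    return StimulusMovie(frames=out, grid=grid, frame_times_s=fixed_movie.frame_times_s.copy())


def preprocess_movie(
    movie: StimulusMovie, target_pixels: int, target_frames: int
) -> StimulusMovie:
    """Linearly downsample a movie in space and time, then re-binarize.

    The standard reduction is 540×540 → 108×108 pixels and (if needed)
    temporal resampling to 366 frames. Upsampling is refused. Pixels
    outside the circular aperture are forced to 0 after binarization.
    """
    n = movie.grid.n_pixels_per_side
    if target_pixels > n or target_frames > movie.n_frames:
        raise ValueError("preprocess_movie only downsamples; target exceeds source size")

    frames = movie.frames.astype(np.float32)
    if target_pixels < n:
        frames = resize(
            frames,
            (target_pixels, target_pixels, movie.n_frames),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
            mode="constant",
        )
    times = movie.frame_times_s
    if target_frames < movie.n_frames:
        new_times = np.linspace(times[0], times[-1], target_frames)
        idx = np.searchsorted(times, new_times, side="right") - 1
        idx = np.clip(idx, 0, times.size - 2)
        w = (new_times - times[idx]) / (times[idx + 1] - times[idx])
        frames = frames[:, :, idx] * (1.0 - w) + frames[:, :, idx + 1] * w
        times = new_times
    else:
        times = times.copy()

    new_grid = replace(movie.grid, n_pixels_per_side=target_pixels)
    binary = (frames >= 0.5).astype(np.uint8)
    binary[~new_grid.aperture_mask] = 0
    return StimulusMovie(frames=binary, grid=new_grid, frame_times_s=times)
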