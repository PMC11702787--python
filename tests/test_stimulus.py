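"""Warp math, bar-movie generation and preprocessing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import logprf
from logprf.stimulus import (
    SweepSchedule,
    VisualFieldGrid,
    WarpParams,
    apparent_eccentricity,
    generate_fixed_bar_movie,
    generate_log_bar_movie,
    preprocess_movie,
    source_eccentricity,
    warp_frame,
)


class TestWarpMath:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (8.0, 8.0),  # aperture edge maps to itself
            (0.0, 0.0),
            (1.0, 8.0 / np.log(41.0) * np.log(6.0)),  # = c*log(1+5) ~ 3.860
        ],
    )
    def test_source_eccentricity_values(self, warp, r, expected):
        assert source_eccentricity(r, warp) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("e, expected", [(8.0, 8.0), (0.0, 0.0)])
    def test_apparent_fixed_points(self, warp, e, expected):
        assert apparent_eccentricity(e, warp) == pytest.approx(expected, abs=1e-9)

    def test_apparent_matches_root_find(self, warp):
        # independent oracle: where does source_eccentricity(r) = 4?
        from scipy.optimize import brentq

        r_star = brentq(lambda r: source_eccentricity(r, warp) - 4.0, 0, 8)
        assert apparent_eccentricity(4.0, warp) == pytest.approx(r_star, abs=1e-9)
        assert apparent_eccentricity(4.0, warp) == pytest.approx(1.081, abs=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.0, 8.0), st.floats(0.0, 8.0))
    def test_monotone_and_inverse_identity(self, r1, r2):
        warp = WarpParams()
        f1, f2 = source_eccentricity(r1, warp), source_eccentricity(r2, warp)
        if r1 < r2:
            assert f1 < f2
        assert apparent_eccentricity(f1, warp) == pytest.approx(r1, abs=1e-9)

    def test_small_k_approaches_identity(self):
        warp = WarpParams(k=1e-6)
        r = np.linspace(0, 8, 1001)
        assert np.max(np.abs(source_eccentricity(r, warp) - r)) < 1e-4

    def test_domain_errors(self, warp):
        with pytest.raises(ValueError):
            source_eccentricity(-0.1, warp)
        with pytest.raises(ValueError):
            apparent_eccentricity(8.5, warp)
        with pytest.raises(ValueError):
            WarpParams(k=0.0)

    def test_c_is_derived(self, warp):
        assert warp.c == pytest.approx(8.0 / np.log(41.0))


class TestWarpFrame:
    def test_trivial_frames(self, grid54, warp):
        zero = np.zeros((54, 54), dtype=np.uint8)
        assert warp_frame(zero, grid54, warp).sum() == 0
        disk = grid54.aperture_mask.astype(np.uint8)
        out = warp_frame(disk, grid54, warp)
        # the warp maps the aperture onto itself; compare away from the
        # rim, where bilinear sampling mixes in outside-aperture zeros —
        # the exclusion radius lives in *source* coordinates
        r_in = apparent_eccentricity(8 - 2 * grid54.pixel_size_deg, warp)
        inside = grid54.eccentricity <= r_in
        assert np.array_equal(out[inside], disk[inside])

    def test_wedge_preserved(self, grid54, warp):
        # a purely radial map leaves polar angle untouched
        xx, yy = grid54.mesh
        ang = np.arctan2(yy, xx)
        wedge = ((np.abs(ang) < np.pi / 6) & grid54.aperture_mask).astype(np.uint8)
        out = warp_frame(wedge, grid54, warp)
        # identical except interpolation-edge pixels
        assert (out != wedge).mean() < 0.02

    def test_identity_at_tiny_k(self, grid54):
        rng = np.random.default_rng(0)
        frame = (rng.random((54, 54)) < 0.3).astype(np.uint8)
        frame[~grid54.aperture_mask] = 0
        out = warp_frame(frame, grid54, WarpParams(k=1e-6))
        assert (out != frame).mean() < 0.02

    def test_dimension_mismatch(self, grid54, warp):
        with pytest.raises(ValueError):
            warp_frame(np.zeros((10, 10)), grid54, warp)


def _band_disk_area(d: float, half_w: float, radius: float) -> float:
    """Analytic area of {|u - d| <= half_w} intersected with a disk."""

    def antideriv(u):
        u = np.clip(u, -radius, radius)
        return u * np.sqrt(radius**2 - u**2) + radius**2 * np.arcsin(u / radius)

    return antideriv(d + half_w) - antideriv(d - half_w)


class TestFixedBarMovie:
    def test_default_duration_and_frames(self, movies54):
        fixed, _ = movies54
        sched = SweepSchedule()
        assert sched.total_duration_s == 366.0
        assert fixed.n_frames == 366
        assert fixed.is_binary()

    def test_blanks(self, movies54):
        fixed, _ = movies54
        assert fixed.frames[:, :, 0].sum() == 0  # pre blank (2 s)
        assert fixed.frames[:, :, -3:].sum() == 0  # post blank (4 s)

    def test_bar_centered_at_sweep_midpoint(self, movies54):
        fixed, _ = movies54
        # sweep 0 spans [2, 47) s; its midpoint 24.5 s falls in frame 24
        frame = fixed.frames[:, :, 24]
        ecc_on = fixed.grid.eccentricity[frame.astype(bool)]
        assert ecc_on.min() < fixed.grid.pixel_size_deg  # bar covers fixation

    def test_nonzero_only_inside_aperture(self, movies54):
        for m in movies54:
            outside = ~m.grid.aperture_mask
            assert m.frames[outside].sum() == 0

    def test_mean_coverage_matches_band_disk_area(self, grid54):
        movie = generate_fixed_bar_movie(SweepSchedule(), grid54, seed=3)
        px_area = grid54.pixel_size_deg**2
        sweep = movie.frames[:, :, 2:47]  # first sweep
        measured = sweep.sum(axis=(0, 1)).astype(float) * px_area
        mids = np.arange(45) + 0.5
        expected = np.array([_band_disk_area(-9 + 0.4 * t, 1.0, 8.0) for t in mids])
        on = expected > 1.0  # skip frames where the bar barely clips the disk
        assert np.median(np.abs(measured[on] - expected[on]) / expected[on]) < 0.1

    def test_seeded_direction_draw_is_reproducible(self, grid54):
        a = generate_fixed_bar_movie(SweepSchedule(), grid54, seed=7)
        b = generate_fixed_bar_movie(SweepSchedule(), grid54, seed=7)
        c = generate_fixed_bar_movie(SweepSchedule(), grid54, seed=8)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_incomplete_coverage_warns(self, grid54):
        short = SweepSchedule(sweep_duration_s=20.0)
        with pytest.warns(UserWarning):
            generate_fixed_bar_movie(short, grid54, seed=0)


class TestLogBarMovie:
    def test_blank_stays_blank_and_times_unchanged(self, movies54):
        fixed, logm = movies54
        assert logm.n_frames == fixed.n_frames
        assert np.array_equal(logm.frame_times_s, fixed.frame_times_s)
        blank = fixed.frames.sum(axis=(0, 1)) == 0
        assert (logm.frames.sum(axis=(0, 1))[blank] == 0).all()

    def test_radius_mismatch_rejected(self, movies54):
        with pytest.raises(ValueError):
            generate_log_bar_movie(movies54[0], WarpParams(r_max=6.0))

    def test_band_edge_maps_to_apparent_eccentricity(self, grid54, warp):
        # annulus with inner edge at 4 deg -> warped inner edge at ~1.081
        ecc = grid54.eccentricity
        band = ((ecc >= 4.0) & (ecc <= 6.0)).astype(np.uint8)
        out = warp_frame(band, grid54, warp)
        inner = ecc[out.astype(bool)].min()
        assert inner == pytest.approx(
            apparent_eccentricity(4.0, warp), abs=1.5 * grid54.pixel_size_deg
        )

    def test_warped_band_width_grows_with_eccentricity(self, grid54, warp):
        # 2-deg-wide annuli at increasing eccentricity: the warped radial
        # extent must be non-decreasing (thin near the fovea, wide out)
        ecc = grid54.eccentricity
        widths = []
        for a0 in [0.0, 2.0, 4.0, 6.0]:
            band = ((ecc >= a0) & (ecc <= a0 + 2.0)).astype(np.uint8)
            out = warp_frame(band, grid54, warp)
            r_on = ecc[out.astype(bool)]
            widths.append(r_on.max() - r_on.min())
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))


class TestPreprocess:
    def test_downsample_shape_540_to_108(self):
        grid = VisualFieldGrid(540)
        frames = np.repeat(grid.aperture_mask[:, :, None].astype(np.uint8), 3, axis=2)
        movie = logprf.StimulusMovie(frames=frames, grid=grid, frame_times_s=np.arange(3.0))
        out = preprocess_movie(movie, 108, 3)
        assert out.frames.shape == (108, 108, 3)
        assert out.is_binary()

    def test_identity_when_targets_equal_source(self, movies54):
        fixed, _ = movies54
        out = preprocess_movie(fixed, 54, fixed.n_frames)
        assert np.array_equal(out.frames, fixed.frames)

    def test_all_ones_stays_ones_inside_aperture(self):
        grid = VisualFieldGrid(108)
        frames = np.ones((108, 108, 2), dtype=np.uint8)
        frames[~grid.aperture_mask] = 0
        movie = logprf.StimulusMovie(frames=frames, grid=grid, frame_times_s=np.arange(2.0))
        out = preprocess_movie(movie, 54, 2)
        interior = out.grid.eccentricity <= 8 - 2 * out.grid.pixel_size_deg
        assert out.frames[interior].all()

    def test_upsampling_refused(self, movies54):
        with pytest.raises(ValueError):
            preprocess_movie(movies54[0], 108, 10)
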