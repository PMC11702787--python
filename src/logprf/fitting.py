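"""Two-stage pRF estimation.

Stage one is a coarse grid search: predicted time courses for 8000 seed
triples (20 centers per axis from -8 to 8 deg x 20 sizes from 1 to 5 deg)
are precomputed once per stimulus movie, and each unit keeps the seed with
the highest Pearson correlation. Stage two refines the winning seed with a
derivative-free Nelder-Mead simplex over (mu_x, mu_y, sigma), maximizing
the same correlation. An optional co-estimation stage alternates
HRF-parameter and pRF-parameter fits on a subset of well-fit units and
returns the elementwise median HRF.

Retention filters mirror the standard criteria: estimated eccentricity
< 8 deg, sigma > 0.05 deg, variance explained > 10% (strict inequalities).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .hemodynamics import HRF_BOUNDS, HRFParams, default_hrf
from .model import PRFEstimate, PRFParams, TimecourseSet, hrf_kernel, volume_times
from .stimulus import StimulusMovie

__all__ = [
    "SeedGrid",
    "FitConfig",
    "PredictionEngine",
    "grid_search",
    "refine_fit",
    "fit_dataset",
    "estimate_hrf_for_dataset",
    "select_hrf_units",
    "apply_retention_filters",
]

_SIGMA_FLOOR = 1e-3  # deg; optimizer-internal clamp against degenerate Gaussians


@dataclass(frozen=True)
class SeedGrid:
    """Seed triples for the coarse search: 20 x 20 x 20 = 8000 candidates.

    Endpoints are inclusive ("from -8 to 8 in 20 steps" = spacing 16/19).
    Enumeration order is mu_x-major, then mu_y, then sigma; grid-search
    ties break toward the first occurrence in this order.
    """

    mu_values: np.ndarray = field(default_factory=lambda: np.linspace(-8.0, 8.0, 20))
    sigma_values: np.ndarray = field(default_factory=lambda: np.linspace(1.0, 5.0, 20))

    @property
    def n_seeds(self) -> int:
        return self.mu_values.size**2 * self.sigma_values.size

    def triples(self) -> np.ndarray:
        """(n_seeds, 3) array of (mu_x, mu_y, sigma) in enumeration order."""
        mx, my, s = np.meshgrid(
            self.mu_values, self.mu_values, self.sigma_values, indexing="ij"
        )
        return np.column_stack([mx.ravel(), my.ravel(), s.ravel()])


@dataclass
class FitConfig:
    """Thresholds and optimizer settings for pRF estimation."""

    variance_explained_min: float = 0.10
    ecc_max_deg: float = 8.0
    sigma_min_deg: float = 0.05
    hrf_subset_fraction: float = 0.15
    hrf_ve_threshold: float = 0.20
    hrf_iterations: int = 3
    tr_s: float = 1.2
    xatol: float = 2e-3
    fatol: float = 1e-7
    maxfev: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("variance_explained_min", "hrf_subset_fraction", "hrf_ve_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ecc_max_deg <= 0 or self.sigma_min_deg <= 0 or self.tr_s <= 0:
            raise ValueError("ecc_max_deg, sigma_min_deg and tr_s must be positive")


def _zscore_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit L2 norm; zero-variance rows become 0."""
    a = np.asarray(a, dtype=np.float32)
    c = a - a.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    ok = norm[:, 0] > 0
    c = np.divide(c, norm, out=np.zeros_like(c), where=norm > 0)
    return c, ok


class PredictionEngine:
    """Precomputed machinery for fast repeated prediction on one movie.

    Holds the movie in two forms — a dense pixel x time matrix for the
    seed bank (one BLAS matmul) and a pixel-major sparse index for the
    refinement objective, where the Gaussian is only evaluated inside a
    +/- 4 sigma window and only active (bar-on) pixels contribute.
    """

    def __init__(self, movie: StimulusMovie, hrf: HRFParams, tr_s: float = 1.2):
        if movie.n_frames == 0:
            raise ValueError("empty stimulus movie")
        self.movie = movie
        self.tr_s = float(tr_s)
        self.grid = movie.grid
        self.n = self.grid.n_pixels_per_side
        self.n_frames = movie.n_frames
        flat = movie.frames.reshape(self.n * self.n, self.n_frames)
        self._flat32 = np.ascontiguousarray(flat, dtype=np.float32)
        pix, fr = np.nonzero(flat)
        self._frame_idx = fr.astype(np.int32)
        counts = np.bincount(pix, minlength=self.n * self.n)
        self._indptr = np.concatenate([[0], np.cumsum(counts)])
        self._x = self.grid.pixel_centers

        ft = movie.frame_times_s
        self._dt = float(np.median(np.diff(ft)))
        vt = volume_times(movie, tr_s)
        self.n_volumes = vt.size
        i0 = np.clip(np.searchsorted(ft, vt, side="right") - 1, 0, ft.size - 2)
        self._interp_i0 = i0
        self._interp_w = ((vt - ft[i0]) / (ft[i0 + 1] - ft[i0])).astype(np.float64)
        self.set_hrf(hrf)
        self._bank_z: np.ndarray | None = None
        self._bank_params: np.ndarray | None = None

    # -- forward pieces ----------------------------------------------------

    def set_hrf(self, hrf: HRFParams) -> None:
        self.hrf = hrf
        self._kernel = hrf_kernel(hrf, self._dt)
        self._bank_z = None  # predictions depend on the HRF

    def overlap(self, mu_x: float, mu_y: float, sigma: float) -> np.ndarray:
        """Windowed per-frame overlap of the movie with one Gaussian."""
        s = max(abs(sigma), _SIGMA_FLOOR)
        half = 4.0 * s
        x = self._x
        j0 = int(np.searchsorted(x, mu_x - half))
        j1 = int(np.searchsorted(x, mu_x + half))
        i0 = int(np.searchsorted(x, mu_y - half))
        i1 = int(np.searchsorted(x, mu_y + half))
        out = np.zeros(self.n_frames)
        if j0 >= j1 or i0 >= i1:
            return out
        inv = 1.0 / (2.0 * s * s)
        gx = np.exp(-((x[j0:j1] - mu_x) ** 2) * inv)
        gy = np.exp(-((x[i0:i1] - mu_y) ** 2) * inv)
        idx_parts, w_parts = [], []
        indptr, frame_idx = self._indptr, self._frame_idx
        for ii in range(i0, i1):
            p0, p1 = ii * self.n + j0, ii * self.n + j1
            lo, hi = indptr[p0], indptr[p1]
            if hi == lo:
                continue
            cnts = np.diff(indptr[p0 : p1 + 1])
            idx_parts.append(frame_idx[lo:hi])
            w_parts.append(np.repeat(gy[ii - i0] * gx, cnts))
        if not idx_parts:
            return out
        return np.bincount(
            np.concatenate(idx_parts),
            weights=np.concatenate(w_parts),
            minlength=self.n_frames,
        )

    def predict_from_overlap(self, overlap: np.ndarray) -> np.ndarray:
        conv = np.convolve(overlap, self._kernel)[: self.n_frames]
        i0, w = self._interp_i0, self._interp_w
        return conv[i0] * (1.0 - w) + conv[i0 + 1] * w

    def predict(self, mu_x: float, mu_y: float, sigma: float) -> np.ndarray:
        return self.predict_from_overlap(self.overlap(mu_x, mu_y, sigma))

    # -- grid search -------------------------------------------------------

    def build_seed_bank(self, seeds: SeedGrid | None = None) -> None:
        """Precompute z-scored predictions for every seed (dense matmul)."""
        seeds = seeds or SeedGrid()
        params = seeds.triples()
        xx, yy = self.grid.mesh
        px = xx.ravel().astype(np.float32)
        py = yy.ravel().astype(np.float32)
        n_seeds = params.shape[0]
        bank = np.empty((n_seeds, self.n_volumes), dtype=np.float32)
        chunk = max(1, int(2e8 // (px.size * 4)))
        for a in range(0, n_seeds, chunk):
            b = min(a + chunk, n_seeds)
            p = params[a:b].astype(np.float32)
            g = np.exp(
                -((px[None, :] - p[:, 0:1]) ** 2 + (py[None, :] - p[:, 1:2]) ** 2)
                / (2.0 * p[:, 2:3] ** 2)
            )
            ov = g @ self._flat32  # (chunk, n_frames)
            for r in range(b - a):
                bank[a + r] = self.predict_from_overlap(ov[r].astype(np.float64))
        self._bank_raw = bank
        self._bank_z, _ = _zscore_rows(bank)
        self._bank_params = params

    def grid_search_batch(self, ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best seed triple and correlation per unit.

        ``ts``: (n_units, n_volumes). Zero-variance units get correlation
        NaN (flagged); ties break toward the first seed in enumeration
        order.
        """
        if self._bank_z is None:
            self.build_seed_bank()
        ts = np.atleast_2d(np.asarray(ts, dtype=np.float32))
        if ts.shape[1] != self.n_volumes:
            raise ValueError(
                f"time series length {ts.shape[1]} != prediction length {self.n_volumes}"
            )
        zts, ok = _zscore_rows(ts)
        n_units = ts.shape[0]
        best_idx = np.empty(n_units, dtype=np.int64)
        best_r = np.empty(n_units)
        step = max(1, int(4e7 // self._bank_z.shape[0]))
        for a in range(0, n_units, step):
            b = min(a + step, n_units)
            corr = zts[a:b] @ self._bank_z.T
            best_idx[a:b] = np.argmax(corr, axis=1)
            best_r[a:b] = corr[np.arange(b - a), best_idx[a:b]]
        best_r[~ok] = np.nan
        return self._bank_params[best_idx], best_r

    # -- refinement --------------------------------------------------------

    def _neg_corr_factory(self, ts: np.ndarray):
        c = ts - ts.mean()
        norm = np.linalg.norm(c)
        if norm == 0:
            raise ValueError("constant time series: correlation undefined")
        zts = c / norm

        def neg_corr(theta: np.ndarray) -> float:
            pred = self.predict(theta[0], theta[1], theta[2])
            pc = pred - pred.mean()
            denom = np.linalg.norm(pc)
            if denom == 0 or not np.isfinite(denom):
                return 0.0
            return -float(pc @ zts) / denom

        return neg_corr

    def refine(
        self, ts: np.ndarray, init: PRFParams, config: FitConfig | None = None
    ) -> PRFEstimate:
        config = config or FitConfig()
        neg_corr = self._neg_corr_factory(np.asarray(ts, dtype=float))
        x0 = np.array([init.mu_x, init.mu_y, init.sigma])
        r0 = -neg_corr(x0)
        res = minimize(
            neg_corr,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxfev": config.maxfev,
            },
        )
        if -res.fun >= r0:
            x, r, ok = res.x, -res.fun, bool(res.success)
        else:  # never return worse than the seed
            x, r, ok = x0, r0, False
        params = PRFParams(float(x[0]), float(x[1]), max(abs(float(x[2])), _SIGMA_FLOOR))
        return PRFEstimate(params=params, fit_correlation=float(r), converged=ok)


# ---------------------------------------------------------------------------
# public operations


def _as_matrix(ts_set) -> np.ndarray:
    if isinstance(ts_set, TimecourseSet):
        return np.asarray(ts_set.data, dtype=float)
    return np.atleast_2d(np.asarray(ts_set, dtype=float))


def grid_search(
    ts: np.ndarray,
    movie: StimulusMovie,
    hrf: HRFParams,
    seeds: SeedGrid | None = None,
    tr_s: float = 1.2,
) -> tuple[PRFParams, float]:
    """Coarse search for one unit; returns (best seed triple, correlation).

    Constant (zero-variance) series are flagged with correlation NaN.
    For many units, build a :class:`PredictionEngine` once and use
    :meth:`PredictionEngine.grid_search_batch`.
    """
    engine = PredictionEngine(movie, hrf, tr_s)
    engine.build_seed_bank(seeds)
    p, r = engine.grid_search_batch(np.atleast_2d(ts))
    return PRFParams(*map(float, p[0])), float(r[0])


def refine_fit(
    ts: np.ndarray,
    movie: StimulusMovie,
    hrf: HRFParams,
    init: PRFParams,
    config: FitConfig | None = None,
) -> PRFEstimate:
    """Simplex refinement of a seed triple for one unit."""
    config = config or FitConfig()
    engine = PredictionEngine(movie, hrf, config.tr_s)
    return engine.refine(ts, init, config)


def fit_dataset(
    ts_set,
    movie: StimulusMovie,
    config: FitConfig | None = None,
    hrf: HRFParams | None = None,
    engine: PredictionEngine | None = None,
) -> list[PRFEstimate]:
    """Grid search + refinement for every unit; order-aligned with input.

    Deterministic: no randomness enters the per-unit fits. Zero-variance
    units come back unconverged with correlation 0.
    """
    config = config or FitConfig()
    hrf = hrf or default_hrf()
    data = _as_matrix(ts_set)
    if engine is None:
        engine = PredictionEngine(movie, hrf, config.tr_s)
    seeds_p, seeds_r = engine.grid_search_batch(data)
    estimates: list[PRFEstimate] = []
    for i in range(data.shape[0]):
        if not np.isfinite(seeds_r[i]):
            params = PRFParams(*map(float, seeds_p[i]))
            estimates.append(PRFEstimate(params=params, fit_correlation=0.0, converged=False))
            continue
        init = PRFParams(*map(float, seeds_p[i]))
        estimates.append(engine.refine(data[i], init, config))
    return estimates


def apply_retention_filters(
    estimates: list[PRFEstimate], config: FitConfig | None = None
) -> tuple[list[PRFEstimate], pd.DataFrame]:
    """Keep estimates with ecc < 8 deg, sigma > 0.05 deg and VE > 10%
    (strict inequalities, so boundary values are rejected).

    Returns the retained estimates and a per-unit log recording which
    rule(s) each excluded unit violated; retained + rejected = total.
    """
    config = config or FitConfig()
    rows = []
    retained: list[PRFEstimate] = []
    for i, e in enumerate(estimates):
        reasons = []
        if not e.eccentricity < config.ecc_max_deg:
            reasons.append("eccentricity")
        if not e.params.sigma > config.sigma_min_deg:
            reasons.append("sigma")
        if not e.variance_explained > config.variance_explained_min:
            reasons.append("variance_explained")
        keep = not reasons
        if keep:
            retained.append(e)
        rows.append(
            {
                "unit_id": i,
                "retained": keep,
                "rejection_reasons": ";".join(reasons),
            }
        )
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HRF co-estimation

_BOUND_KEYS = ("delta", "alpha1", "alpha2", "beta1", "beta2", "ratio")


def select_hrf_units(
    ve: np.ndarray, fraction: float, threshold: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of the random HRF-fitting subset: ceil(fraction * n) of the
    units whose variance explained exceeds ``threshold``."""
    ve = np.asarray(ve, dtype=float)
    eligible = np.flatnonzero(np.nan_to_num(ve) > threshold)
    if eligible.size == 0:
        return eligible
    n_sel = math.ceil(fraction * eligible.size)
    return rng.choice(eligible, size=n_sel, replace=False)


def _hrf_to_unconstrained(p: HRFParams) -> np.ndarray:
    u = np.empty(6)
    for i, k in enumerate(_BOUND_KEYS):
        lo, hi = HRF_BOUNDS[k]
        v = np.clip(getattr(p, k), lo + 0.01 * (hi - lo), hi - 0.01 * (hi - lo))
        u[i] = math.log((v - lo) / (hi - v))
    return u


def _hrf_from_unconstrained(u: np.ndarray) -> HRFParams:
    vals = {}
    for i, k in enumerate(_BOUND_KEYS):
        lo, hi = HRF_BOUNDS[k]
        vals[k] = lo + (hi - lo) / (1.0 + math.exp(-float(u[i])))
    return HRFParams(**vals)


def estimate_hrf_for_dataset(
    ts_set,
    movies,
    config: FitConfig | None = None,
) -> HRFParams:
    """Co-estimate a dataset-level HRF from well-fit units.

    Procedure: (1) grid-search every unit with the canonical HRF on all
    runs jointly (units aligned across runs, predictions and data
    concatenated in time); (2) draw a seeded random 15% of the units whose
    variance explained exceeds 20%; (3) per unit, alternate a simplex fit
    of the six HRF parameters (pRF fixed, bounds enforced by logistic
    reparameterization) with a pRF refit (HRF fixed) for three iterations;
    (4) return the elementwise median across units. Falls back to the
    canonical HRF with a warning when no unit passes the threshold.
    """
    config = config or FitConfig()
    if not isinstance(movies, (list, tuple)):
        movies = [movies]
        ts_set = [ts_set]
    data = [_as_matrix(t) for t in ts_set]
    n_units = data[0].shape[0]
    if n_units == 0:
        raise ValueError("empty time-course set")
    if any(d.shape[0] != n_units for d in data):
        raise ValueError("all runs must contain the same units")

    hrf0 = default_hrf()
    engines = [PredictionEngine(m, hrf0, config.tr_s) for m in movies]
    for e in engines:
        e.build_seed_bank()
    cat = np.concatenate(data, axis=1)

    if len(engines) == 1:
        seeds_p, seeds_r = engines[0].grid_search_batch(data[0])
    else:
        # joint grid search across runs: correlate concatenated raw series
        raw = np.concatenate([e._bank_raw for e in engines], axis=1)
        bank_z, _ = _zscore_rows(raw)
        params = engines[0]._bank_params
        zts, ok = _zscore_rows(cat)
        corr = zts @ bank_z.T
        idx = np.argmax(corr, axis=1)
        seeds_p = params[idx]
        seeds_r = corr[np.arange(n_units), idx]
        seeds_r[~ok] = np.nan

    ve = np.square(seeds_r)
    chosen = select_hrf_units(
        ve, config.hrf_subset_fraction, config.hrf_ve_threshold,
        np.random.default_rng(config.seed),
    )
    if chosen.size == 0:
        warnings.warn(
            "no units exceed the HRF variance-explained threshold; "
            "falling back to the canonical HRF",
            stacklevel=2,
        )
        return hrf0

    def joint_neg_corr_hrf(u: np.ndarray, overlaps, zts_unit) -> float:
        try:
            hrf = _hrf_from_unconstrained(u)
        except ValueError:
            return 0.0
        preds = []
        for e, ov in zip(engines, overlaps):
            kern = hrf_kernel(hrf, e._dt)
            conv = np.convolve(ov, kern)[: e.n_frames]
            i0, w = e._interp_i0, e._interp_w
            preds.append(conv[i0] * (1.0 - w) + conv[i0 + 1] * w)
        pred = np.concatenate(preds)
        pc = pred - pred.mean()
        denom = np.linalg.norm(pc)
        if denom == 0:
            return 0.0
        return -float(pc @ zts_unit) / denom

    per_unit: list[np.ndarray] = []
    for ui in chosen:
        prf = PRFParams(*map(float, seeds_p[ui]))
        hrf_u = hrf0
        y = cat[ui]
        c = y - y.mean()
        zts_unit = c / np.linalg.norm(c)
        for _ in range(config.hrf_iterations):
            overlaps = [e.overlap(prf.mu_x, prf.mu_y, prf.sigma) for e in engines]
            res = minimize(
                joint_neg_corr_hrf,
                _hrf_to_unconstrained(hrf_u),
                args=(overlaps, zts_unit),
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-7, "maxfev": 600},
            )
            hrf_u = _hrf_from_unconstrained(res.x)
            for e in engines:
                e.set_hrf(hrf_u)
            if len(engines) == 1:
                est = engines[0].refine(data[0][ui], prf, config)
                prf = est.params
            else:
                # joint refinement across runs
                def neg_corr_prf(theta: np.ndarray) -> float:
                    pred = np.concatenate(
                        [e.predict(theta[0], theta[1], theta[2]) for e in engines]
                    )
                    pc = pred - pred.mean()
                    denom = np.linalg.norm(pc)
                    if denom == 0:
                        return 0.0
                    return -float(pc @ zts_unit) / denom

                res2 = minimize(
                    neg_corr_prf,
                    np.array([prf.mu_x, prf.mu_y, prf.sigma]),
                    method="Nelder-Mead",
                    options={
                        "xatol": config.xatol,
                        "fatol": config.fatol,
                        "maxfev": config.maxfev,
                    },
                )
                prf = PRFParams(
                    float(res2.x[0]),
                    float(res2.x[1]),
                    max(abs(float(res2.x[2])), _SIGMA_FLOOR),
                )
        per_unit.append(hrf_u.as_array())
        for e in engines:
            e.set_hrf(hrf0)  # reset for the next unit's first iteration

    med = np.median(np.stack(per_unit), axis=0)
    return HRFParams.from_array(med)
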