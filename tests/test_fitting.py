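"""Two-stage fitting: grid search, simplex refinement, HRF co-estimation
and retention filtering."""

import math

import numpy as np
import pytest

import logprf
from logprf.fitting import (
    FitConfig,
    PredictionEngine,
    SeedGrid,
    apply_retention_filters,
    estimate_hrf_for_dataset,
    fit_dataset,
    select_hrf_units,
)
from logprf.model import PRFEstimate, PRFParams, predict_timecourse


def test_seed_grid_counts_and_spacing():
    g = SeedGrid()
    assert g.n_seeds == 8000
    assert np.allclose(np.diff(g.mu_values), 16 / 19)
    assert np.allclose(np.diff(g.sigma_values), 4 / 19)
    t = g.triples()
    assert t.shape == (8000, 3)
    # mu_x-major enumeration: first 400 triples share mu_x = -8
    assert np.all(t[:400, 0] == -8.0)


class TestGridSearch:
    def test_exact_seed_recovered_noise_free(self, engine_log108):
        g = SeedGrid()
        triple = g.triples()[4321]
        ts = engine_log108.predict(*triple)
        p, r = engine_log108.grid_search_batch(ts[None])
        assert np.allclose(p[0], triple)
        assert r[0] == pytest.approx(1.0, abs=1e-5)

    def test_negated_prediction_is_not_argmax(self, engine_log108):
        triple = SeedGrid().triples()[4321]
        ts = -engine_log108.predict(*triple)
        p, _ = engine_log108.grid_search_batch(ts[None])
        assert not np.allclose(p[0], triple)

    def test_constant_series_flagged(self, engine_log108):
        ts = np.ones(engine_log108.n_volumes)
        _, r = engine_log108.grid_search_batch(ts[None])
        assert np.isnan(r[0])

    def test_batch_matches_naive_per_seed_loop(self, movies54, hrf):
        """Dual route: vectorized bank argmax vs plain per-seed Pearson
        correlation on a reduced seed grid."""
        fixed, _ = movies54
        seeds = SeedGrid(
            mu_values=np.linspace(-6, 6, 5), sigma_values=np.linspace(1, 4, 4)
        )
        triples = seeds.triples()
        preds = np.array(
            [predict_timecourse(fixed, PRFParams(*t), hrf, 1.2) for t in triples]
        )
        rng = np.random.default_rng(2)
        ts = preds[rng.integers(0, len(triples), 10)] + 0.3 * rng.standard_normal(
            (10, preds.shape[1])
        )
        engine = PredictionEngine(fixed, hrf, 1.2)
        engine.build_seed_bank(seeds)
        p_fast, r_fast = engine.grid_search_batch(ts)
        for i in range(10):
            corr = [np.corrcoef(ts[i], pr)[0, 1] for pr in preds]
            j = int(np.argmax(corr))
            assert np.allclose(p_fast[i], triples[j])
            assert r_fast[i] == pytest.approx(corr[j], abs=1e-4)


class TestRefine:
    def test_noise_free_truth_recovered(self, engine_log108, fit_config):
        ts = engine_log108.predict(1.0, 1.0, 0.5)
        p, _ = engine_log108.grid_search_batch(ts[None])
        est = engine_log108.refine(ts, PRFParams(*p[0]), fit_config)
        assert est.params.mu_x == pytest.approx(1.0, abs=0.05)
        assert est.params.mu_y == pytest.approx(1.0, abs=0.05)
        assert est.params.sigma == pytest.approx(0.5, abs=0.05)

    def test_refinement_never_decreases_correlation(self, engine_log108, fit_config):
        rng = np.random.default_rng(5)
        for _ in range(3):
            mu = rng.uniform(-4, 4, 2)
            ts = engine_log108.predict(mu[0], mu[1], rng.uniform(0.3, 2.0))
            ts = ts + 0.5 * np.std(ts) * rng.standard_normal(ts.size)
            p, r0 = engine_log108.grid_search_batch(ts[None])
            est = engine_log108.refine(ts, PRFParams(*p[0]), fit_config)
            assert est.fit_correlation >= r0[0] - 1e-12

    def test_affine_invariance(self, engine_log108, fit_config):
        rng = np.random.default_rng(6)
        ts = engine_log108.predict(2.0, -1.0, 0.8)
        ts = ts + 0.3 * np.std(ts) * rng.standard_normal(ts.size)
        p, _ = engine_log108.grid_search_batch(ts[None])
        a = engine_log108.refine(ts, PRFParams(*p[0]), fit_config)
        b = engine_log108.refine(3.7 * ts + 11.0, PRFParams(*p[0]), fit_config)
        assert a.params == b.params
        assert a.fit_correlation == pytest.approx(b.fit_correlation, abs=1e-12)


class TestFitDataset:
    def test_order_aligned_and_deterministic(self, movies108, hrf, engine_log108):
        rng = np.random.default_rng(7)
        truths = [PRFParams(*rng.uniform(-3, 3, 2), rng.uniform(0.3, 1.5)) for _ in range(5)]
        clean = np.array([engine_log108.predict(p.mu_x, p.mu_y, p.sigma) for p in truths])
        ts = clean + 0.2 * clean.std(axis=1, keepdims=True) * rng.standard_normal(clean.shape)
        cfg = FitConfig()
        est1 = fit_dataset(ts, movies108[1], cfg, hrf, engine=engine_log108)
        est2 = fit_dataset(ts, movies108[1], cfg, hrf, engine=engine_log108)
        assert len(est1) == 5
        for a, b, t in zip(est1, est2, truths):
            assert a.params == b.params  # determinism
            assert a.params.mu_x == pytest.approx(t.mu_x, abs=0.3)

    def test_noise_free_recovery_within_5_percent(self, movies108, hrf, engine_log108):
        """50 random pRFs (ecc 0.5-7, sigma 0.2-2) recovered from
        noise-free log-bar data within 5% relative error."""
        rng = np.random.default_rng(42)
        ecc = rng.uniform(0.5, 7.0, 50)
        ang = rng.uniform(0, 2 * np.pi, 50)
        sig = rng.uniform(0.2, 2.0, 50)
        truths = [
            PRFParams(e * np.cos(a), e * np.sin(a), s) for e, a, s in zip(ecc, ang, sig)
        ]
        clean = np.array([engine_log108.predict(p.mu_x, p.mu_y, p.sigma) for p in truths])
        est = fit_dataset(clean, movies108[1], FitConfig(), hrf, engine=engine_log108)
        for e, t in zip(est, truths):
            tol = 0.05 * t.eccentricity
            assert e.params.mu_x == pytest.approx(t.mu_x, abs=tol)
            assert e.params.mu_y == pytest.approx(t.mu_y, abs=tol)
            assert e.params.sigma == pytest.approx(t.sigma, rel=0.05)


class TestRetention:
    def _est(self, ecc, sigma, ve):
        mu = (ecc, 0.0)
        return PRFEstimate(
            params=PRFParams(mu[0], mu[1], sigma), fit_correlation=math.sqrt(ve)
        )

    def test_boundaries_are_exclusive(self):
        cfg = FitConfig()
        keep, _ = apply_retention_filters([self._est(7.9, 0.2, 0.5)], cfg)
        assert len(keep) == 1
        for bad in [self._est(8.0, 0.2, 0.5), self._est(7.9, 0.05, 0.5), self._est(7.9, 0.2, 0.10)]:
            keep, log = apply_retention_filters([bad], cfg)
            assert not keep
            assert log.loc[0, "rejection_reasons"] != ""

    def test_planted_violations_counted(self):
        cfg = FitConfig()
        rng = np.random.default_rng(3)
        good = [self._est(rng.uniform(0, 7), rng.uniform(0.1, 2), 0.5) for _ in range(20)]
        bad_ecc = [self._est(9.0, 0.5, 0.5) for _ in range(4)]
        bad_ve = [self._est(3.0, 0.5, 0.02) for _ in range(3)]
        keep, log = apply_retention_filters(good + bad_ecc + bad_ve, cfg)
        assert len(keep) == 20
        assert (log["rejection_reasons"] == "eccentricity").sum() == 4
        assert (log["rejection_reasons"] == "variance_explained").sum() == 3
        # conservation: retained + rejected = total
        assert log["retained"].sum() + (~log["retained"]).sum() == 27


class TestHRFEstimation:
    def test_selection_respects_fraction_and_threshold(self):
        rng = np.random.default_rng(0)
        ve = np.concatenate([np.full(40, 0.5), np.full(60, 0.05)])
        chosen = select_hrf_units(ve, 0.15, 0.20, rng)
        assert chosen.size == math.ceil(0.15 * 40)
        assert np.all(ve[chosen] > 0.20)
        assert select_hrf_units(np.full(10, 0.01), 0.15, 0.20, rng).size == 0

    def test_fallback_to_canonical_when_nothing_passes(self, movies54, hrf):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((6, 305))
        with pytest.warns(UserWarning):
            est = estimate_hrf_for_dataset(noise, movies54[0], FitConfig())
        assert est == logprf.default_hrf()

    def test_recovers_canonical_hrf_peak(self, movies108, hrf):
        """Simulated data with the canonical HRF: the co-estimated median
        HRF's peak time lands within 0.5 s of truth."""
        from logprf.simulate import NoiseModel, simulate_timecourses, stratified_subsample

        truth = logprf.build_ground_truth()
        sub = [truth[i] for i in stratified_subsample(truth, 40)]
        sim = simulate_timecourses(sub, movies108[0], hrf, NoiseModel(sd=0.15, seed=3), 1)
        est = estimate_hrf_for_dataset(sim.noisy[0], movies108[0], FitConfig(seed=4))
        t = np.arange(0.0, 30.0, 0.05)
        peak_true = t[np.argmax(logprf.evaluate_hrf(t, hrf))]
        peak_est = t[np.argmax(logprf.evaluate_hrf(t, est))]
        assert peak_est == pytest.approx(peak_true, abs=0.5)
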