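"""Dose-distribution models: outlier rejection, CAM/FMM/MAM estimation and
reliability classification, checked against closed forms and parameter
recovery on simulated samples."""

import warnings

import numpy as np
import pytest

from palaeosed import (ComponentFit, GrainSample, central_age_model,
                       classify_reliability, finite_mixture_model,
                       minimum_age_model, nmad_outlier_filter,
                       simulate_grain_sample)


def sample_from(de, rel=0.1, **kw):
    de = np.asarray(de, dtype=float)
    return GrainSample("t", de, rel * de, **kw)


class TestNmadFilter:
    def test_gross_outlier_rejected(self):
        gs = sample_from([100.0] * 9 + [1000.0])
        kept, rejected = nmad_outlier_filter(gs, threshold=2.0)
        assert list(rejected.de) == [1000.0]
        assert kept.n_grains == 9

    def test_computed_scores_drive_rejection(self):
        # oracle: recompute the robust z-scores directly
        rng = np.random.default_rng(0)
        de = 50 * np.exp(rng.normal(0, 0.2, 40))
        z = np.log(de)
        mad = np.median(np.abs(z - np.median(z)))
        scores = np.abs(z - np.median(z)) / (1.4826 * mad)
        kept, rejected = nmad_outlier_filter(sample_from(de), threshold=1.5)
        assert rejected.n_grains == int(np.sum(scores > 1.5))

    def test_identical_grains_all_kept(self):
        kept, rejected = nmad_outlier_filter(sample_from([50.0] * 8), 2.0)
        assert kept.n_grains == 8 and rejected.n_grains == 0

    def test_huge_threshold_keeps_all(self):
        gs = sample_from([10.0, 20.0, 30.0, 40.0, 500.0])
        kept, _ = nmad_outlier_filter(gs, threshold=1e9)
        assert kept.n_grains == 5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nmad_outlier_filter(sample_from([10.0] * 4), 2.0)
        with pytest.raises(ValueError):
            nmad_outlier_filter(sample_from([10.0] * 6), 0.0)


class TestCentralAgeModel:
    def test_identical_grains_identity(self):
        fit = central_age_model(sample_from([50.0] * 10))
        dose, se, prop = fit.components[0]
        assert dose == pytest.approx(50.0, rel=1e-6)
        assert fit.overdispersion == pytest.approx(0.0, abs=1e-4)
        assert prop == 1.0

    def test_equal_errors_reduce_to_log_mean(self):
        """With sigma-hat at 0 and equal relative errors, log delta is the
        arithmetic mean of log doses (inverse-variance oracle)."""
        de = np.array([99.0, 100.0, 101.0, 100.5, 99.5, 100.2])
        gs = GrainSample("t", de, 10.0 * de / 100.0)  # large equal rel errors
        fit = central_age_model(gs)
        assert fit.overdispersion == pytest.approx(0.0, abs=1e-5)
        assert fit.extra["log_dose"] == pytest.approx(
            np.mean(np.log(de)), abs=1e-8)

    def test_parameter_recovery(self):
        gs = simulate_grain_sample([(120.0, 1.0)], od=0.15, n_grains=500,
                                   rel_se=0.10, seed=1)
        fit = central_age_model(gs)
        dose, se, _ = fit.components[0]
        assert abs(dose - 120.0) < 3 * se
        assert abs(fit.overdispersion - 0.15) < 0.03

    def test_confidence_interval_coverage(self):
        """delta +/- 1.96 se covers the true dose ~95% of the time."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            gs = simulate_grain_sample([(80.0, 1.0)], od=0.12, n_grains=100,
                                       rel_se=0.08, seed=seed)
            fit = central_age_model(gs)
            dose, se, _ = fit.components[0]
            hits += abs(dose - 80.0) <= 1.96 * se
        assert 0.91 <= hits / n_rep <= 0.99


class TestFiniteMixtureModel:
    def test_single_component_selects_k1_and_matches_cam(self):
        gs = simulate_grain_sample([(90.0, 1.0)], od=0.10, n_grains=300,
                                   rel_se=0.08, seed=2)
        fmm = finite_mixture_model(gs, [1, 2, 3], sigma_b=0.10, seed=0)
        cam = central_age_model(gs)
        assert fmm.k == 1
        comb_se = np.hypot(fmm.components[0][1], cam.components[0][1])
        assert abs(fmm.components[0][0] - cam.components[0][0]) < comb_se

    def test_two_component_recovery(self):
        gs = simulate_grain_sample([(60.0, 0.3), (180.0, 0.7)], od=0.0,
                                   n_grains=600, rel_se=0.08, seed=3)
        fit = finite_mixture_model(gs, [1, 2, 3], sigma_b=0.10, seed=0)
        assert fit.k == 2
        (d1, _, p1), (d2, _, p2) = fit.components
        assert abs(p1 - 0.3) < 0.06 and abs(p2 - 0.7) < 0.06
        assert d1 == pytest.approx(60.0, rel=0.1)
        assert d2 == pytest.approx(180.0, rel=0.1)

    def test_deterministic_given_seed(self):
        gs = simulate_grain_sample([(60.0, 0.5), (150.0, 0.5)], od=0.05,
                                   n_grains=200, rel_se=0.08, seed=4)
        a = finite_mixture_model(gs, [1, 2, 3], 0.10, seed=5)
        b = finite_mixture_model(gs, [1, 2, 3], 0.10, seed=5)
        assert a.components == b.components and a.k == b.k

    def test_likelihood_nesting(self):
        gs = simulate_grain_sample([(60.0, 0.4), (150.0, 0.6)], od=0.0,
                                   n_grains=300, rel_se=0.08, seed=6)
        fit = finite_mixture_model(gs, [1, 2, 3], 0.10, seed=0)
        k1 = finite_mixture_model(gs, [1], 0.10, seed=0)
        assert fit.log_likelihood >= k1.log_likelihood - 1e-6
        assert all(p > 0 for _, _, p in fit.components)

    def test_invalid_candidates(self):
        gs = simulate_grain_sample([(60.0, 1.0)], n_grains=20, seed=7)
        with pytest.raises(ValueError):
            finite_mixture_model(gs, [], 0.10)
        with pytest.raises(ValueError):
            finite_mixture_model(gs, [10], 0.10)


class TestMinimumAgeModel:
    def test_identical_grains_return_that_dose(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = minimum_age_model(sample_from([75.0] * 20), sigma_b=0.10)
        assert fit.components[0][0] == pytest.approx(75.0, rel=0.01)

    def test_minimum_population_recovery(self):
        """40% of grains at 50 Gy plus grains smeared over 50-200 Gy:
        gamma recovers log 50 within 3 profile-likelihood se."""
        rng = np.random.default_rng(8)
        n = 300
        true = np.concatenate([np.full(120, 50.0), rng.uniform(50, 200, n - 120)])
        de = true * np.exp(rng.normal(0, 0.08, n))
        fit = minimum_age_model(sample_from(de, rel=0.08), sigma_b=0.10)
        assert not fit.extra["fallback_cam"]
        assert abs(fit.extra["gamma"] - np.log(50.0)) < 3 * fit.extra["gamma_se"]

    def test_never_exceeds_central_age(self):
        """The minimum-dose population can never postdate the central dose."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            true = np.concatenate([np.full(40, 60.0),
                                   rng.uniform(60, 250, 60)])
            de = true * np.exp(rng.normal(0, 0.1, 100))
            gs = sample_from(de)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mam = minimum_age_model(gs, 0.10)
            cam = central_age_model(gs)
            assert mam.dose <= cam.dose * (1 + 1e-9)


class TestReliability:
    def test_single_component(self):
        fit = ComponentFit("CAM", [(50.0, 2.0, 1.0)], 0.1, 0.0, 10)
        assert classify_reliability(fit).label == "single_component"

    def test_dominant_component_at_seventy_percent(self):
        fit = ComponentFit("FMM", [(50.0, 2.0, 0.28), (90.0, 3.0, 0.72)],
                           0.1, 0.0, 100)
        rc = classify_reliability(fit)
        assert rc.label == "dominant_component"
        assert rc.dominant_proportion == pytest.approx(0.72)

    def test_mixed_when_no_dominance(self):
        fit = ComponentFit("FMM", [(50.0, 2.0, 0.5), (90.0, 3.0, 0.3),
                                   (140.0, 4.0, 0.2)], 0.1, 0.0, 100)
        assert classify_reliability(fit).label == "mixed"

    def test_boundary_exactly_seventy(self):
        fit = ComponentFit("FMM", [(50.0, 2.0, 0.30), (90.0, 3.0, 0.70)],
                           0.1, 0.0, 100)
        assert classify_reliability(fit).label == "dominant_component"
        just_below = ComponentFit("FMM", [(50.0, 2.0, 0.301), (90.0, 3.0, 0.699)],
                                  0.1, 0.0, 100)
        assert classify_reliability(just_below).label == "mixed"

    def test_invariant_to_component_order(self):
        comps = [(90.0, 3.0, 0.72), (50.0, 2.0, 0.28)]
        a = ComponentFit("FMM", comps, 0.1, 0.0, 100)
        b = ComponentFit("FMM", list(reversed(comps)), 0.1, 0.0, 100)
        assert classify_reliability(a) == classify_reliability(b)
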