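import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fdperf.cohort import (CohortConfig, draw_cohort, generating_spec,
                           simulate_paired_dataset)
from fdperf.model import (FORMS, ModelSpec, PerformanceModel, VARIABLES,
                          adjusted_r2_from_resid, aic_sweep, composite_X,
                          fit_subset_ls, predict, prediction_error_summary)

GEN = generating_spec()


class TestCompositeX:
    def test_zeroed_coefficients_leave_alertness(self):
        assert composite_X(50.0, 123.0, 7.0, {"b6": 0, "b7": 0, "b8": 0}) == 50.0

    def test_cosine_at_zero_phase(self):
        assert composite_X(0.0, 0.0, 0.0, {"b6": 1.0, "b7": 0.0, "b8": 0.0}) \
            == pytest.approx(1.0)

    def test_quadrature_example(self):
        # 70 + 10*cos(90 deg) + 0.5*16 = 78
        x = composite_X(70.0, 60.0, 16.0, {"b6": 10.0, "b7": 30.0, "b8": 0.5})
        assert x == pytest.approx(78.0)

    def test_alertness_excluded_drops_a_term(self):
        x = composite_X(99.0, 0.0, 2.0, {"b6": 1.0, "b7": 0.0, "b8": 1.0},
                        include=("phase", "wake_duration"))
        assert x == pytest.approx(3.0)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            composite_X(float("nan"), 0.0, 0.0, {})


class TestPredict:
    def test_logistic_midpoint(self):
        spec = ModelSpec("logistic", params=dict(b1=2.0, b2=0.1, b3=1.0,
                                                 b4=3.0, b5=-1.5))
        X = 2.0  # b4 + b5*X = 0
        assert predict(spec, X, 4.0) == pytest.approx(2.0 + (0.4 + 1.0) / 2)

    def test_exponential_with_zero_rate_reduces_to_gain(self):
        spec = ModelSpec("exponential", params=dict(b1=1.0, b2=0.2, b3=0.5, b4=0.0))
        assert predict(spec, 123.0, 2.0) == pytest.approx(1.0 + (0.4 + 0.5))

    def test_linear_arithmetic_example(self):
        spec = ModelSpec("linear", params=dict(b1=1.0, b2=0.01, b3=0.5))
        assert predict(spec, 80.0, 50.0) == pytest.approx(81.0)

    def test_exponential_overflow_guarded(self):
        spec = ModelSpec("exponential", params=dict(b1=0.0, b3=1.0, b4=10.0))
        assert np.isfinite(predict(spec, 1e6, 0.0))

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_logistic_monotone_in_x_for_fixed_gain_sign(self, sign):
        spec = ModelSpec("logistic", params=dict(b1=0.0, b3=sign, b4=0.5, b5=0.8))
        xs = np.linspace(-30, 30, 301)
        p = predict(spec, xs, 0.0)
        assert np.all(np.diff(p) * sign * 0.8 > 0)


class TestFixedFit:
    @pytest.mark.parametrize("form,pars", [
        ("logistic", dict(GEN.params)),
        ("linear", dict(b1=5.7, b2=0.005, b3=0.02, b6=10.0, b7=180.0, b8=-0.5)),
        ("exponential", dict(b1=5.7, b2=0.02, b3=1.0, b4=-0.03,
                             b6=10.0, b7=180.0, b8=-0.5)),
    ])
    def test_zero_noise_recovery_all_forms(self, form, pars, noiseless_cohort):
        spec = ModelSpec(form, params=pars)
        df = simulate_paired_dataset(noiseless_cohort, n_obs=100, model=spec,
                                     rng=np.random.default_rng(31), noise_sd=0.0)
        res = PerformanceModel(df, form=form).fit(n_starts=8, seed=0)
        for k, v in pars.items():
            assert res.spec.params[k] == pytest.approx(v, rel=1e-4, abs=1e-6), k
        assert res.converged

    def test_alertness_excluded_fit_has_larger_residuals(self, noisy_paired):
        full = PerformanceModel(noisy_paired, form="logistic").fit(n_starts=5, seed=0)
        wo = PerformanceModel(noisy_paired, form="logistic",
                              include=("phase", "wake_duration", "sleep_debt")
                              ).fit(n_starts=5, seed=0)
        assert wo.rss > full.rss

    def test_nested_models_never_beat_full_on_rss(self, noisy_paired):
        full = PerformanceModel(noisy_paired, form="logistic").fit(n_starts=6, seed=0)
        for drop in VARIABLES:
            sub = tuple(v for v in VARIABLES if v != drop)
            res = PerformanceModel(noisy_paired, form="logistic",
                                   include=sub).fit(n_starts=6, seed=0)
            assert full.rss <= res.rss + 1e-6

    def test_aic_identity(self, noisy_paired):
        res = PerformanceModel(noisy_paired, form="logistic").fit(n_starts=4, seed=0)
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.loglik)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"P": [1.0, 2.0], "A": [50, 60], "C": [0, 10],
                           "T": [1, 2], "W": [0, 0], "participant_id": "p"})
        with pytest.raises(ValueError, match="observations"):
            PerformanceModel(df, form="logistic").fit()

    def test_summary_renders(self, noisy_paired):
        res = PerformanceModel(noisy_paired, form="logistic").fit(n_starts=4, seed=0)
        text = res.summary()
        assert "logistic" in text and "AIC" in text and "b5" in text


class TestOptimizerOracle:
    def test_reduced_three_parameter_problem_matches_brute_force_grid(self):
        """least-squares minimum over (b1, b3, b5) agrees with a nested
        brute-force grid search to 1e-6 in the objective."""
        truths = draw_cohort(CohortConfig(n_control=1, n_csr=1, noise_sd=0.0,
                                          re_sd_b1=0.0, re_sd_b3=0.0), seed=19)
        df = simulate_paired_dataset(truths, n_obs=30, model=GEN,
                                     rng=np.random.default_rng(23), noise_sd=0.0)
        fixed = {k: v for k, v in GEN.params.items()}
        free = ("b1", "b3", "b5")
        start = {"b1": 5.0, "b3": 0.5, "b5": -0.05}
        params, rss_opt = fit_subset_ls(df, "logistic", free, fixed, x0=start)

        # independent oracle: iteratively refined grid over the 3 parameters
        y = df["P"].to_numpy()
        A, C = df["A"].to_numpy(), df["C"].to_numpy()
        T, W = df["T"].to_numpy(), df["W"].to_numpy()

        def rss_at(b1, b3, b5):
            p = dict(fixed); p.update({"b1": b1, "b3": b3, "b5": b5})
            spec = ModelSpec("logistic", params=p)
            X = composite_X(A, C, T, p)
            r = y - predict(spec, X, W)
            return float(r @ r)

        centers = np.array([5.0, 0.5, -0.05])
        widths = np.array([2.0, 1.5, 0.1])
        best = np.inf
        for level in range(14):
            g1 = np.linspace(centers[0] - widths[0], centers[0] + widths[0], 9)
            g3 = np.linspace(centers[1] - widths[1], centers[1] + widths[1], 9)
            g5 = np.linspace(centers[2] - widths[2], centers[2] + widths[2], 9)
            vals = [(rss_at(a, b, c), a, b, c)
                    for a in g1 for b in g3 for c in g5]
            best, a, b, c = min(vals)
            centers = np.array([a, b, c])
            widths = widths / 3.0
        assert abs(best - rss_opt) <= 1e-6


class TestMixedFit:
    def test_degenerate_random_effects_agree_with_fixed(self):
        truths = draw_cohort(CohortConfig(noise_sd=0.2, re_sd_b1=0.0,
                                          re_sd_b3=0.0), seed=13)
        df = simulate_paired_dataset(truths, n_obs=150, model=GEN,
                                     rng=np.random.default_rng(14), noise_sd=0.2)
        m = PerformanceModel(df, form="logistic")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fx = m.fit(n_starts=5, seed=0, method="fixed")
            mx = m.fit(n_starts=5, seed=0, method="mixed")
        for k in ("b1", "b2", "b3", "b5", "b6", "b8"):
            assert mx.spec.params[k] == pytest.approx(fx.spec.params[k],
                                                      rel=0.05, abs=0.02), k

    def test_mixed_beats_fixed_adjusted_r2_on_random_effect_data(self):
        truths = draw_cohort(CohortConfig(noise_sd=0.2, re_sd_b1=0.3,
                                          re_sd_b3=0.15), seed=11)
        df = simulate_paired_dataset(truths, n_obs=200, model=GEN,
                                     rng=np.random.default_rng(12), noise_sd=0.2)
        m = PerformanceModel(df, form="logistic")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fx = m.fit(n_starts=5, seed=0, method="fixed")
            mx = m.fit(n_starts=5, seed=0, method="mixed")
        assert mx.adj_r2 > fx.adj_r2
        assert mx.random_effects is not None and len(mx.random_effects) == 17

    def test_random_intercept_sd_recovered(self):
        """Median estimated subject-intercept SD across seeded replicates is
        within 25% of the generating SD (0.3)."""
        ests = []
        for rep in range(5):
            truths = draw_cohort(CohortConfig(noise_sd=0.2, re_sd_b1=0.3,
                                              re_sd_b3=0.15), seed=40 + rep)
            df = simulate_paired_dataset(truths, n_obs=150, model=GEN,
                                         rng=np.random.default_rng(50 + rep),
                                         noise_sd=0.2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mx = PerformanceModel(df, form="logistic").fit(
                    n_starts=4, seed=rep, method="mixed")
            ests.append(mx.re_sd["b1"])
        assert abs(np.median(ests) - 0.3) / 0.3 <= 0.25

    def test_fewer_than_two_subjects_rejected(self):
        df = pd.DataFrame({"P": np.random.default_rng(0).normal(6, 1, 30),
                           "A": np.linspace(20, 90, 30), "C": 10.0,
                           "T": 5.0, "W": 0.0, "participant_id": "p1"})
        with pytest.raises(ValueError, match="2 subjects"):
            PerformanceModel(df, form="linear").fit(method="mixed", n_starts=2)


class TestSweepAndErrors:
    def test_sweep_has_16_rows_sorted_by_aic(self, noisy_paired):
        tab = aic_sweep(noisy_paired, form="logistic", n_starts=3, seed=0)
        assert len(tab) == 16
        finite = tab["aic"].to_numpy()
        assert np.all(np.diff(finite[np.isfinite(finite)]) >= -1e-9)
        assert tab["include"].str.contains("none").any()

    def test_prediction_errors_vanish_for_perfect_fit(self, noiseless_paired):
        res = PerformanceModel(noiseless_paired, form="logistic").fit(
            n_starts=6, seed=0)
        summ = prediction_error_summary(res, noiseless_paired)
        assert (summ["max_under_ms"] < 1e-3).all()
        assert (summ["max_over_ms"] < 1e-3).all()

    def test_constant_log2_shift_overestimates_by_factor_two(self, noiseless_paired):
        res = PerformanceModel(noiseless_paired, form="logistic").fit(
            n_starts=6, seed=0)
        shifted = res
        shifted.fittedvalues = noiseless_paired["P"].to_numpy() + np.log(2.0)
        summ = prediction_error_summary(shifted, noiseless_paired)
        obs_ms = np.exp(noiseless_paired["P"])
        frame = noiseless_paired.assign(ms=obs_ms)
        for row in summ.itertuples():
            assert row.max_under_ms == 0.0
            expect = frame[frame["participant_id"] == row.participant_id]["ms"].max()
            assert row.max_over_ms == pytest.approx(expect)

    def test_empty_pairs_rejected(self, noiseless_paired):
        res = PerformanceModel(noiseless_paired, form="logistic").fit(
            n_starts=2, seed=0)
        with pytest.raises(ValueError):
            prediction_error_summary(res, noiseless_paired.iloc[0:0])


class TestAdjustedR2:
    def test_hand_computed_five_point_example(self):
        # y on x: fit by hand with numpy, then verify the closed form
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        expect = 1 - (1 - r2) * 4 / 3
        assert adjusted_r2_from_resid(y, resid, 2) == pytest.approx(expect)

    def test_perfect_fit_scores_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert adjusted_r2_from_resid(y, np.zeros(4), 2) == pytest.approx(1.0)

    def test_intercept_only_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert adjusted_r2_from_resid(y, y - y.mean(), 1) == pytest.approx(0.0)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            adjusted_r2_from_resid(np.array([1.0, 2.0]), np.zeros(2), 3)
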