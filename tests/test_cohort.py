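import numpy as np
import pandas as pd
import pytest

from fdperf.cohort import (AlertnessParams, CohortConfig, GENERATING_PARAMS,
                           ParticipantTruth, draw_cohort,
                           generate_cohort_observations, generating_spec,
                           simulate_alertness, simulate_melatonin,
                           simulate_performance, simulate_paired_dataset,
                           true_phase)
from fdperf.model import ModelSpec, composite_X, predict
from fdperf.protocol import (build_schedule, classify_phase_window,
                             classify_time_window)


def _quiet_truth(condition="csr", period=24.2, phase0=60.0):
    return ParticipantTruth("p01", condition, period, phase0,
                            subject_effects={}, noise_sd=0.0)


class TestDrawCohort:
    def test_default_cohort_matches_study_composition(self):
        truths = draw_cohort(seed=0)
        assert len(truths) == 17
        assert sum(t.condition == "control" for t in truths) == 8
        assert sum(t.condition == "csr" for t in truths) == 9
        for t in truths:
            assert 23.5 < t.intrinsic_period < 25.0

    def test_deterministic_given_seed(self):
        a = draw_cohort(seed=5)
        b = draw_cohort(seed=5)
        assert [t.intrinsic_period for t in a] == [t.intrinsic_period for t in b]

    def test_period_outside_plausible_range_rejected(self):
        with pytest.raises(ValueError):
            ParticipantTruth("p", "csr", 22.0, 0.0)


class TestSimulateMelatonin:
    def test_noiseless_peak_equals_amplitude_and_trough_rectified(self):
        truth = _quiet_truth()
        peak = truth.peak_time
        df = simulate_melatonin(truth, [peak, peak + 12.1], amplitude=8.0,
                                noise_sd=0.0)
        assert df["value"].iloc[0] == pytest.approx(8.0)
        assert df["value"].iloc[1] == pytest.approx(0.0)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            simulate_melatonin(_quiet_truth(), [0.0], amplitude=0.0)


class TestSimulateAlertness:
    def test_constant_when_all_coefficients_zero(self):
        truth = _quiet_truth()
        schedule = build_schedule(truth.protocol, "p01")
        params = AlertnessParams(a0=70.0, a1=0.0, a2=0.0, a3=0.0,
                                 subject_sd=0.0, noise_sd=0.0)
        vas = simulate_alertness(truth, schedule, params)
        assert np.all(vas["value"] == 70.0)

    def test_monotone_decline_within_wake_episode_at_zero_phase_amplitude(self):
        truth = _quiet_truth()
        schedule = build_schedule(truth.protocol, "p01")
        params = AlertnessParams(a0=90.0, a1=0.0, a2=-0.5, a3=0.0,
                                 subject_sd=0.0, noise_sd=0.0)
        vas = simulate_alertness(truth, schedule, params)
        day1 = vas[vas["t_elapsed"] < truth.protocol.wake_per_day]
        assert np.all(np.diff(day1["value"]) < 0)

    def test_bounds_respected(self):
        truth = _quiet_truth()
        schedule = build_schedule(truth.protocol, "p01")
        vas = simulate_alertness(truth, schedule, AlertnessParams(),
                                 np.random.default_rng(0))
        assert vas["value"].between(0, 100).all()

    def test_optimal_conditions_beat_adverse_conditions(self):
        """Mean alertness in the optimal-phase & optimal-time bin exceeds the
        adverse & adverse bin, the qualitative pattern the generator encodes."""
        frames = []
        for seed, truth in enumerate(draw_cohort(
                CohortConfig(n_control=0, n_csr=3), seed=9)):
            schedule = build_schedule(truth.protocol, truth.participant_id)
            vas = simulate_alertness(truth, schedule, AlertnessParams(),
                                     np.random.default_rng(seed))
            vas["C"] = true_phase(truth, vas["t_elapsed"].to_numpy())
            vas["T"] = vas["t_elapsed"] % truth.protocol.day_length
            frames.append(vas)
        vas = pd.concat(frames)
        pw = vas["C"].map(classify_phase_window)
        tw = vas["T"].map(classify_time_window)
        best = vas[(pw == "optimal") & (tw == "optimal")]["value"].mean()
        worst = vas[(pw == "adverse") & (tw == "adverse")]["value"].mean()
        assert best > worst


class TestSimulatePerformance:
    def _sessions(self, truth, model, **kw):
        schedule = build_schedule(truth.protocol, truth.participant_id)
        vas_times = sorted({e.t_elapsed for e in schedule if e.kind == "vas"})
        vas = pd.DataFrame({"participant_id": truth.participant_id,
                            "kind": "vas", "t_elapsed": vas_times,
                            "value": 70.0})
        return schedule, vas, simulate_performance(
            truth, schedule, vas, model, np.random.default_rng(1), **kw)

    def test_noiseless_pvt_mean_is_exact_model_prediction(self):
        truth = _quiet_truth()
        model = generating_spec()
        schedule, vas, perf = self._sessions(truth, model, noise_sd=0.0)
        pvt = perf[perf["kind"] == "pvt"].reset_index(drop=True)
        from fdperf.protocol import sleep_debt
        for row in pvt.itertuples():
            C = float(true_phase(truth, row.t_elapsed))
            T = row.t_elapsed % truth.protocol.day_length
            W = sleep_debt(row.t_elapsed, truth.protocol)
            X = composite_X(70.0, C, T, model.params, model.include)
            assert row.value == pytest.approx(float(np.exp(predict(model, X, W))))

    def test_coefficient_zeroing_makes_pvt_depend_only_on_alertness(self):
        truth = _quiet_truth()
        model = ModelSpec("logistic", params=dict(GENERATING_PARAMS,
                                                  b2=0.0, b6=0.0, b8=0.0))
        _, _, perf = self._sessions(truth, model, noise_sd=0.0)
        pvt = perf[perf["kind"] == "pvt"]
        # constant alertness and zeroed phase/wake/debt coefficients:
        # identical session means at every test time
        assert pvt["value"].nunique() == 1

    def test_streams_respect_physical_bounds(self):
        truth = ParticipantTruth("p01", "csr", 24.2, 60.0,
                                 subject_effects={"b1": 0.1, "b3": -0.1,
                                                  "alert": 2.0},
                                 noise_sd=0.2)
        schedule = build_schedule(truth.protocol, "p01")
        vas = simulate_alertness(truth, schedule, AlertnessParams(),
                                 np.random.default_rng(3))
        perf = simulate_performance(truth, schedule, vas, generating_spec(),
                                    np.random.default_rng(4))
        pvt = perf[perf["kind"] == "pvt"]
        counts = perf[perf["kind"].isin(["add", "dsst"])]["value"]
        assert (pvt["value"] > 0).all() and (pvt["sd_ms"] > 0).all()
        assert (pvt["lapses"] >= 0).all()
        assert (counts >= 0).all()
        assert np.allclose(counts, np.round(counts))

    def test_missing_alertness_at_test_time_rejected(self):
        truth = _quiet_truth()
        schedule = build_schedule(truth.protocol, "p01")
        vas = pd.DataFrame({"participant_id": "p01", "kind": "vas",
                            "t_elapsed": [0.25], "value": [70.0]})
        with pytest.raises(ValueError, match="no alertness record"):
            simulate_performance(truth, schedule, vas, generating_spec(),
                                 np.random.default_rng(0))


class TestCohortLevel:
    def test_csr_week3_slower_than_week1(self):
        cfg = CohortConfig(n_control=0, n_csr=3, seed=17)
        truths = draw_cohort(cfg)
        obs = generate_cohort_observations(truths, cfg)
        pvt = obs[obs["kind"] == "pvt"].copy()
        pvt["week"] = (pvt["t_elapsed"] // (4 * 42.85)).astype(int) + 1
        w1 = pvt[pvt["week"] == 1]["value"].mean()
        w3 = pvt[pvt["week"] == 3]["value"].mean()
        assert w3 > w1

    def test_paired_dataset_shapes_and_determinism(self):
        truths = draw_cohort(CohortConfig(n_control=1, n_csr=1), seed=2)
        a = simulate_paired_dataset(truths, n_obs=50,
                                    rng=np.random.default_rng(8))
        b = simulate_paired_dataset(truths, n_obs=50,
                                    rng=np.random.default_rng(8))
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 100
        assert a["A"].between(0, 100).all()
        assert a["C"].between(0, 360, inclusive="left").all()
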