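"""Choice preprocessing, kinematics, GLMM, contrasts, Holm, RT models."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from motorhyst.behavior_stats import (
    central_contrasts,
    fit_choice_glmm,
    fit_rt_lmm,
    holm_correct,
    preprocess_choices,
    prime_analysis,
    rt_switch_analysis,
)
from motorhyst.glmm import fit_logistic_glmm, marginal_loglik
from motorhyst.kinematics import (
    TrajectoryTrace,
    clean_rt,
    compute_rt,
    lowpass_filter,
    movement_onset,
)


def trial_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "experiment", "block_type", "condition",
            "trial_index", "obstacle_x_mm", "side", "outcome", "rt_ms",
        ],
    )


class TestPreprocessChoices:
    def _fixture(self):
        rows = []
        rng = np.random.default_rng(2)
        for i in range(100):
            side = "none" if i in (10, 50) else rng.choice(["left", "right"])
            rows.append(("p0", 1, "experimental", "random", i,
                         float(rng.choice([-34.2, 0.0, 34.2])), side,
                         "fail" if side == "none" else "success", np.nan))
        return trial_frame(rows)

    def test_no_passage_trials_removed(self):
        out = preprocess_choices(self._fixture())
        assert len(out) == 98
        assert not (out["side"] == "none").any()

    def test_extremes_recoded(self):
        out = preprocess_choices(self._fixture())
        coded = out.loc[out["obstacle_x_mm"] == 34.2, "coded_position"]
        assert len(coded) > 0 and np.allclose(coded, 0.9)

    def test_prime_flag_manual_trace(self):
        rows = [
            ("p0", 1, "experimental", "random", 0, 0.0, "left", "success", np.nan),
            ("p0", 1, "experimental", "random", 1, 0.0, "right", "success", np.nan),
            ("p0", 1, "experimental", "random", 2, 0.0, "none", "fail", np.nan),
            ("p0", 1, "experimental", "random", 3, 0.0, "right", "success", np.nan),
            ("p0", 1, "experimental", "random", 4, 0.0, "right", "success", np.nan),
        ]
        out = preprocess_choices(trial_frame(rows))
        primes = list(out["prime"].fillna("NA"))
        # first trial: undefined; t1: left; t3: after no-passage -> undefined; t4: right
        assert primes == ["NA", "left", "NA", "right"]
        assert list(out["switch"].fillna("NA")) == ["NA", "switched", "NA", "repeated"]

    def test_unknown_condition_rejected(self):
        df = self._fixture()
        df.loc[0, "condition"] = "sideways"
        with pytest.raises(ValueError):
            preprocess_choices(df)


class TestLowpassFilter:
    def _trace(self, x, t_ms=None):
        n = len(x)
        t = np.arange(n) * 10.0 if t_ms is None else t_ms
        df = pd.DataFrame({"t_ms": t, "x_mm": x, "y_mm": np.zeros(n)})
        return TrajectoryTrace(df, exit_timestamp_ms=0.0)

    def test_constant_trace_unchanged(self):
        out = lowpass_filter(self._trace(np.full(100, 7.5)))
        assert np.allclose(out.samples["x_mm"], 7.5)

    def test_30hz_sinusoid_attenuated_to_squared_butterworth_gain(self):
        t = np.arange(0, 10, 0.01)  # 10 s at 100 Hz
        x = np.sin(2 * np.pi * 30 * t)
        out = lowpass_filter(self._trace(x, t_ms=t * 1000.0))
        mid = slice(200, -200)
        gain = np.abs(out.samples["x_mm"].to_numpy()[mid]).max()
        # the analog squared-magnitude bound at 3x cutoff is 1/(1+3^4) ~= 1.2%;
        # the digital realization warps frequencies toward Nyquist, so the
        # measured attenuation must be at least that strong (and nonzero)
        assert 1e-4 < gain < 1.0 / 82.0 * 1.05

    def test_zero_phase_keeps_pulse_peak(self):
        x = np.exp(-0.5 * ((np.arange(200) - 100) / 8.0) ** 2)
        out = lowpass_filter(self._trace(x))
        assert int(np.argmax(out.samples["x_mm"])) == 100

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(self._trace(np.zeros(5)))


class TestMovementOnset:
    def _trace_from_speed(self, speed_mm_s):
        # integrate a 1-D speed profile into displacement at 100 Hz
        x = np.concatenate([[0.0], np.cumsum(speed_mm_s[:-1]) * 0.01])
        df = pd.DataFrame(
            {"t_ms": np.arange(len(x)) * 10.0, "x_mm": x, "y_mm": np.zeros_like(x)}
        )
        return TrajectoryTrace(df)

    def test_stationary_trace_has_no_onset(self):
        trace = self._trace_from_speed(np.zeros(200))
        assert movement_onset(trace, exit_timestamp_ms=500.0) is None

    def test_trapezoidal_profile_crossing_detected(self):
        speed = np.zeros(300)
        speed[120:160] = np.linspace(0, 400, 40)  # ramp starting at 1200 ms
        speed[160:200] = 400.0
        trace = self._trace_from_speed(speed)
        onset = movement_onset(trace, exit_timestamp_ms=1250.0)
        # 50 mm/s is crossed 5 samples into the ramp (analytically 1250 ms);
        # central differencing smears the corner by at most one sample
        assert onset == pytest.approx(1250.0, abs=20.0)

    def test_nearest_crossing_to_exit_timestamp_wins(self):
        speed = np.zeros(300)
        speed[90:100] = 300.0  # crossing at 900 ms
        speed[119:200] = 300.0  # crossing at 1190 ms
        trace = self._trace_from_speed(speed)
        assert movement_onset(trace, exit_timestamp_ms=1205.0) == pytest.approx(1190.0, abs=10.0)
        assert movement_onset(trace, exit_timestamp_ms=900.0) == pytest.approx(900.0, abs=10.0)


class TestComputeRT:
    def _trace(self, redbox=None):
        df = pd.DataFrame({"t_ms": np.arange(10) * 10.0, "x_mm": np.zeros(10),
                           "y_mm": np.zeros(10)})
        return TrajectoryTrace(df, stimulus_onset_ms=0.0, redbox_offset_ms=redbox)

    def test_standard_task_references_stimulus(self):
        assert compute_rt(1, self._trace(), 350.0) == pytest.approx(350.0)

    def test_delayed_task_references_hold_release(self):
        assert compute_rt(2, self._trace(redbox=1800.0), 2100.0) == pytest.approx(300.0)

    def test_missing_onset_gives_none(self):
        assert compute_rt(1, self._trace(), None) is None

    def test_missing_reference_event_rejected(self):
        with pytest.raises(ValueError):
            compute_rt(2, self._trace(), 2100.0)


class TestCleanRT:
    def _base_rows(self, rts, pid="p0", cond="random"):
        return [
            (pid, 1, "experimental", cond, i, 0.0, "right", "success", rt)
            for i, rt in enumerate(rts)
        ]

    def test_missing_and_anticipation_rules(self):
        df = trial_frame(self._base_rows([np.nan, 90.0] + [400.0] * 10))
        retained, report = clean_rt(df)
        assert report.counts["missing"] == 1
        assert report.counts["anticipation"] == 1
        assert report.n_retained == 10

    def test_trial_outlier_rule_manual_fixture(self):
        rts = [400.0, 410, 390, 405, 395, 400, 410, 390, 405, 395, 400]
        mean = np.mean(rts)
        sd = np.std(rts + [mean + 3 * np.std(rts, ddof=1)], ddof=1)
        outlier = float(np.mean(rts) + 3 * np.std(rts, ddof=1))
        df = trial_frame(self._base_rows(rts + [outlier]))
        retained, report = clean_rt(df)
        assert report.counts["trial_outlier"] == 1
        assert outlier not in set(retained["rt_ms"])

    def test_identical_rts_survive_sd_rules(self):
        df = trial_frame(self._base_rows([400.0] * 12))
        retained, report = clean_rt(df)
        assert report.counts["trial_outlier"] == 0
        assert report.counts["participant_condition_outlier"] == 0
        assert report.n_retained == 12

    def test_participant_condition_outlier_rule(self):
        rows = []
        rng = np.random.default_rng(8)
        for p in range(10):
            center = 400.0 if p < 9 else 900.0  # one wildly slow participant
            rows += self._base_rows(
                list(center + rng.normal(0, 10, 12)), pid=f"p{p}", cond="random"
            )
        retained, report = clean_rt(trial_frame(rows))
        assert report.counts["participant_condition_outlier"] >= 10
        assert not (retained["participant_id"] == "p9").any()

    def test_cascade_is_deterministic(self):
        df = trial_frame(self._base_rows([np.nan, 90.0, 400, 410, 390, 800, 395, 405]))
        r1 = clean_rt(df)[1].to_dict()
        r2 = clean_rt(df)[1].to_dict()
        assert r1 == r2


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_correct([0.03]) == pytest.approx([0.03])

    def test_two_p_substitution(self):
        assert holm_correct([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_stepdown_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(50):
            m = rng.integers(1, 7)
            p = rng.uniform(0, 1, m)
            got = holm_correct(p)
            # brute-force step-down: reject smallest at alpha/m, then alpha/(m-1), ...
            order = np.argsort(p)
            oracle = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, min((m - rank) * p[idx], 1.0))
                oracle[idx] = running
            assert got == pytest.approx(oracle)
            assert got == pytest.approx(multipletests(p, method="holm")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.2])


def _bernoulli_fixture(rng, n_groups=3, n_per=20, sigma=0.0, beta=(0.3, 1.2)):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma)
        x = rng.uniform(-1, 1, n_per)
        eta = beta[0] + beta[1] * x + u
        y = rng.uniform(size=n_per) < 1 / (1 + np.exp(-eta))
        for xi, yi in zip(x, y):
            rows.append((f"g{g}", xi, int(yi)))
    df = pd.DataFrame(rows, columns=["group", "x", "y"])
    X = np.column_stack([np.ones(len(df)), df["x"]])
    return X, df["y"].to_numpy(float), df["group"].to_numpy()


class TestGLMM:
    def test_zero_variance_matches_plain_logistic(self):
        # independent groups with no group effect: the GLMM should collapse
        # to ordinary logistic regression
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X, y, g = _bernoulli_fixture(rng, n_groups=12, n_per=40, sigma=0.0)
        res = fit_logistic_glmm(X, y, g, ["intercept", "x"])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert res.beta == pytest.approx(np.asarray(glm.params), abs=5e-2)
        assert res.sigma < 0.3

    def test_loglik_matches_dense_quadrature_oracle(self):
        rng = np.random.default_rng(4)
        X, y, g = _bernoulli_fixture(rng, n_groups=3, n_per=20, sigma=0.8)
        slices = [(0, 20), (20, 40), (40, 60)]
        theta = np.array([0.2, 1.0, np.log(0.7)])
        fast = marginal_loglik(theta, X, y, slices, n_nodes=15, adaptive=True)
        slow = marginal_loglik(theta, X, y, slices, n_nodes=199, adaptive=False)
        assert fast == pytest.approx(slow, abs=1e-3)

    def test_recovers_group_variance(self):
        rng = np.random.default_rng(5)
        X, y, g = _bernoulli_fixture(rng, n_groups=40, n_per=40, sigma=1.0)
        res = fit_logistic_glmm(X, y, g, ["intercept", "x"])
        assert res.converged
        assert 0.5 < res.sigma < 1.6

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_glmm(np.ones((5, 2)), np.ones(4), np.arange(5))


class TestChoiceContrasts:
    def test_mirror_symmetric_data_gives_null_contrast(self):
        # left/right mirrored dataset: every condition effect cancels
        rng = np.random.default_rng(6)
        rows = []
        for p in range(12):
            for cond in ("rightwards", "leftwards", "random"):
                for i, x in enumerate(np.linspace(-34.2, 34.2, 29)):
                    pl = 1 / (1 + np.exp(-5.0 * (x / 38.0)))
                    side = "right" if rng.uniform() < pl else "left"
                    rows.append((f"p{p}", 1, "experimental", cond, i, float(x),
                                 side, "success", np.nan))
        df = preprocess_choices(trial_frame(rows))
        model = fit_choice_glmm(df)
        for c in central_contrasts(model):
            assert abs(c.estimate) < 3.0 * c.se + 1e-9

    def test_contrast_antisymmetry(self, exp1_choices):
        model = fit_choice_glmm(exp1_choices)
        res = central_contrasts(model)
        by_label = {c.label: c for c in res}
        rl = by_label["exp1: rightwards - leftwards"]
        rr = by_label["exp1: rightwards - random"].estimate
        lr = by_label["exp1: leftwards - random"].estimate
        assert rl.estimate == pytest.approx(rr - lr, abs=1e-9)

    def test_synthetic_cohort_shows_hysteresis(self, exp1_choices):
        model = fit_choice_glmm(exp1_choices)
        res = {c.label: c for c in central_contrasts(model)}
        hyst = res["exp1: rightwards - leftwards"]
        assert hyst.estimate > 0 and hyst.ci_low > 0

    def test_prime_effect_positive_on_synthetic_cohort(self, exp1_choices):
        _, prime = prime_analysis(exp1_choices)
        assert prime.estimate > 0 and prime.ci_low > 0


class TestRTModels:
    def _rt_rows(self, rng, cond_means, n_p=16, slow_p=0.0):
        rows = []
        for p in range(n_p):
            shift = rng.normal(0, 10)
            for cond, mu in cond_means.items():
                base = 0
                for i in range(29):
                    rt = rng.lognormal(np.log(mu + shift), 0.12)
                    side = rng.choice(["left", "right"])
                    rows.append((f"p{p:02d}", 1, "experimental", cond,
                                 base + i, 0.0, side, "success", float(rt)))
        return trial_frame(rows)

    def test_back_transform_reciprocal(self):
        # inverse-RT mean of 2.5 1/s corresponds to 400 ms
        assert 1000.0 / 2.5 == pytest.approx(400.0)

    def test_emms_recover_condition_means(self):
        rng = np.random.default_rng(9)
        df = self._rt_rows(rng, {"random": 420.0, "rightwards": 390.0, "leftwards": 390.0})
        clean = preprocess_choices(df)
        res = fit_rt_lmm(clean)
        assert res.emm_ms["random"][0] == pytest.approx(420.0, abs=15.0)
        assert res.emm_ms["rightwards"][0] == pytest.approx(390.0, abs=15.0)
        faster = [c for c in res.comparisons if c.label.startswith("rightwards - random")]
        assert faster[0].estimate > 0  # faster RT = larger inverse RT

    def test_zero_variance_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        rows = []
        for p in range(10):
            for cond, mu in (("random", 2.4), ("rightwards", 2.6), ("leftwards", 2.5)):
                for i in range(20):
                    inv = mu + rng.normal(0, 0.05)
                    rows.append((f"p{p}", 1, "experimental", cond, i, 0.0,
                                 "right", "success", 1000.0 / inv))
        df = preprocess_choices(trial_frame(rows))
        res = fit_rt_lmm(df)
        t = df.groupby(["participant_id", "condition"])["trial_index"].rank(method="first") - 1
        n = df.groupby(["participant_id", "condition"])["trial_index"].transform("size")
        tc = (t - (n - 1) / 2).to_numpy()
        d_l = (df["condition"] == "leftwards").to_numpy(float)
        d_r = (df["condition"] == "rightwards").to_numpy(float)
        X = np.column_stack([np.ones(len(df)), tc, d_l, d_r, tc * d_l, tc * d_r])
        ols = sm.OLS(1000.0 / df["rt_ms"].to_numpy(), X).fit()
        assert np.asarray(res.params) == pytest.approx(np.asarray(ols.params), abs=0.02)

    def test_switch_analysis_detects_repeat_benefit(self):
        rng = np.random.default_rng(11)
        rows = []
        for p in range(16):
            prev = "right"
            for i in range(60):
                side = rng.choice(["left", "right"])
                mu = 400.0 if side == prev else 430.0
                rows.append((f"p{p:02d}", 1, "experimental", "random", i, 0.0,
                             side, "success", float(rng.lognormal(np.log(mu), 0.1))))
                prev = side
        clean = preprocess_choices(trial_frame(rows))
        res = rt_switch_analysis(clean)
        assert res.emm_ms["switched"][0] > res.emm_ms["repeated"][0]
        assert res.comparisons[0].p_raw < 0.01
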