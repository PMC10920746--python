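"""Mixed-model comparison, within-subject CIs, correlations, confounds."""

import numpy as np
import pandas as pd
import pytest

from realness_ssvep import stats
from realness_ssvep import synthetic_data as sd
from realness_ssvep.synthetic_data import GenerativeParams


def amplitude_table(n_subj=6, seed=0, beta=(1.2, -0.175, 0.025),
                    subject_sd=0.3, noise_sd=1.0, n_sessions=4):
    design = sd.make_design(n_subj, n_sessions, seed=seed)
    params = GenerativeParams(beta=beta, subject_sd=subject_sd,
                              amplitude_noise_sd=noise_sd)
    return sd.simulate_amplitudes(design, params, seed=seed)


class TestCompareModels:
    def test_nesting_loglikelihood(self):
        for seed in range(5):
            mc = stats.compare_models(amplitude_table(seed=seed))
            assert mc.quadratic["llf"] >= mc.linear["llf"] - 1e-6
            assert mc.chi2 >= 0.0

    def test_aic_bic_reproduce_loglikelihood(self):
        mc = stats.compare_models(amplitude_table(seed=1))
        for fit in (mc.linear, mc.quadratic):
            assert fit["aic"] == pytest.approx(2 * fit["k"] - 2 * fit["llf"])
            assert fit["bic"] == pytest.approx(
                fit["k"] * np.log(mc.n_obs) - 2 * fit["llf"])
        assert mc.quadratic["k"] == mc.linear["k"] + 1

    def test_quadratic_generator_prefers_quadratic_model(self):
        mc = stats.compare_models(amplitude_table(n_subj=10, seed=3))
        assert mc.p < 0.05
        assert mc.quadratic["aic"] < mc.linear["aic"]

    def test_constant_response_degenerate(self):
        df = amplitude_table(seed=0)
        df["amplitude"] = 1.0
        mc = stats.compare_models(df)
        assert mc.degenerate
        assert mc.chi2 == 0.0
        assert mc.p == 1.0

    def test_recovers_generative_coefficients(self):
        # fixed effects estimated from session-averaged data should land
        # near the generating polynomial
        df = amplitude_table(n_subj=10, seed=7, n_sessions=8)
        mc = stats.compare_models(df)
        params = mc.quadratic["params"]
        assert params["realness"] == pytest.approx(-0.175, abs=0.1)
        assert params["I(realness ** 2)"] == pytest.approx(0.025, abs=0.015)

    def test_single_subject_rejected(self):
        df = amplitude_table()
        with pytest.raises(ValueError, match="two subjects"):
            stats.compare_models(df[df["subject"] == 1])

    def test_confound_column_used(self):
        df = amplitude_table(seed=2)
        eye = {r: 300.0 - 30.0 * min(r, 5) for r in range(1, 7)}
        df["eye_size"] = df["realness"].map(eye)
        mc = stats.compare_models(df, confound="eye_size")
        assert mc.confound == "eye_size"
        assert mc.linear["k"] == 5  # intercept, realness, eye_size + 2 var

    def test_type_i_error_near_nominal_small(self):
        # scaled-down null check; the full calibration runs in acceptance
        design = sd.make_design(10, 8, seed=0)
        null = GenerativeParams(beta=(1.0, 0.0, 0.0))
        hits = sum(
            stats.compare_models(
                sd.simulate_amplitudes(design, null, seed=s)).p < 0.05
            for s in range(60))
        assert 0 <= hits <= 9  # ~5% of 60, generous bound


class TestWithinSubjectCI:
    def test_constant_data_zero_halfwidth(self):
        df = pd.DataFrame({
            "subject": np.repeat([1, 2, 3], 2),
            "realness": np.tile([1, 2], 3),
            "amplitude": 5.0,
        })
        out = stats.within_subject_ci(df)
        assert np.allclose(out["ci_halfwidth"], 0.0)

    def test_centering_noop_without_subject_offsets(self):
        # when subjects share the same mean, the within-subject CI equals
        # the ordinary between-subject CI times the Morey factor
        rng = np.random.default_rng(0)
        n_subj, n_cond = 20, 4
        base = rng.normal(size=(n_subj, n_cond))
        base -= base.mean(axis=1, keepdims=True)  # zero subject offsets
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n_subj), n_cond),
            "realness": np.tile(np.arange(1, n_cond + 1), n_subj),
            "amplitude": base.ravel(),
        })
        out = stats.within_subject_ci(df)
        from scipy import stats as sps
        morey = np.sqrt(n_cond / (n_cond - 1))
        tcrit = sps.t.ppf(0.975, n_subj - 1)
        for k, cond in enumerate(range(1, n_cond + 1)):
            plain_sem = base[:, k].std(ddof=1) / np.sqrt(n_subj)
            row = out[out["realness"] == cond].iloc[0]
            assert row["ci_halfwidth"] == pytest.approx(
                tcrit * plain_sem * morey, rel=1e-9)

    def test_difference_coverage(self):
        # 95% CI on the condition difference: empirical coverage near
        # nominal over repeated two-condition experiments
        rng = np.random.default_rng(1)
        n_subj, runs, cover = 12, 400, 0
        for _ in range(runs):
            subj = rng.normal(0, 5.0, n_subj)  # large between-subject spread
            a = subj + rng.normal(0, 1.0, n_subj)
            b = subj + 1.0 + rng.normal(0, 1.0, n_subj)
            df = pd.DataFrame({
                "subject": np.tile(np.arange(n_subj), 2),
                "realness": np.repeat([1, 2], n_subj),
                "amplitude": np.concatenate([a, b]),
            })
            out = stats.within_subject_ci(df)
            diff = out["mean"].iloc[1] - out["mean"].iloc[0]
            half = np.hypot(out["ci_halfwidth"].iloc[0],
                            out["ci_halfwidth"].iloc[1])
            cover += abs(diff - 1.0) <= half
        assert 0.92 <= cover / runs <= 0.995

    def test_unbalanced_rejected(self):
        df = pd.DataFrame({"subject": [1, 1, 2], "realness": [1, 2, 1],
                           "amplitude": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="unbalanced"):
            stats.within_subject_ci(df)


class TestCorrelations:
    def test_collinear_gives_unit_correlation(self):
        stim = sd.make_stimulus_table(seed=0)
        stim["eye_size"] = 400.0 - 20.0 * stim["realness"]
        stim["realism"] = 1.0 + stim["realness"]
        stim["sclera_size"] = stim["eye_size"] * 0.4
        out = stats.stimulus_correlations(stim)
        r = out[(out["x"] == "eye_size")]["r"].iloc[0]
        assert abs(r) == pytest.approx(1.0)

    def test_partial_correlation_controlling_itself_is_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        r, p = stats.partial_correlation(y, x, covar=x)
        assert abs(r) < 1e-10
        assert p == 1.0

    def test_partial_correlation_matches_regression_oracle(self):
        # independent oracle: correlation of OLS residuals computed by hand
        rng = np.random.default_rng(4)
        c = rng.normal(size=80)
        x = 0.5 * c + rng.normal(size=80)
        y = -0.3 * c + 0.4 * x + rng.normal(size=80)
        r, _ = stats.partial_correlation(x, y, covar=c)
        def resid(v):
            A = np.column_stack([np.ones_like(c), c])
            return v - A @ np.linalg.lstsq(A, v, rcond=None)[0]
        expected = np.corrcoef(resid(x), resid(y))[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_confound_sign_recovered(self):
        neg = 0
        for seed in range(20):
            stim = sd.make_stimulus_table(confound_slope=-30.0, seed=seed)
            out = stats.stimulus_correlations(stim)
            neg += out[out["x"] == "eye_size"]["r"].iloc[0] < 0
        assert neg >= 19

    def test_amplitude_merge_and_partial(self):
        stim = sd.make_stimulus_table(seed=3)
        rng = np.random.default_rng(3)
        amps = pd.DataFrame({
            "image_id": np.repeat(np.arange(1, 37), 4),
            "amplitude": rng.normal(1.0, 0.2, 36 * 4),
        })
        out = stats.stimulus_correlations(stim, amps=amps)
        assert (out["kind"] == "partial").sum() == 1
        assert len(out) == 4

    def test_too_few_pairs_rejected(self):
        stim = sd.make_stimulus_table(seed=0).head(2)
        with pytest.raises(ValueError, match="pairs"):
            stats.stimulus_correlations(stim)


class TestConfoundBalance:
    def test_identical_distributions_yield_uniform_p(self):
        # generator draws R4 and R5 eye sizes from the same distribution
        ps = [stats.confound_balance_tests(
            sd.make_stimulus_table(seed=s)).iloc[0]["p"] for s in range(100)]
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac <= 0.12

    def test_zero_difference_gives_p_one(self):
        stim = sd.make_stimulus_table(seed=1)
        stim["eye_size"] = 100.0
        stim["luminosity"] = 50.0
        out = stats.confound_balance_tests(stim)
        assert (out["t"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_six_pairs_give_five_df(self):
        out = stats.confound_balance_tests(sd.make_stimulus_table(seed=0))
        assert (out["df"] == 5).all()

    def test_unpaired_rows_rejected(self):
        stim = sd.make_stimulus_table(seed=0)
        stim = stim[~((stim["realness"] == 6) & (stim["emotion"] == "happy"))]
        with pytest.raises(ValueError, match="paired"):
            stats.confound_balance_tests(stim)
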