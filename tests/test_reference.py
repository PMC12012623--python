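"""Reference-model tests: fits vs closed-form oracles, LOO, percentiles, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msrefcurve import (CovariateSpec, FULL_SPEC, RankDeficientDesignError,
                        ReferenceModelFit, assign_quartile, bootstrap_cis,
                        default_config, fit_beta, fit_linear, fit_spline_check,
                        generate_cohort, hc_reference, interaction_screen,
                        linear_predictor, loo_predictions, predict_nbv,
                        residual_percentile, score_deviations, stepwise_select)
from msrefcurve.reference import build_design

from conftest import scaled_config

PAPER_BETAS = {"age": -0.077, "sex[M]": -0.758, "disease_duration": -0.083,
               "phenotype[PPMS]": -1.038, "phenotype[RRMS]": -1.076,
               "phenotype[SPMS]": -1.787}


def paper_fit(intercept=86.6, sigma=2.8):
    """A ReferenceModelFit carrying the published coefficient vector."""
    return ReferenceModelFit("linear", FULL_SPEC, intercept, dict(PAPER_BETAS),
                             sigma, 0.265, 0.0, 972)


class TestFitLinear:
    def test_noiseless_cohort_recovers_truth_exactly(self):
        cfg = scaled_config(seed=3, scale=0.2)
        cfg.residual_sd = 1e-10
        coh = generate_cohort(cfg)
        fit = fit_linear(coh, FULL_SPEC)
        c = cfg.generative_coefficients
        truth = {"age": c.age, "sex[M]": c.male, "disease_duration": c.duration,
                 "phenotype[RRMS]": c.rrms, "phenotype[SPMS]": c.spms,
                 "phenotype[PPMS]": c.ppms}
        for k, v in truth.items():
            assert fit.coefficients[k] == pytest.approx(v, abs=1e-6)
        assert fit.intercept == pytest.approx(c.intercept, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_on_hand_rows(self):
        # eight hand-written rows; oracle = closed-form normal equations
        df = pd.DataFrame({
            "age": [30, 40, 50, 60, 35, 45, 55, 65],
            "sex": ["F", "M", "F", "M", "F", "M", "F", "M"],
            "nbv": [85.0, 83.2, 81.1, 78.9, 84.5, 82.0, 80.3, 77.5],
            "phenotype": ["HC"] * 8,
            "disease_duration": [0.0] * 8,
        })
        spec = CovariateSpec(terms=("age", "sex"))
        X, names = build_design(df, spec)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ df.nbv.to_numpy())
        fit = fit_linear(df, spec)
        got = np.array([fit.intercept] + [fit.coefficients[c] for c in names[1:]])
        np.testing.assert_allclose(got, beta_oracle, rtol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        cfg = scaled_config(seed=1, scale=0.1)
        coh = generate_cohort(cfg)
        coh["sex"] = "F"  # constant indicator, collinear with intercept
        with pytest.raises(RankDeficientDesignError) as err:
            fit_linear(coh, FULL_SPEC)
        assert any("sex" in c or "intercept" in c for c in err.value.columns)

    def test_too_few_rows_rejected(self):
        coh = generate_cohort(scaled_config(seed=1, scale=0.1)).head(6)
        with pytest.raises(ValueError, match="rows"):
            fit_linear(coh, FULL_SPEC)


class TestFitBeta:
    def test_predictions_inside_open_interval(self, small_cohort):
        coh, _ = small_cohort
        fit = fit_beta(coh, FULL_SPEC)
        pred = fit.predict(coh)
        assert np.all((pred > 0) & (pred < 100))

    def test_boundary_response_rejected(self, small_cohort):
        coh, _ = small_cohort
        bad = coh.copy()
        bad.loc[bad.index[0], "nbv"] = 100.0
        with pytest.raises(ValueError, match="strictly inside"):
            fit_beta(bad, FULL_SPEC)

    def test_recovers_logit_linear_mean(self):
        # simulate from the beta likelihood itself with a known mean link
        rng = np.random.default_rng(5)
        n = 1500
        age = rng.uniform(20, 70, n)
        sex = rng.choice(["F", "M"], n)
        eta = 1.5 - 0.012 * (age - 45) - 0.08 * (sex == "M")
        mu = 1 / (1 + np.exp(-eta))
        phi = 300.0
        y = rng.beta(mu * phi, (1 - mu) * phi)
        df = pd.DataFrame({"nbv": y * 100, "age": age - 45, "sex": sex,
                           "phenotype": "HC", "disease_duration": 0.0})
        fit = fit_beta(df, CovariateSpec(terms=("age", "sex")))
        assert fit.coefficients["age"] == pytest.approx(-0.012, abs=0.002)
        assert fit.coefficients["sex[M]"] == pytest.approx(-0.08, abs=0.02)
        assert fit.phi == pytest.approx(phi, rel=0.15)

    def test_near_constant_mean_predicts_sample_mean(self):
        rng = np.random.default_rng(6)
        n = 400
        y = rng.normal(0.82, 0.002, n)  # tiny dispersion, no covariate signal
        df = pd.DataFrame({"nbv": y * 100, "age": rng.uniform(-1, 1, n),
                           "sex": "F", "phenotype": "HC",
                           "disease_duration": 0.0})
        fit = fit_beta(df, CovariateSpec(terms=("age",)))
        assert np.allclose(fit.predict(df), 100 * y.mean(), atol=0.1)


class TestSplineCheck:
    def test_linear_truth_prefers_linear_mostly(self):
        wins = 0
        reps = 20
        for s in range(reps):
            coh = generate_cohort(scaled_config(seed=200 + s, scale=0.25))
            chk = fit_spline_check(coh, FULL_SPEC)
            wins += chk.preferred == "linear" or chk.delta < 2.0
        assert wins / reps >= 0.9

    def test_quadratic_age_effect_detected(self):
        cfg = scaled_config(seed=4, scale=0.4)
        coh = generate_cohort(cfg)
        coh["nbv"] = coh["nbv"] - 0.004 * (coh["age"] - 45) ** 2
        chk = fit_spline_check(coh, FULL_SPEC)
        assert chk.preferred == "spline"
        assert chk.aic_spline < chk.aic_linear

    def test_deterministic(self, small_cohort):
        coh, _ = small_cohort
        a = fit_spline_check(coh, FULL_SPEC)
        b = fit_spline_check(coh, FULL_SPEC)
        assert (a.aic_linear, a.aic_spline) == (b.aic_linear, b.aic_spline)


class TestStepwise:
    def test_all_true_effects_retained(self):
        # all four covariate blocks carry real effects at the full cohort
        # size, so selection should keep them in nearly every replicate
        kept = 0
        reps = 12
        for s in range(reps):
            coh = generate_cohort(default_config(seed=300 + s))
            spec = stepwise_select(coh, FULL_SPEC)
            kept += set(spec.terms) == set(FULL_SPEC.terms)
        assert kept >= 10

    def test_noise_covariate_mostly_excluded(self):
        excluded = 0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(400 + s)
            coh = generate_cohort(scaled_config(seed=400 + s, scale=0.3))
            coh["junk"] = rng.normal(size=len(coh))
            cand = CovariateSpec(terms=FULL_SPEC.terms + ("junk",))
            spec = stepwise_select(coh, cand)
            excluded += "junk" not in spec.terms
        assert excluded / reps >= 0.7

    def test_single_true_candidate_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"age": rng.uniform(20, 70, 200)})
        df["nbv"] = 90 - 0.1 * df.age + rng.normal(0, 1, 200)
        spec = stepwise_select(df, CovariateSpec(terms=("age",)))
        assert spec.terms == ("age",)

    def test_pvalue_mode_matches_on_strong_signal(self, default_cohort):
        spec = stepwise_select(default_cohort, FULL_SPEC, criterion="pvalue")
        assert set(spec.terms) == set(FULL_SPEC.terms)


class TestPredict:
    def test_sex_contrast_equals_published_beta(self):
        fit = paper_fit()
        base = dict(age=45.0, sex="F", disease_duration=10.0, phenotype="RRMS")
        male = base | {"sex": "M"}
        diff = predict_nbv(fit, male)[0] - predict_nbv(fit, base)[0]
        assert diff == pytest.approx(-0.758, abs=1e-12)

    def test_decade_of_age(self):
        fit = paper_fit()
        a = dict(age=40.0, sex="F", disease_duration=5.0, phenotype="RRMS")
        b = a | {"age": 50.0}
        assert (predict_nbv(fit, b) - predict_nbv(fit, a))[0] == pytest.approx(
            -0.77, abs=1e-9)

    def test_spms_vs_rrms_contrast(self):
        fit = paper_fit()
        a = dict(age=50.0, sex="F", disease_duration=15.0, phenotype="RRMS")
        b = a | {"phenotype": "SPMS"}
        assert (predict_nbv(fit, b) - predict_nbv(fit, a))[0] == pytest.approx(
            -0.711, abs=1e-9)

    def test_missing_covariate_fails(self):
        with pytest.raises(KeyError, match="missing"):
            predict_nbv(paper_fit(), dict(age=50.0, sex="F", phenotype="RRMS"))


class TestLeaveOneOut:
    def test_equals_hat_matrix_closed_form(self):
        # LOO residual = in-sample residual / (1 - leverage)
        cfg = scaled_config(seed=8, scale=0.18)
        coh = generate_cohort(cfg)
        assert len(coh) <= 200
        loo = loo_predictions(coh, FULL_SPEC)
        X, _ = build_design(coh, FULL_SPEC)
        y = coh.nbv.to_numpy()
        H = X @ np.linalg.solve(X.T @ X, X.T)
        resid_in = y - H @ y
        oracle = resid_in / (1.0 - np.diag(H))
        np.testing.assert_allclose(loo.residual.to_numpy(), oracle, atol=1e-8)

    def test_intercept_only_three_rows(self):
        df = pd.DataFrame({"nbv": [1.0, 2.0, 3.0]})
        loo = loo_predictions(df, CovariateSpec(terms=()))
        np.testing.assert_allclose(loo.predicted, [2.5, 2.0, 1.5])

    def test_noiseless_residuals_vanish(self):
        cfg = scaled_config(seed=3, scale=0.15)
        cfg.residual_sd = 1e-10
        coh = generate_cohort(cfg)
        loo = loo_predictions(coh, FULL_SPEC)
        assert np.abs(loo.residual).max() < 1e-6


class TestPercentilesAndQuartiles:
    def test_gaussian_anchor_points(self):
        assert residual_percentile(0.0, sigma=2.8)[0] == pytest.approx(50.0)
        assert residual_percentile(1.645 * 2.8, sigma=2.8)[0] == pytest.approx(
            95.0, abs=0.01)
        assert residual_percentile(-1.96 * 2.8, sigma=2.8)[0] == pytest.approx(
            2.5, abs=0.01)

    def test_gaussian_needs_positive_sigma(self):
        with pytest.raises(ValueError):
            residual_percentile([0.0], sigma=0.0)

    def test_ecdf_midranks(self):
        pct = residual_percentile([-1.0, 0.0, 1.0, 2.0], mode="ecdf")
        np.testing.assert_allclose(pct, [12.5, 37.5, 62.5, 87.5])

    def test_percentile_shift_invariance(self):
        rng = np.random.default_rng(0)
        r = rng.normal(0, 2.8, 100)
        base = residual_percentile(r, sigma=2.8)
        shifted = residual_percentile((r + 5.0) - 5.0, sigma=2.8)
        np.testing.assert_allclose(base, shifted)

    def test_quartile_examples(self):
        assert assign_quartile(10.0)[0] == 1
        assert assign_quartile(25.0)[0] == 2  # cutoff goes to the upper bin
        assert assign_quartile(100.0)[0] == 4

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_quartile_bins_partition(self, p):
        q = assign_quartile(p)[0]
        assert q in (1, 2, 3, 4)
        lo = {1: 0.0, 2: 25.0, 3: 50.0, 4: 75.0}[q]
        assert lo <= p and (p < lo + 25.0 or q == 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_quartile(101.0)

    def test_monotone_residual_monotone_percentile(self):
        r = np.linspace(-5, 5, 50)
        for mode, sig in (("gaussian", 2.8), ("ecdf", None)):
            pct = residual_percentile(r, sigma=sig, mode=mode)
            assert (np.diff(pct) >= 0).all()


class TestReferences:
    def test_hc_subject_on_curve_scores_fifty(self, small_cohort):
        coh, _ = small_cohort
        fit = hc_reference(coh)
        probe = coh[coh.phenotype == "HC"].head(1).copy()
        probe["nbv"] = fit.predict(probe)
        pct = residual_percentile(
            probe.nbv.to_numpy() - fit.predict(probe), sigma=fit.residual_scale)
        assert pct[0] == pytest.approx(50.0, abs=1e-9)

    def test_patients_fall_below_hc_curve(self, default_cohort):
        dev = score_deviations(default_cohort, "hc")
        assert dev.percentile.mean() < 50.0
        assert (dev.reference == "hc-based").all()

    def test_references_disagree_for_long_duration(self, default_cohort):
        dms = score_deviations(default_cohort, "ms")
        dhc = score_deviations(default_cohort, "hc")
        ms = default_cohort[default_cohort.phenotype != "HC"]
        long_dur = ms.disease_duration.to_numpy() > 20
        disagree = (dms.quartile.to_numpy() != dhc.quartile.to_numpy())
        assert disagree[long_dur].mean() > disagree[~long_dur].mean()
        assert disagree[long_dur].mean() > 0.3

    def test_no_hc_rows_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="healthy-control"):
            hc_reference(default_cohort[default_cohort.phenotype != "HC"])

    def test_quartile_counts_partition_cohort(self, default_cohort):
        for mode in ("gaussian", "ecdf"):
            dev = score_deviations(default_cohort, "ms", mode=mode)
            counts = dev.quartile.value_counts()
            assert counts.sum() == 713
            if mode == "ecdf":
                assert counts.max() - counts.min() <= 1


class TestBootstrap:
    def test_noiseless_cis_collapse(self):
        cfg = scaled_config(seed=2, scale=0.15)
        cfg.residual_sd = 1e-10
        coh = generate_cohort(cfg)
        res = bootstrap_cis(coh, FULL_SPEC, B=100, seed=0)
        for _, lo, hi in res.estimates.values():
            assert hi - lo < 1e-6

    def test_point_inside_interval(self, small_cohort):
        coh, _ = small_cohort
        res = bootstrap_cis(coh, FULL_SPEC, B=300, seed=1)
        assert res.n_replicates == 300
        for pt, lo, hi in res.estimates.values():
            assert lo <= pt <= hi

    def test_default_cohort_cis_exclude_zero(self, default_cohort):
        # every generative effect is nonzero and the CIs say so
        res = bootstrap_cis(default_cohort, FULL_SPEC, B=500, seed=2)
        for name, (pt, lo, hi) in res.estimates.items():
            if name == "intercept":
                continue
            assert lo > 0 or hi < 0, name

    def test_b_too_small_rejected(self, small_cohort):
        coh, _ = small_cohort
        with pytest.raises(ValueError):
            bootstrap_cis(coh, FULL_SPEC, B=1)


def test_parameter_recovery_means(default_cfg):
    # mean estimated coefficients track the generative values over replicates
    reps = 30
    est = []
    for s in range(reps):
        coh = generate_cohort(default_config(seed=1000 + s))
        fit = fit_linear(coh, FULL_SPEC)
        est.append([fit.coefficients[k] for k in PAPER_BETAS])
    est = np.asarray(est)
    mean = est.mean(axis=0)
    se = est.std(axis=0, ddof=1) / np.sqrt(reps)
    truth = np.asarray(list(PAPER_BETAS.values()))
    assert np.all(np.abs(mean - truth) < 4 * se + 1e-3)


def test_interaction_screen_prefers_main_effects(default_cohort):
    res = interaction_screen(default_cohort, FULL_SPEC)
    assert res["n_interaction_terms"] > 0
    assert res["preferred"] == "main-effects"
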