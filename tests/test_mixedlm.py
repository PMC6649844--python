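"""Random-intercept LMM estimation, per-patient test likelihood, and CV."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from das2c import cohorts, mixedlm, scores
from das2c.mixedlm import (
    CvReport,
    ModelSpec,
    assign_folds,
    compare_models,
    evidence_threshold,
    fit_lmm,
    kfold_cv,
    predict_fixed,
)
from das2c.mixedlm import test_loglik as out_of_sample_loglik
from conftest import analysis_ready, iacon_like_spec


def _simulated_lmm(seed, n_patients=400, visits=4,
                   beta=(10.0, 30.0, 15.0), tau2=100.0, sigma2=150.0):
    """Direct draw from the random-intercept model (no joint-grid step)."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 5, (n_patients, visits))
    x2 = rng.uniform(0, 4, (n_patients, visits))
    u = rng.normal(0, math.sqrt(tau2), (n_patients, 1))
    y = (beta[0] + beta[1] * x1 + beta[2] * x2 + u
         + rng.normal(0, math.sqrt(sigma2), (n_patients, visits)))
    return pd.DataFrame({
        "patient_id": np.repeat(np.arange(n_patients), visits),
        "gspd": y.ravel(), "sqrt_sjc28": x1.ravel(), "ln_crp1": x2.ravel(),
    })


SPEC_2C = ModelSpec(("sqrt_sjc28", "ln_crp1"))


def test_fit_lmm_recovers_truth_within_two_se():
    d = _simulated_lmm(0)
    fit = fit_lmm(d, SPEC_2C)
    truth = {"Intercept": 10.0, "sqrt_sjc28": 30.0, "ln_crp1": 15.0}
    for name, val in truth.items():
        assert abs(fit.beta[name] - val) <= 2 * fit.beta_se[name]
    assert fit.tau2 == pytest.approx(100.0, rel=0.35)
    assert fit.sigma2 == pytest.approx(150.0, rel=0.15)


def test_fit_lmm_boundary_tau2_zero():
    d = _simulated_lmm(1, n_patients=200, tau2=0.0)
    fit = fit_lmm(d, SPEC_2C)
    assert fit.tau2 == pytest.approx(0.0, abs=5.0)


def test_fit_lmm_matches_statsmodels_ml():
    """Independent mixed-model implementation agrees on coefficients,
    variance components and the ML log-likelihood."""
    d = _simulated_lmm(2, n_patients=60, visits=3)
    fit = fit_lmm(d, SPEC_2C)
    oracle = sm.MixedLM.from_formula(
        "gspd ~ sqrt_sjc28 + ln_crp1", groups="patient_id", data=d,
    ).fit(reml=False)
    np.testing.assert_allclose(
        fit.beta.to_numpy(),
        oracle.params[["Intercept", "sqrt_sjc28", "ln_crp1"]].to_numpy(),
        rtol=1e-4)
    assert fit.tau2 == pytest.approx(float(oracle.cov_re.iloc[0, 0]), rel=1e-3)
    assert fit.sigma2 == pytest.approx(oracle.scale, rel=1e-3)
    assert fit.loglik == pytest.approx(oracle.llf, abs=1e-3)


def test_fit_lmm_invariant_to_duplicating_data():
    d = _simulated_lmm(3, n_patients=50, visits=2)
    fit = fit_lmm(d, SPEC_2C)
    d2 = d.copy()
    d2["patient_id"] = d2["patient_id"] + 1000
    doubled = pd.concat([d, d2], ignore_index=True)
    fit2 = fit_lmm(doubled, SPEC_2C)
    np.testing.assert_allclose(fit.beta.to_numpy(), fit2.beta.to_numpy(),
                               rtol=1e-6)


def test_fit_lmm_errors():
    d = _simulated_lmm(4, n_patients=10, visits=2)
    d["dup"] = d["sqrt_sjc28"]
    with pytest.raises(ValueError, match="singular"):
        fit_lmm(d, ModelSpec(("sqrt_sjc28", "dup")))
    with pytest.raises(ValueError, match="fewer patients"):
        fit_lmm(d.iloc[:4], ModelSpec(("sqrt_sjc28", "ln_crp1", "dup")))
    d.loc[0, "ln_crp1"] = np.nan
    with pytest.raises(ValueError, match="missing cells"):
        fit_lmm(d, SPEC_2C)


def test_predict_fixed_structure():
    d = _simulated_lmm(5, n_patients=30, visits=2)
    fit = fit_lmm(d, SPEC_2C)
    zero = pd.DataFrame({"sqrt_sjc28": [0.0], "ln_crp1": [0.0]})
    assert predict_fixed(fit, zero)[0] == pytest.approx(fit.beta["Intercept"])
    # linear in ln(CRP+1) holding the joint count fixed
    grid = pd.DataFrame({"sqrt_sjc28": 1.0, "ln_crp1": [0.0, 1.0, 2.0]})
    pred = predict_fixed(fit, grid)
    assert np.diff(pred, 2) == pytest.approx([0.0], abs=1e-10)
    # matches the oracle's population-level prediction
    oracle = sm.MixedLM.from_formula(
        "gspd ~ sqrt_sjc28 + ln_crp1", groups="patient_id", data=d,
    ).fit(reml=False)
    np.testing.assert_allclose(predict_fixed(fit, d),
                               oracle.predict(d), rtol=1e-4)


def test_test_loglik_single_observation_closed_form():
    fit = _unit_fit()
    one = pd.DataFrame({"gspd": [0.0], "sqrt_sjc28": [0.0], "ln_crp1": [0.0],
                        "patient_id": ["a"]})
    assert out_of_sample_loglik(fit, one) == pytest.approx(-0.5 * math.log(2 * math.pi),
                                                  abs=1e-12)


def _unit_fit(tau2=0.0, sigma2=1.0):
    return mixedlm.LmmFit(
        spec=SPEC_2C,
        beta=pd.Series({"Intercept": 0.0, "sqrt_sjc28": 0.0, "ln_crp1": 0.0}),
        beta_se=pd.Series({"Intercept": 0.0, "sqrt_sjc28": 0.0, "ln_crp1": 0.0}),
        tau2=tau2, sigma2=sigma2, loglik=0.0, n_obs=1, n_groups=1)


def test_test_loglik_matches_dense_multivariate_normal():
    d = _simulated_lmm(6, n_patients=40, visits=3)
    fit = fit_lmm(d.iloc[:90], SPEC_2C)
    test = d.iloc[90:]
    dense = 0.0
    for _, g in test.groupby("patient_id"):
        r = g["gspd"].to_numpy() - predict_fixed(fit, g)
        n = len(g)
        cov = fit.sigma2 * np.eye(n) + fit.tau2 * np.ones((n, n))
        dense += multivariate_normal.logpdf(r, mean=np.zeros(n), cov=cov)
    assert out_of_sample_loglik(fit, test) == pytest.approx(dense, abs=1e-10)


def test_test_loglik_empty_test_set():
    with pytest.raises(ValueError, match="empty"):
        out_of_sample_loglik(_unit_fit(), pd.DataFrame(columns=[
            "gspd", "sqrt_sjc28", "ln_crp1", "patient_id"]))


def test_assign_folds_partitions_patients():
    patients = np.array([f"p{i}" for i in range(434)])
    folds = assign_folds(patients, 20, seed=0)
    sizes = np.bincount(list(folds.values()))
    assert sorted(set(sizes)) == [21, 22]
    assert set(folds) == set(patients)
    with pytest.raises(ValueError):
        assign_folds(patients[:5], 20, seed=0)
    with pytest.raises(ValueError):
        assign_folds(patients, 1, seed=0)


def test_kfold_cv_perfect_linear_data():
    d = _simulated_lmm(7, n_patients=60, visits=2, tau2=0.0, sigma2=1e-12)
    rep = kfold_cv(d, SPEC_2C, k=5, seed=0)
    assert rep.r2 > 0.999


def test_kfold_cv_folds_are_patient_disjoint():
    d = _simulated_lmm(8, n_patients=47, visits=3)
    rep = kfold_cv(d, SPEC_2C, k=10, seed=1)
    fold_of = rep.folds
    # every patient in exactly one fold; folds cover all patients
    assert set(fold_of) == set(d["patient_id"].unique())
    assert set(fold_of.values()) == set(range(10))


def test_in_sample_r2_exceeds_cv_r2_on_average():
    gaps = []
    for seed in range(10):
        d = _simulated_lmm(100 + seed, n_patients=50, visits=2, sigma2=400.0)
        fit = fit_lmm(d, SPEC_2C)
        pred = predict_fixed(fit, d)
        in_r2 = np.corrcoef(d["gspd"], pred)[0, 1] ** 2
        cv_r2 = kfold_cv(d, SPEC_2C, k=5, seed=seed).r2
        gaps.append(in_r2 - cv_r2)
    assert np.mean(gaps) > 0


def test_two_component_model_preferred_when_extra_effects_null():
    """With no true TJC/GHVAS effects, pooled CV evidence across the three
    cohort designs favours the 2C model over the 4C model."""
    spec4 = ModelSpec(("sqrt_sjc28", "ln_crp1", "sqrt_tjc28", "ghvas"))
    wins = 0
    n_seeds = 15
    for seed in range(n_seeds):
        truth = cohorts.TruthRecord(seed=500 + seed)
        specs = cohorts.default_development_specs(1.0)
        for s in specs:
            s.missingness_rates = {}
        dev = cohorts.generate_development_cohorts(
            specs, truth, include_ultrasound=False)
        delta = 0.0
        for tables in dev.values():
            d = analysis_ready(tables["visits"])
            folds = assign_folds(d["patient_id"].to_numpy(), 20, seed)
            r2 = kfold_cv(d, SPEC_2C, k=20, folds=folds)
            r4 = kfold_cv(d, spec4, k=20, folds=folds)
            delta += compare_models(r2, r4).delta_test_loglik
        wins += delta > 0
    assert wins >= 10


def test_evidence_threshold_constant():
    # half the 0.99 chi-square quantile at 2 df, minus 2
    assert evidence_threshold(2, 0.01) == pytest.approx(2.6052, abs=1e-4)
    assert round(evidence_threshold(), 1) == 2.6


def test_compare_models_semantics():
    d = _simulated_lmm(9, n_patients=40, visits=2)
    rep = kfold_cv(d, SPEC_2C, k=5, seed=0)
    same = compare_models(rep, rep)
    assert same.delta_test_loglik == 0.0
    other = kfold_cv(d, SPEC_2C, k=5, seed=99)
    with pytest.raises(ValueError, match="fold"):
        compare_models(rep, other)


def test_cv_report_deltas_from_best_nonpositive():
    d = _simulated_lmm(10, n_patients=45, visits=3)
    folds = assign_folds(d["patient_id"].to_numpy(), 5, 0)
    reports = [kfold_cv(d, ModelSpec(terms), k=5, folds=folds)
               for terms in (("sqrt_sjc28", "ln_crp1"), ("sqrt_sjc28",),
                             ("ln_crp1",))]
    best = max(r.test_loglik for r in reports)
    assert all(r.test_loglik - best <= 0 for r in reports)
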