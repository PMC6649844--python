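"""Censored-CRP ROS imputation, MICE/PMM, and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from das2c import imputation as imp
from das2c.imputation import CensoredSeries, mice_pmm, ros_impute, rubin_pool


# ---------------------------------------------------------------------------
# ROS
# ---------------------------------------------------------------------------

def test_ros_identity_without_censoring():
    s = CensoredSeries([6.0, 10.0, 20.0], [False] * 3, 5.0)
    res = ros_impute(s)
    np.testing.assert_array_equal(res.completed, [6.0, 10.0, 20.0])
    assert res.imputed.size == 0


def test_ros_five_vector_regression_fixture():
    """Frozen values from an independent hand implementation of ROS with
    Weibull plotting positions on {<5, <5, 6, 10, 20}."""
    s = CensoredSeries([5.0, 5.0, 6.0, 10.0, 20.0],
                       [True, True, False, False, False], 5.0)
    res = ros_impute(s)
    assert res.slope == pytest.approx(1.3234000631, abs=1e-9)
    assert res.intercept == pytest.approx(1.6193896389, abs=1e-9)
    np.testing.assert_allclose(res.imputed, [1.16113086, 2.21446247], atol=1e-7)
    # imputed values ordered, inside (0, threshold); detected untouched
    assert np.all(np.diff(res.imputed) >= 0)
    assert np.all((res.imputed > 0) & (res.imputed < 5.0))
    np.testing.assert_array_equal(res.completed[2:], [6.0, 10.0, 20.0])


def test_ros_imputed_below_threshold_on_lognormal_draws():
    rng = np.random.default_rng(0)
    x = rng.lognormal(np.log(6), 1.2, 500)
    cen = x < 5
    s = CensoredSeries(np.where(cen, 5.0, x), cen, 5.0)
    res = ros_impute(s)
    assert np.all(res.imputed < 5.0)
    assert np.all(res.imputed > 0.0)
    np.testing.assert_array_equal(res.completed[~cen], x[~cen])


@pytest.mark.parametrize("values,censored", [
    ([5.0, 5.0, 5.0], [True, True, True]),          # everything censored
    ([5.0, 6.0, 7.0, 5.0], [True, False, False, True]),  # <3 detected
    ([-1.0, 6.0, 7.0, 8.0], [True, False, False, False]),  # negative value
])
def test_ros_input_validation(values, censored):
    with pytest.raises(ValueError):
        ros_impute(CensoredSeries(values, censored, 5.0))


@pytest.mark.parametrize("imputed,want", [
    ([1.5, 1.88, 2.3], 2),
    ([1.88], 2),          # the published median, rounded up to the substitute
    ([3.4, 3.6], 4),      # median 3.5 rounds half-up
])
def test_select_single_substitute(imputed, want):
    assert imp.select_single_substitute(np.array(imputed)) == want


def test_select_single_substitute_empty():
    with pytest.raises(ValueError):
        imp.select_single_substitute(np.array([]))


def test_ros_substitute_on_calibrated_cohort():
    """Lognormal CRP calibrated to median 6 / upper quartile 18 mg/L,
    censored at 5: the median imputed value rounds to 2."""
    sigma = np.log(18 / 6) / stats.norm.ppf(0.75)
    rng = np.random.default_rng(12345)
    x = rng.lognormal(np.log(6.0), sigma, 889)
    cen = x < 5.0
    res = ros_impute(CensoredSeries(np.where(cen, 5.0, x), cen, 5.0))
    assert imp.select_single_substitute(res.imputed) == 2


# ---------------------------------------------------------------------------
# MICE with predictive mean matching
# ---------------------------------------------------------------------------

def test_mice_fully_observed_is_identity(small_dev_visits):
    complete = small_dev_visits.dropna().reset_index(drop=True)
    out = mice_pmm(complete, m=3, seed=0, n_cycles=2)
    for ds in out.datasets:
        pd.testing.assert_frame_equal(ds, complete)


def test_mice_pmm_donor_property_and_observed_cells(small_dev_visits):
    v = small_dev_visits
    out = mice_pmm(v, m=3, seed=1, n_cycles=3)
    for col in ("sjc28", "esr", "ghvas"):
        observed = v[col].dropna()
        miss = v[col].isna()
        for ds in out.datasets:
            assert ds[col].notna().all()
            # observed cells never change
            pd.testing.assert_series_equal(ds.loc[~miss, col],
                                           v.loc[~miss, col])
            # PMM: imputations are observed donor values (up to the
            # transform round-trip)
            if miss.any():
                donors = np.sort(observed.unique())
                vals = ds.loc[miss, col].to_numpy()
                nearest = donors[np.argmin(
                    np.abs(vals[:, None] - donors[None, :]), axis=1)]
                np.testing.assert_allclose(vals, nearest, rtol=1e-9, atol=1e-9)


def test_mice_reproducible_under_seed(small_dev_visits):
    a = mice_pmm(small_dev_visits, m=3, seed=9, n_cycles=2)
    b = mice_pmm(small_dev_visits, m=3, seed=9, n_cycles=2)
    for da, db in zip(a.datasets, b.datasets):
        pd.testing.assert_frame_equal(da, db)
    c = mice_pmm(small_dev_visits, m=3, seed=10, n_cycles=2)
    assert any(not da.equals(dc) for da, dc in zip(a.datasets, c.datasets))


def test_mice_input_validation(small_dev_visits):
    with pytest.raises(ValueError, match="m must be"):
        mice_pmm(small_dev_visits, m=1, seed=0)
    bad = small_dev_visits.copy()
    bad["esr"] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        mice_pmm(bad, m=3, seed=0)
    with pytest.raises(ValueError, match="GSPD"):
        mice_pmm(small_dev_visits, m=3, seed=0,
                 columns=["gspd", "sjc28"])


def test_mice_recovers_complete_data_coefficients():
    """With 15% MAR missingness imposed on CRP, pooled two-component
    coefficients stay within 2 pooled SEs of the complete-data fit."""
    from das2c import cohorts, mixedlm, scores
    from conftest import analysis_ready, iacon_like_spec

    spec = iacon_like_spec(250)
    dev = cohorts.generate_development_cohorts(
        [spec], cohorts.TruthRecord(seed=77), include_ultrasound=False)
    v = dev["SIM"]["visits"]
    model = mixedlm.ModelSpec(("sqrt_sjc28", "ln_crp1"))
    complete_fit = mixedlm.fit_lmm(analysis_ready(v), model)

    rng = np.random.default_rng(3)
    from scipy.special import logit
    miss = rng.random(len(v)) < expit(
        logit(0.15) + 0.5 * (v["haq"] - v["haq"].mean()))
    vm = v.copy()
    vm.loc[miss, "crp"] = np.nan
    vm.loc[miss, "crp_censored"] = False
    assert 0.10 < miss.mean() < 0.20

    out = mice_pmm(vm, m=10, seed=4, n_cycles=3)
    betas, variances = [], []
    for ds in out.datasets:
        fit = mixedlm.fit_lmm(analysis_ready(ds, dropna=False), model)
        betas.append(fit.beta.to_numpy())
        variances.append(fit.beta_se.to_numpy() ** 2)
    pooled = rubin_pool(np.array(betas), np.array(variances))
    diff = np.abs(pooled.estimate - complete_fit.beta.to_numpy())
    assert np.all(diff <= 2.0 * pooled.se)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def test_rubin_pool_hand_values():
    pooled = rubin_pool([[1.0], [2.0]], [[1.0], [1.0]])
    assert pooled.estimate[0] == pytest.approx(1.5)
    assert pooled.total_variance[0] == pytest.approx(1.75)  # 1 + 1.5*0.5


def test_rubin_pool_degenerate_between_variance():
    pooled = rubin_pool([[3.0], [3.0], [3.0]], [[0.5], [0.7], [0.6]])
    assert pooled.between[0] == 0.0
    assert pooled.total_variance[0] == pytest.approx(0.6)
    assert np.isinf(pooled.df[0])


def test_rubin_pool_total_at_least_within():
    rng = np.random.default_rng(5)
    est = rng.normal(size=(8, 4))
    var = rng.uniform(0.1, 1.0, size=(8, 4))
    pooled = rubin_pool(est, var)
    assert np.all(pooled.total_variance >= pooled.within - 1e-12)


def test_rubin_pool_validation():
    with pytest.raises(ValueError):
        rubin_pool([[1.0]], [[1.0]])
    with pytest.raises(ValueError):
        rubin_pool([[1.0], [2.0]], [[1.0]])


def test_rubin_pool_ci_coverage_under_mar():
    """Pooled t-interval for a regression coefficient attains roughly
    nominal 95% coverage across replicated MAR datasets."""
    def one_rep(seed, n=120, m=20):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1, n)
        x = 0.6 * z + rng.normal(0, 0.8, n)
        y = 1.0 + 0.5 * x + 0.3 * z + rng.normal(0, 0.7, n)
        miss = rng.random(n) < expit(-1.8 + z)
        df = pd.DataFrame({"xvar": np.where(miss, np.nan, x),
                           "zvar": z, "yvar": y})
        comp = mice_pmm(df, m=m, seed=seed, n_cycles=2, k_pmm=5,
                        columns=["xvar", "zvar", "yvar"])
        est, var = [], []
        for ds in comp.datasets:
            res = sm.OLS(ds["yvar"], sm.add_constant(ds[["xvar", "zvar"]])).fit()
            est.append([res.params["xvar"]])
            var.append([res.bse["xvar"] ** 2])
        pooled = rubin_pool(np.array(est), np.array(var), dfcom=n - 3)
        return pooled.ci_lower[0] <= 0.5 <= pooled.ci_upper[0]

    coverage = np.mean([one_rep(s) for s in range(100)])
    assert 0.89 <= coverage <= 1.0
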