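"""Left-censored and missing-data imputation.

Two distinct problems are handled here:

* CRP values reported only as "below the assay limit" (left-censored at a
  single threshold, typically 5 mg/L).  These are imputed by robust
  regression on order statistics (ROS): a lognormal quantile-quantile
  regression is fitted to the detected values at censoring-adjusted
  Weibull plotting positions, and censored observations are replaced by
  back-transformed predictions at their own plotting positions.  The
  median of the imputed values, rounded to the nearest integer, gives the
  single substitute recommended for routine scoring.

* Missing covariates, imputed by chained equations with predictive mean
  matching (PMM) on the analysis scales (sqrt counts, log reactants), and
  results across imputations pooled by Rubin's rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.mice import MICEData

__all__ = [
    "CensoredSeries",
    "RosResult",
    "ros_impute",
    "select_single_substitute",
    "CompletedDatasets",
    "mice_pmm",
    "PooledEstimate",
    "rubin_pool",
    "MICE_TRANSFORMS",
]


@dataclass
class CensoredSeries:
    """Values with a left-censoring indicator at a single threshold."""

    values: np.ndarray
    censored: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censored flags differ in length")
        if self.threshold <= 0:
            raise ValueError("censoring threshold must be positive")


@dataclass
class RosResult:
    """Completed series plus the fitted lognormal Q-Q line."""

    completed: np.ndarray
    imputed: np.ndarray          # imputed values, ascending
    slope: float
    intercept: float
    plotting_positions_detected: np.ndarray
    plotting_positions_censored: np.ndarray
    n_capped: int = 0            # predictions capped just below threshold


def ros_impute(series: CensoredSeries) -> RosResult:
    """Impute left-censored values by robust regression on order statistics.

    Detected values are never altered.  A line ``ln(x) = a + b*z(p)`` is
    fitted by least squares to the detected values at Weibull plotting
    positions adjusted for the censored fraction; censored observations
    are replaced by back-transformed predictions at plotting positions
    spread over the sub-threshold probability range, so the imputed
    values are ordered and lie below the threshold.
    """
    v, cen, thr = series.values, series.censored, series.threshold
    if np.any(~np.isfinite(v)):
        raise ValueError("non-finite values in censored series")
    if np.any(v < 0):
        raise ValueError("negative values in censored series")
    n = v.size
    n_cen = int(cen.sum())
    if n_cen == 0:
        return RosResult(v.copy(), np.empty(0), math.nan, math.nan,
                         np.empty(0), np.empty(0))
    detected = v[~cen]
    if detected.size < 3:
        raise ValueError("ROS needs at least 3 detected values")
    if np.any(detected < thr):
        raise ValueError("detected value below the censoring threshold; "
                         "ROS here assumes a single left threshold")
    if np.any(detected <= 0):
        raise ValueError("detected values must be positive for a lognormal fit")

    # Exceedance probability of the threshold; with a single limit the
    # Hirsch-Stedinger/Weibull machinery reduces to the detected fraction.
    pe = detected.size / n
    order = np.argsort(detected)
    i_det = np.arange(1, detected.size + 1)
    p_det = (1.0 - pe) + pe * i_det / (detected.size + 1.0)
    i_cen = np.arange(1, n_cen + 1)
    p_cen = (1.0 - pe) * i_cen / (n_cen + 1.0)

    z_det = stats.norm.ppf(p_det)
    slope, intercept = np.polyfit(z_det, np.log(detected[order]), 1)
    pred = np.exp(intercept + slope * stats.norm.ppf(p_cen))

    # A weak fit can push the largest prediction marginally past the
    # threshold; cap it so imputed values always stay strictly below.
    cap = np.nextafter(thr, 0.0)
    n_capped = int(np.sum(pred >= thr))
    pred = np.minimum(pred, cap)

    completed = v.copy()
    completed[np.flatnonzero(cen)] = pred  # ascending, in index order
    return RosResult(completed, pred, float(slope), float(intercept),
                     p_det, p_cen, n_capped)


def select_single_substitute(imputed: np.ndarray) -> int:
    """Single substitute for censored CRP: median of imputed values,
    rounded half-up to the nearest integer."""
    imputed = np.asarray(imputed, dtype=float)
    if imputed.size == 0:
        raise ValueError("no imputed values")
    med = float(np.median(imputed))
    return int(math.floor(med + 0.5))


# ---------------------------------------------------------------------------
# Multiple imputation by chained equations with predictive mean matching
# ---------------------------------------------------------------------------

#: Analysis-scale transforms used inside the chained equations.
MICE_TRANSFORMS = {
    "tjc28": (np.sqrt, np.square, "sqrt_tjc28"),
    "sjc28": (np.sqrt, np.square, "sqrt_sjc28"),
    "crp": (lambda x: np.log(x + 1.0), lambda z: np.exp(z) - 1.0, "ln_crp1"),
    "esr": (lambda x: np.log(np.maximum(x, 1.0)), np.exp, "ln_esr"),
    "ghvas": (None, None, "ghvas"),
    "haq": (None, None, "haq"),
    "age": (None, None, "age"),
    "sex": (None, None, "sex"),
}


@dataclass
class CompletedDatasets:
    """m completed copies of a visit table (observed cells untouched)."""

    m: int
    datasets: list[pd.DataFrame]
    seed: int
    n_cycles: int = 10
    k_pmm: int = 5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 imputations for pooling")
        if len(self.datasets) != self.m:
            raise ValueError("dataset count does not match m")


def mice_pmm(
    visits: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_cycles: int = 10,
    k_pmm: int = 5,
    columns: list[str] | None = None,
) -> CompletedDatasets:
    """Multiply impute missing covariates by chained equations with PMM.

    The chained equations run on the analysis scales (sqrt joint counts,
    log acute-phase reactants); PMM draws each imputation from observed
    donor values, so back-transformed imputations always belong to the
    observed support.  The outcome (GSPD) must not be passed in
    ``columns`` and is never used as a predictor.  ``m`` independent
    chains are run, each for ``n_cycles`` full cycles.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if columns is None:
        columns = [c for c in MICE_TRANSFORMS if c in visits.columns]
    if "gspd" in columns:
        raise ValueError("GSPD must be excluded from the imputation model")
    for col in columns:
        if visits[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing")

    fwd = {}
    work = pd.DataFrame(index=visits.index)
    for col in columns:
        f, _, tname = MICE_TRANSFORMS.get(col, (None, None, col))
        x = visits[col].astype(float)
        work[tname] = f(x) if f is not None else x
        fwd[tname] = col

    passthrough = visits.drop(columns=columns)
    any_missing = work.isna().any().any()

    datasets: list[pd.DataFrame] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(m)]
    for i in range(m):
        if not any_missing:
            completed_t = work.copy()
        else:
            np.random.seed(child_seeds[i])  # MICEData draws from the global RNG
            imp = MICEData(work.reset_index(drop=True), k_pmm=k_pmm)
            imp.update_all(n_cycles)
            completed_t = imp.data.set_axis(work.index, axis=0)
        out = passthrough.copy()
        for tname, col in fwd.items():
            _, inv, _ = MICE_TRANSFORMS.get(col, (None, None, col))
            x = completed_t[tname].astype(float)
            out[col] = inv(x) if inv is not None else x
            if col in ("tjc28", "sjc28"):
                out[col] = out[col].round().clip(0, 28)
            # observed cells are carried over verbatim; only imputed cells
            # take the (back-transformed) donor values
            observed_mask = visits[col].notna()
            out.loc[observed_mask, col] = visits.loc[observed_mask, col]
            if pd.api.types.is_integer_dtype(visits[col]):
                out[col] = out[col].round().astype(visits[col].dtype)
        datasets.append(out[visits.columns])
    return CompletedDatasets(m, datasets, seed, n_cycles, k_pmm)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    """Rubin-pooled coefficient(s) across m imputations."""

    estimate: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total_variance: np.ndarray
    se: np.ndarray
    df: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    m: int


def rubin_pool(
    estimates,
    variances,
    alpha: float = 0.05,
    dfcom: float | None = None,
) -> PooledEstimate:
    """Pool per-imputation estimates and squared SEs by Rubin's rules.

    total variance T = Ubar + (1 + 1/m) * B, with Ubar the mean within-
    imputation variance and B the between-imputation variance.  Reference
    distribution is t with the classic Rubin degrees of freedom, replaced
    by the Barnard-Rubin small-sample adjustment when the complete-data
    degrees of freedom ``dfcom`` are supplied.
    """
    q = np.atleast_2d(np.asarray(estimates, dtype=float))
    u = np.atleast_2d(np.asarray(variances, dtype=float))
    if q.shape != u.shape:
        raise ValueError("estimates and variances must be aligned")
    m = q.shape[0]
    if m < 2:
        raise ValueError("need m >= 2 imputations")

    qbar = q.mean(axis=0)
    ubar = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    t = ubar + (1.0 + 1.0 / m) * b

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b / ubar
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2
    df_old = np.where(b > 0, df_old, np.inf)
    if dfcom is not None:
        lam = (1.0 + 1.0 / m) * b / t
        df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
        with np.errstate(divide="ignore"):
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old

    se = np.sqrt(t)
    tcrit = np.where(np.isinf(df), stats.norm.ppf(1 - alpha / 2),
                     stats.t.ppf(1 - alpha / 2, np.where(np.isinf(df), 1, df)))
    return PooledEstimate(
        estimate=qbar, within=ubar, between=b, total_variance=t, se=se,
        df=df, ci_lower=qbar - tcrit * se, ci_upper=qbar + tcrit * se, m=m,
    )
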