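"""Synthetic early-RA cohorts with the structure the analysis assumes.

Development cohorts mimic three observational early-RA datasets: repeated
visits per patient, DAS28 components drawn on their analysis scales
(lognormal acute-phase reactants, rounded-sqrt-normal joint counts,
bounded-normal patient global), CRP left-censored at an assay limit,
component-wise missingness that is MAR given age and HAQ-DI, and a
joint-level ultrasound outcome generated as a linear function of
sqrt(SJC28) and ln(CRP+1) with a patient random intercept:

    GSPD = a + b_sjc*sqrt(SJC28) + b_crp*ln(CRP*+1)
             + b_tjc*sqrt(TJC28) + b_ghvas*GHVAS + u_i + e_ij

where CRP* is the value an analyst would use (the observed value, or
the single substitute when censored) so that downstream model fits can
recover the generative coefficients.  The realised GSPD is rounded and
decomposed into per-joint GS/PD grades whose recombined total equals it
exactly.

The validation cohort mimics a radiographic register: longitudinal
Larsen damage totals built from Poisson increments (hence monotone
non-decreasing within patient) and per-visit erosion indicators, both
driven positively by SJC28 and CRP and non-positively by TJC28, with a
patient random intercept.

All generation is deterministic given the truth record's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from . import ultrasound as us

__all__ = [
    "ComponentDistribution",
    "CohortSpec",
    "TruthRecord",
    "RadiographTruth",
    "GspdRangeError",
    "generate_development_cohorts",
    "generate_validation_cohort",
    "decompose_gspd",
    "default_development_specs",
    "default_validation_spec",
    "DEFAULT_TRUTH",
    "DEFAULT_RADIOGRAPH_TRUTH",
]

_Z75 = float(stats.norm.ppf(0.75))

VISIT_COLUMNS = [
    "patient_id", "cohort", "week", "age", "sex", "haq",
    "tjc28", "sjc28", "crp", "crp_censored", "esr", "ghvas", "gspd",
]
ULTRASOUND_COLUMNS = ["patient_id", "week", "joint", "gs", "pd"]
RADIOGRAPH_COLUMNS = [
    "patient_id", "years", "larsen", "erosion", "age", "disease_duration",
    "tjc28", "sjc28", "crp",
]


class GspdRangeError(ValueError):
    """A target GSPD total cannot be laid out on the joint grade grid."""


@dataclass(frozen=True)
class ComponentDistribution:
    """Marginal distribution of one component on its transformed scale.

    family: 'lognormal' (loc/scale of ln X), 'sqrtnormal' (loc/scale of
    sqrt X, squared, rounded and clipped to a count range) or 'normal'
    (clipped to bounds).
    """

    family: str
    loc: float
    scale: float
    lo: float = 0.0
    hi: float = np.inf

    @classmethod
    def from_quartiles(cls, family: str, median: float,
                       q1: float | None, q3: float,
                       lo: float = 0.0, hi: float = np.inf):
        """Calibrate location/scale to printed quartiles.

        When q1 is unavailable (reported only as below a censoring limit)
        the scale comes from the median-to-q3 spread alone.
        """
        if family == "lognormal":
            loc = np.log(median)
            t1, t3 = (None if q1 in (None, 0) else np.log(q1)), np.log(q3)
        elif family == "sqrtnormal":
            loc = np.sqrt(median)
            t1, t3 = (None if q1 is None else np.sqrt(q1)), np.sqrt(q3)
        elif family == "normal":
            loc, t1, t3 = median, q1, q3
        else:
            raise ValueError(f"unknown family {family!r}")
        scale = (t3 - loc) / _Z75 if t1 is None else (t3 - t1) / (2 * _Z75)
        return cls(family, float(loc), float(scale), lo, hi)

    def from_normal(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws to the component's raw scale."""
        t = self.loc + self.scale * z
        if self.family == "lognormal":
            return np.exp(t)
        if self.family == "sqrtnormal":
            x = np.round(np.maximum(t, 0.0) ** 2)
            return np.clip(x, self.lo, self.hi)
        return np.clip(t, self.lo, self.hi)


@dataclass
class CohortSpec:
    """Design of one synthetic cohort."""

    name: str
    n_patients: int
    visit_weeks: tuple[float, ...]
    gspd_method: str = "composite22"   # or 'sum10'
    gs_scale_max: int = 3
    component_distributions: dict[str, ComponentDistribution] = field(
        default_factory=dict)
    missingness_rates: dict[str, float] = field(default_factory=dict)
    crp_censor_threshold: float = 5.0
    outcome_scale: float = 1.0         # cohort-specific GSPD scaling
    corr_counts: float = 0.5           # TJC28-SJC28 latent correlation
    corr_reactants: float = 0.7        # CRP-ESR latent correlation
    corr_other: float = 0.3            # remaining pairwise latent correlation
    patient_share: float = 0.4         # share of component variance at patient level
    mean_age: float = 55.0
    sd_age: float = 14.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if len(self.visit_weeks) == 0:
            raise ValueError("visit schedule is empty")
        if not all(a < b for a, b in zip(self.visit_weeks, self.visit_weeks[1:])):
            raise ValueError("visit times must be strictly increasing")
        if self.gs_scale_max not in (3, 4):
            raise ValueError("gs_scale_max must be 3 or 4")
        if self.gspd_method not in ("composite22", "sum10"):
            raise ValueError("gspd_method must be 'composite22' or 'sum10'")
        for k, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {k} outside [0,1]")
        if self.crp_censor_threshold <= 0:
            raise ValueError("censor threshold must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Generative coefficients for the development GSPD model."""

    beta_sjc: float = 5.0
    beta_crp: float = 3.0
    beta_tjc: float = 0.0
    beta_ghvas: float = 0.0
    intercept: float = 6.0
    tau2: float = 4.0
    sigma2: float = 9.0
    crp_substitute: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2 <= 0:
            raise ValueError("need tau2 >= 0 and sigma2 > 0")
        if self.beta_crp == 0 or not np.isfinite(self.beta_sjc / self.beta_crp):
            raise ValueError("true SJC:CRP ratio must be finite")


@dataclass(frozen=True)
class RadiographTruth:
    """Generative effects for the radiographic validation cohort."""

    gamma_sjc: float = 0.20
    gamma_crp: float = 0.30
    gamma_tjc: float = -0.10
    baseline_larsen: float = 0.45      # damage increments per year at eta=0
    erosion_intercept: float = -1.0    # log-odds
    subject_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gamma_sjc > 0 and self.gamma_crp > 0):
            raise ValueError("SJC and CRP effects must be positive")
        if self.gamma_tjc > 0:
            raise ValueError("TJC effect must be non-positive")
        if self.subject_sd < 0 or self.baseline_larsen < 0:
            raise ValueError("subject_sd and baseline_larsen must be >= 0")


_COMPONENT_ORDER = ("tjc28", "sjc28", "crp", "esr", "ghvas")


def _latent_correlation(spec: CohortSpec) -> np.ndarray:
    p = len(_COMPONENT_ORDER)
    r = np.full((p, p), spec.corr_other)
    np.fill_diagonal(r, 1.0)
    r[0, 1] = r[1, 0] = spec.corr_counts      # tjc28-sjc28
    r[2, 3] = r[3, 2] = spec.corr_reactants   # crp-esr
    return np.linalg.cholesky(r)


def _draw_components(spec: CohortSpec, rng: np.random.Generator):
    """Correlated component draws: a patient-level latent severity plus
    visit-level noise, pushed through each component's marginal."""
    n, v = spec.n_patients, len(spec.visit_weeks)
    chol = _latent_correlation(spec)
    a = rng.standard_normal((n, 1, len(_COMPONENT_ORDER))) @ chol.T
    e = rng.standard_normal((n, v, len(_COMPONENT_ORDER))) @ chol.T
    z = np.sqrt(spec.patient_share) * a + np.sqrt(1 - spec.patient_share) * e
    comp = {}
    for j, name in enumerate(_COMPONENT_ORDER):
        comp[name] = spec.component_distributions[name].from_normal(z[:, :, j])
    return comp


def _mar_mask(rate: float, age: np.ndarray, haq: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """MAR missingness: probability increases with age and HAQ-DI, with
    the intercept solved so the realised expected rate equals `rate`."""
    if rate <= 0:
        return np.zeros(age.shape, dtype=bool)
    zage = (age - age.mean()) / max(age.std(), 1e-9)
    zhaq = (haq - haq.mean()) / max(haq.std(), 1e-9)
    lin = 0.5 * zage + 0.5 * zhaq

    def mean_rate(a):
        return expit(a + lin).mean() - rate

    a = optimize.brentq(mean_rate, -20.0, 20.0)
    return rng.random(age.shape) < expit(a + lin)


def decompose_gspd(total: int, method: str, gs_scale_max: int,
                   rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Spread an integer GSPD total over the joint grid.

    Returns (joint, gs, pd) rows whose recombined total under the given
    method equals ``total`` exactly.  Raises :class:`GspdRangeError` when
    the total is negative or exceeds the grid capacity; totals are never
    silently truncated.
    """
    joints = us.COMPOSITE22_JOINTS if method == "composite22" else us.SUM10_JOINTS
    cap = gs_scale_max if method == "composite22" else 2 * gs_scale_max
    total = int(total)
    if total < 0 or total > cap * len(joints):
        raise GspdRangeError(
            f"GSPD total {total} not representable on {len(joints)} joints "
            f"with per-joint capacity {cap}")
    base, rem = divmod(total, len(joints))
    per_joint = np.full(len(joints), base, dtype=int)
    bump = rng.permutation(len(joints))[:rem]
    per_joint[bump] += 1
    rows = []
    for joint, load in zip(joints, per_joint):
        if method == "composite22":
            gs = load
            pd_grade = int(rng.integers(0, load + 1)) if load > 0 else 0
        else:
            gs = (load + 1) // 2
            pd_grade = load // 2
        rows.append((joint, int(gs), int(pd_grade)))
    return rows


def _realise_gspd(spec: CohortSpec, truth: TruthRecord, comp: dict,
                  crp_censored: np.ndarray, rng: np.random.Generator):
    """Linear-model GSPD, rounded onto the joint grid.

    Out-of-grid draws (possible in the Gaussian tails) are handled by
    re-drawing that visit's residual noise rather than clamping, so the
    realised totals stay on the grid without a truncation artefact at
    the boundaries; the number of re-draws is returned for diagnostics.
    """
    n, v = spec.n_patients, len(spec.visit_weeks)
    crp_analysis = np.where(crp_censored, truth.crp_substitute, comp["crp"])
    eta = (truth.intercept
           + truth.beta_sjc * np.sqrt(comp["sjc28"])
           + truth.beta_crp * np.log(crp_analysis + 1.0)
           + truth.beta_tjc * np.sqrt(comp["tjc28"])
           + truth.beta_ghvas * comp["ghvas"])
    u = rng.normal(0.0, np.sqrt(truth.tau2), size=(n, 1))
    eps = rng.normal(0.0, np.sqrt(truth.sigma2), size=(n, v))
    latent = spec.outcome_scale * (eta + u + eps)
    cap = us.gspd_max(spec.gspd_method, spec.gs_scale_max)
    gspd = np.round(latent).astype(int)
    n_redraw = 0
    bad = (gspd < 0) | (gspd > cap)
    for _ in range(1000):
        if not bad.any():
            break
        n_redraw += int(bad.sum())
        eps_new = rng.normal(0.0, np.sqrt(truth.sigma2), size=int(bad.sum()))
        latent[bad] = spec.outcome_scale * ((eta + u)[bad] + eps_new)
        gspd = np.round(latent).astype(int)
        bad = (gspd < 0) | (gspd > cap)
    else:
        raise GspdRangeError(
            "could not realise a GSPD total on the joint grid; the truth "
            "parameters place too much mass outside it")
    return gspd, n_redraw


def generate_development_cohorts(
    specs: list[CohortSpec], truth: TruthRecord,
    include_ultrasound: bool = True,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Generate per-visit clinical and joint-level ultrasound tables.

    Returns ``{cohort: {"visits": ..., "ultrasound": ...,
    "n_noise_redraws": int}}``; identical inputs (including
    ``truth.seed``) give byte-identical tables.  Simulation studies that
    only need the visit table can set ``include_ultrasound=False`` to
    skip the joint-level decomposition (the visit table is unchanged).
    """
    out = {}
    for idx, spec in enumerate(specs):
        spec.validate()
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, idx]))
        n, v = spec.n_patients, len(spec.visit_weeks)
        comp = _draw_components(spec, rng)
        age0 = np.clip(rng.normal(spec.mean_age, spec.sd_age, n), 18, 90)
        sex = (rng.random(n) < 0.70).astype(int)  # 1 = female
        haq_pat = np.clip(rng.normal(1.0, 0.7, n), 0, 3)
        weeks = np.asarray(spec.visit_weeks, dtype=float)
        age = age0[:, None] + weeks[None, :] / 52.0
        haq = np.clip(haq_pat[:, None] + rng.normal(0, 0.2, (n, v)), 0, 3)
        haq = np.round(haq / 0.125) * 0.125

        crp_censored = comp["crp"] < spec.crp_censor_threshold
        gspd, n_redraw = _realise_gspd(spec, truth, comp, crp_censored, rng)

        pids = np.array([f"{spec.name}-{i:04d}" for i in range(n)])
        visits = pd.DataFrame({
            "patient_id": np.repeat(pids, v),
            "cohort": spec.name,
            "week": np.tile(weeks, n),
            "age": age.ravel().round(2),
            "sex": np.repeat(sex, v),
            "haq": haq.ravel(),
            "tjc28": comp["tjc28"].ravel(),
            "sjc28": comp["sjc28"].ravel(),
            "crp": np.where(crp_censored, spec.crp_censor_threshold,
                            comp["crp"]).ravel().round(2),
            "crp_censored": crp_censored.ravel(),
            "esr": comp["esr"].ravel().round(1),
            "ghvas": comp["ghvas"].ravel().round(0),
            "gspd": gspd.ravel(),
        })[VISIT_COLUMNS]

        # Missingness after outcome generation, MAR in age and HAQ-DI.
        for col in ("tjc28", "sjc28", "crp", "esr", "ghvas"):
            rate = spec.missingness_rates.get(col, 0.0)
            mask = _mar_mask(rate, visits["age"].to_numpy(),
                             visits["haq"].to_numpy(), rng)
            visits.loc[mask, col] = np.nan
            if col == "crp":
                visits.loc[mask, "crp_censored"] = False

        if include_ultrasound:
            scan_rows = []
            for pid, week, total in zip(visits["patient_id"], visits["week"],
                                        gspd.ravel()):
                for joint, gs, pd_grade in decompose_gspd(
                        int(total), spec.gspd_method, spec.gs_scale_max, rng):
                    scan_rows.append((pid, week, joint, gs, pd_grade))
            ultra = pd.DataFrame(scan_rows, columns=ULTRASOUND_COLUMNS)
        else:
            ultra = pd.DataFrame(columns=ULTRASOUND_COLUMNS)
        out[spec.name] = {"visits": visits, "ultrasound": ultra,
                          "n_noise_redraws": n_redraw}
    return out


def generate_validation_cohort(
    spec: CohortSpec, truth: RadiographTruth
) -> pd.DataFrame:
    """Longitudinal radiographic table (visit times in years).

    Larsen totals are cumulative sums of Poisson increments whose log
    rate is the linear predictor, hence non-negative, right-skewed and
    monotone within patient; erosion is a per-visit Bernoulli with the
    same linear predictor and a shared patient intercept.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 99]))
    n = spec.n_patients
    years = np.asarray(spec.visit_weeks, dtype=float)
    v = years.size
    comp = _draw_components_validation(spec, rng)
    age0 = np.clip(rng.normal(spec.mean_age, spec.sd_age, n), 18, 90)
    dur0 = np.exp(rng.normal(np.log(8.0 / 12.0), 0.6, n))  # years at entry
    u = rng.normal(0.0, truth.subject_sd, size=(n, 1))

    eta = (truth.gamma_sjc * np.sqrt(comp["sjc28"])
           + truth.gamma_crp * np.log(comp["crp"] + 1.0)
           + truth.gamma_tjc * np.sqrt(comp["tjc28"]))

    exposure = np.concatenate([[1.0 + years[0]], np.diff(years)])
    rate = truth.baseline_larsen * np.exp(eta + u) * exposure[None, :]
    increments = rng.poisson(rate)
    larsen = np.cumsum(increments, axis=1)

    p_ero = expit(truth.erosion_intercept + eta + u)
    erosion = (rng.random((n, v)) < p_ero).astype(int)

    pids = np.array([f"{spec.name}-{i:04d}" for i in range(n)])
    return pd.DataFrame({
        "patient_id": np.repeat(pids, v),
        "years": np.tile(years, n),
        "larsen": larsen.ravel(),
        "erosion": erosion.ravel(),
        "age": (age0[:, None] + years[None, :]).ravel().round(2),
        "disease_duration": (dur0[:, None] + years[None, :]).ravel().round(2),
        "tjc28": comp["tjc28"].ravel(),
        "sjc28": comp["sjc28"].ravel(),
        "crp": comp["crp"].ravel().round(2),
    })[RADIOGRAPH_COLUMNS]


def _draw_components_validation(spec: CohortSpec, rng: np.random.Generator):
    """tjc/sjc/crp draws for the validation register (no ESR/GHVAS)."""
    names = ("tjc28", "sjc28", "crp")
    r = np.full((3, 3), spec.corr_other)
    np.fill_diagonal(r, 1.0)
    r[0, 1] = r[1, 0] = spec.corr_counts
    chol = np.linalg.cholesky(r)
    n, v = spec.n_patients, len(spec.visit_weeks)
    a = rng.standard_normal((n, 1, 3)) @ chol.T
    e = rng.standard_normal((n, v, 3)) @ chol.T
    z = np.sqrt(spec.patient_share) * a + np.sqrt(1 - spec.patient_share) * e
    return {name: spec.component_distributions[name].from_normal(z[:, :, j])
            for j, name in enumerate(names)}


# ---------------------------------------------------------------------------
# Default study designs
# ---------------------------------------------------------------------------

def _dists(q: dict) -> dict[str, ComponentDistribution]:
    d = {
        "tjc28": ComponentDistribution.from_quartiles(
            "sqrtnormal", *q["tjc28"], lo=0, hi=28),
        "sjc28": ComponentDistribution.from_quartiles(
            "sqrtnormal", *q["sjc28"], lo=0, hi=28),
        "crp": ComponentDistribution.from_quartiles("lognormal", *q["crp"]),
    }
    if "esr" in q:
        d["esr"] = ComponentDistribution.from_quartiles("lognormal", *q["esr"])
        d["ghvas"] = ComponentDistribution.from_quartiles(
            "normal", *q["ghvas"], lo=0, hi=100)
    return d


def default_development_specs(scale: float = 1.0) -> list[CohortSpec]:
    """The three development cohorts at the study's sizes and schedules.

    ``scale`` < 1 shrinks patient counts proportionally (minimum 25) for
    quicker simulation studies without changing any distribution.
    """
    from .published import COHORT_QUARTILES, OBSERVATION_COUNTS, MISSING_COUNTS

    def rates(cohort):
        n = OBSERVATION_COUNTS[cohort]
        return {k: v / n for k, v in MISSING_COUNTS[cohort].items()}

    def size(n):
        return max(25, int(round(n * scale)))

    return [
        CohortSpec(
            name="IACON", n_patients=size(434), visit_weeks=(0, 26, 52, 104),
            gspd_method="composite22", gs_scale_max=3,
            component_distributions=_dists(COHORT_QUARTILES["IACON"]),
            missingness_rates=rates("IACON"), mean_age=56, sd_age=15,
        ),
        CohortSpec(
            name="IDEA", n_patients=size(59), visit_weeks=(0, 52, 78),
            gspd_method="composite22", gs_scale_max=3,
            component_distributions=_dists(COHORT_QUARTILES["IDEA"]),
            missingness_rates=rates("IDEA"), mean_age=51, sd_age=12,
        ),
        CohortSpec(
            name="PEAC", n_patients=size(117), visit_weeks=(0, 26),
            gspd_method="sum10", gs_scale_max=4,
            component_distributions=_dists(COHORT_QUARTILES["PEAC"]),
            missingness_rates=rates("PEAC"), outcome_scale=0.4,
            mean_age=51, sd_age=16,
        ),
    ]


def default_validation_spec(scale: float = 1.0) -> CohortSpec:
    """The radiographic validation register design (times in years)."""
    from .published import COHORT_QUARTILES

    return CohortSpec(
        name="NOAR", n_patients=max(25, int(round(717 * scale))),
        visit_weeks=(0, 3, 5, 10),
        component_distributions=_dists(COHORT_QUARTILES["NOAR"]),
        crp_censor_threshold=5.0,  # unused: register CRP is high-sensitivity
        mean_age=58, sd_age=14,
    )


DEFAULT_TRUTH = TruthRecord()
DEFAULT_RADIOGRAPH_TRUTH = RadiographTruth()
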