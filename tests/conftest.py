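import numpy as np
import pandas as pd
import pytest

from das2c import cohorts, mixedlm, scores


def analysis_ready(visits: pd.DataFrame, substitute: float = 2.0,
                   dropna: bool = True) -> pd.DataFrame:
    """Resolve censored CRP, add transformed columns, drop incomplete rows."""
    d = visits.copy()
    if dropna:
        d = d.dropna(subset=["tjc28", "sjc28", "crp", "esr", "ghvas"])
    d["crp"] = scores.resolve_censored_crp(
        d["crp"], d["crp_censored"].astype(bool), substitute)
    return mixedlm.add_transformed_components(d)


def iacon_like_spec(n_patients: int, visit_weeks=(0, 26, 52, 104),
                    missingness: dict | None = None, **kwargs) -> cohorts.CohortSpec:
    base = cohorts.default_development_specs(1.0)[0]
    return cohorts.CohortSpec(
        name="SIM", n_patients=n_patients, visit_weeks=visit_weeks,
        component_distributions=base.component_distributions,
        missingness_rates=missingness or {}, **kwargs)


@pytest.fixture(scope="session")
def small_dev_visits() -> pd.DataFrame:
    """One IACON-style cohort, 120 patients, default truth, with
    missingness and censoring as in the full design."""
    spec = cohorts.default_development_specs(1.0)[0]
    spec.n_patients = 120
    dev = cohorts.generate_development_cohorts(
        [spec], cohorts.TruthRecord(seed=42), include_ultrasound=False)
    return dev["IACON"]["visits"]


@pytest.fixture(scope="session")
def radiograph_visits() -> pd.DataFrame:
    """Validation register, ~140 patients, default radiographic truth."""
    spec = cohorts.default_validation_spec(0.2)
    return cohorts.generate_validation_cohort(
        spec, cohorts.RadiographTruth(seed=7))
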