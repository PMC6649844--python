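"""Column schemas for every CSV the pipeline reads or writes.

All files are UTF-8 CSV with a header row; floating-point values are
written at 6 significant digits.
"""

SCHEMAS = {
    "visits": {
        "patient_id": "cohort-scoped patient identifier",
        "cohort": "cohort label (IACON / IDEA / PEAC)",
        "week": "visit time in weeks from baseline",
        "age": "age in years at the visit",
        "sex": "1 = female, 0 = male",
        "haq": "HAQ-DI score, 0-3 in steps of 0.125",
        "tjc28": "28-joint tender joint count (blank if missing)",
        "sjc28": "28-joint swollen joint count (blank if missing)",
        "crp": "C-reactive protein, mg/L; censored rows carry the threshold",
        "crp_censored": "True if CRP was below the reporting limit",
        "esr": "erythrocyte sedimentation rate, mm/h",
        "ghvas": "patient general health VAS, mm (0-100)",
        "gspd": "scalar ultrasound synovitis total for the visit",
    },
    "ultrasound": {
        "patient_id": "patient identifier",
        "week": "visit time in weeks",
        "joint": "joint label, side-prefixed (r_/l_)",
        "gs": "grey-scale synovitis grade",
        "pd": "power Doppler grade",
    },
    "gspd": {
        "patient_id": "patient identifier",
        "week": "visit time in weeks",
        "gspd": "recombined GSPD total",
        "method": "composite22 or sum10",
    },
    "radiographs": {
        "patient_id": "patient identifier",
        "years": "time in years from register entry",
        "larsen": "Larsen damage total (non-negative integer)",
        "erosion": "1 if erosions present on the visit's films",
        "age": "age in years",
        "disease_duration": "symptom duration in years",
        "tjc28": "28-joint tender joint count",
        "sjc28": "28-joint swollen joint count",
        "crp": "high-sensitivity CRP, mg/L (no censoring)",
    },
    "cv_report": {
        "cohort": "development cohort",
        "model": "component set or score column used as predictor",
        "r2": "squared Pearson correlation, observed vs predicted, "
              "concatenated test folds (averaged over imputations)",
        "test_loglik": "summed per-patient test log-likelihood (natural "
                       "log units, averaged over imputations)",
        "delta_from_best": "test_loglik minus the cohort's best model",
    },
    "validation_report": {
        "outcome": "larsen or erosion",
        "model": "univariable / multivariable / score label",
        "variable": "predictor the row describes",
        "coef": "estimated coefficient (log scale for larsen, log-odds "
                "for erosion)",
        "ci_lower": "lower 95% confidence limit",
        "ci_upper": "upper 95% confidence limit",
        "p": "two-sided Wald p-value",
        "aic": "Akaike information criterion (larsen models)",
        "bic": "Bayesian information criterion (larsen models)",
        "qic": "quasi-likelihood information criterion (erosion models)",
    },
}
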