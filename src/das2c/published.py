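"""Published constants from the original 2C-DAS28 derivation study.

The study fitted two-component random-intercept models of GSPD on
sqrt(SJC28) and one acute-phase term in three early-RA development
cohorts (IACON, IDEA, PEAC).  The reported coefficients and the
data-availability counts below are the inputs from which the final
score weights (0.6 for ln(CRP+1), 0.32 for ln(ESR)) are re-derivable;
:func:`published_cohort_ratios` feeds them into
:mod:`das2c.derivation`.
"""

from __future__ import annotations

from .derivation import CohortRatio, ratio_from_coefficients

__all__ = [
    "TWO_COMPONENT_COEFFICIENTS",
    "OBSERVATION_COUNTS",
    "MISSING_COUNTS",
    "CENSORED_CRP_COUNTS",
    "COHORT_QUARTILES",
    "acute_phase_weights",
    "published_cohort_ratios",
]

#: Two-component mixed-model coefficients (GSPD units per transformed unit).
TWO_COMPONENT_COEFFICIENTS = {
    "CRP": {
        "IACON": {"sqrt_sjc28": 30.61, "ln_crp1": 15.45},
        "IDEA": {"sqrt_sjc28": 31.40, "ln_crp1": 40.31},
        "PEAC": {"sqrt_sjc28": 4.69, "ln_crp1": 4.06},
    },
    "ESR": {
        "IACON": {"sqrt_sjc28": 32.30, "ln_esr": 11.74},
        "IDEA": {"sqrt_sjc28": 47.70, "ln_esr": 12.68},
        "PEAC": {"sqrt_sjc28": 5.59, "ln_esr": 1.43},
    },
}

#: Longitudinal observations per development cohort.
OBSERVATION_COUNTS = {"IACON": 889, "IDEA": 163, "PEAC": 183}

#: Observations with a missing component, per cohort.
MISSING_COUNTS = {
    "IACON": {"tjc28": 3, "sjc28": 3, "ghvas": 59, "esr": 159, "crp": 53},
    "IDEA": {"tjc28": 0, "sjc28": 0, "ghvas": 0, "esr": 10, "crp": 9},
    "PEAC": {"tjc28": 22, "sjc28": 2, "ghvas": 2, "esr": 3, "crp": 5},
}

#: Observations with CRP reported below the 5 mg/L limit.
CENSORED_CRP_COUNTS = {"IACON": 431, "IDEA": 72, "PEAC": 51}

#: Baseline median (q1, q3) summaries used to calibrate the synthetic
#: cohorts; a None quartile was reported only as below the CRP limit.
COHORT_QUARTILES = {
    "IACON": {
        "age": (56, None, None), "tjc28": (4, 1, 10), "sjc28": (2, 0, 5),
        "crp": (6, None, 18), "esr": (23, 10, 38), "ghvas": (35, 15, 57),
    },
    "IDEA": {
        "age": (51, None, None), "tjc28": (15, 8, 22), "sjc28": (8, 3, 11),
        "crp": (21, 10, 52), "esr": (37, 19, 65), "ghvas": (53, 39, 72),
    },
    "PEAC": {
        "age": (51, None, None), "tjc28": (10, 5, 15), "sjc28": (5, 3, 8),
        "crp": (7, None, 18), "esr": (30, 15, 49), "ghvas": (72, 51, 84),
    },
    "NOAR": {
        "age": (58, None, None), "tjc28": (5, 1, 11), "sjc28": (5, 2, 9),
        "crp": (11, 3, 24),
    },
}


def acute_phase_weights(acute_phase: str) -> dict[str, int]:
    """Observations with a non-missing acute-phase measurement per cohort."""
    key = acute_phase.lower()
    return {c: OBSERVATION_COUNTS[c] - MISSING_COUNTS[c][key]
            for c in OBSERVATION_COUNTS}


def published_cohort_ratios(acute_phase: str) -> list[CohortRatio]:
    """Per-cohort SJC:acute-phase coefficient ratios from the published
    two-component models, weighted by non-missing acute-phase counts."""
    coefs = TWO_COMPONENT_COEFFICIENTS[acute_phase]
    weights = acute_phase_weights(acute_phase)
    ap_term = "ln_crp1" if acute_phase == "CRP" else "ln_esr"
    return [
        ratio_from_coefficients(c, coefs[c]["sqrt_sjc28"], coefs[c][ap_term],
                                weights[c])
        for c in ("IACON", "IDEA", "PEAC")
    ]
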