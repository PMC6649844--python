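"""Re-weighted two-component score derivation.

Cohorts scan different joint sets and combine GS/PD differently, so their
GSPD outcomes sit on different scales and mixed-model coefficients are
not directly comparable.  The scale cancels in the ratio of the
sqrt(SJC28) coefficient to the acute-phase coefficient within each
cohort; the per-cohort ratios are averaged with weights equal to the
number of observations with a non-missing acute-phase measurement, and
the final score fixes the sqrt(SJC28) weight at 1 and gives the
acute-phase term the reciprocal of the combined ratio:

    2C score = sqrt(SJC28) + (1 / combined_ratio) * ln(AP term)

with the CRP weight rounded to 1 decimal and the ESR weight to 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .mixedlm import LmmFit
from . import scores

__all__ = [
    "CohortRatio",
    "ScoreEquation",
    "coefficient_ratio",
    "combine_ratios",
    "emit_equation",
    "derive_equation",
]

_AP_TERMS = {"CRP": "ln_crp1", "ESR": "ln_esr"}
_AP_RENDER = {"CRP": "ln(CRP+1)", "ESR": "ln(ESR)"}
_DEFAULT_DECIMALS = {"CRP": 1, "ESR": 2}


@dataclass(frozen=True)
class CohortRatio:
    """SJC28-to-acute-phase coefficient ratio for one cohort."""

    cohort: str
    ratio: float
    n_weight: int

    def __post_init__(self) -> None:
        if self.n_weight <= 0:
            raise ValueError("n_weight must be positive")
        if not np.isfinite(self.ratio):
            raise ValueError("ratio must be finite")


def coefficient_ratio(fit: LmmFit, cohort: str, n_weight: int) -> CohortRatio:
    """Ratio of the sqrt(SJC28) coefficient to the acute-phase coefficient
    from a fitted two-component model."""
    terms = set(fit.spec.fixed)
    ap = terms & set(_AP_TERMS.values())
    if terms - {"sqrt_sjc28"} != ap or "sqrt_sjc28" not in terms or len(ap) != 1:
        raise ValueError(
            "expected a two-component fit with sqrt_sjc28 and one acute-phase term")
    beta_sjc = float(fit.beta["sqrt_sjc28"])
    beta_ap = float(fit.beta[ap.pop()])
    if beta_ap <= 0:
        raise ValueError(
            "acute-phase coefficient is not positive; the ratio is undefined "
            "for score construction")
    return CohortRatio(cohort, beta_sjc / beta_ap, n_weight)


def ratio_from_coefficients(cohort: str, beta_sjc: float, beta_ap: float,
                            n_weight: int) -> CohortRatio:
    """Build a :class:`CohortRatio` directly from published coefficients."""
    if beta_ap <= 0:
        raise ValueError("acute-phase coefficient must be positive")
    return CohortRatio(cohort, beta_sjc / beta_ap, n_weight)


def combine_ratios(ratios: list[CohortRatio]) -> float:
    """Observation-weighted mean of per-cohort coefficient ratios."""
    if not ratios:
        raise ValueError("no ratios to combine")
    w = np.array([r.n_weight for r in ratios], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight is zero")
    vals = np.array([r.ratio for r in ratios], dtype=float)
    return float(np.dot(vals, w) / w.sum())


@dataclass
class ScoreEquation:
    """Weights of a derived two-component score, with provenance."""

    acute_phase: str
    weight_ap: float
    combined_ratio: float
    weight_sjc: float = 1.0
    decimals: int = 1
    provenance: list[CohortRatio] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.acute_phase not in _AP_TERMS:
            raise ValueError("acute_phase must be 'CRP' or 'ESR'")
        if self.weight_ap <= 0:
            raise ValueError("acute-phase weight must be positive")

    @property
    def text(self) -> str:
        return (f"2C-DAS28{self.acute_phase} = sqrt(SJC28) + "
                f"({self.weight_ap} x {_AP_RENDER[self.acute_phase]})")

    def score(self, sjc28, acute_phase_value):
        """Evaluate the derived score (CRP already censoring-resolved)."""
        if self.acute_phase == "CRP":
            return scores.das28_2c_crp(sjc28, acute_phase_value, self.weight_ap)
        return scores.das28_2c_esr(sjc28, acute_phase_value, self.weight_ap)

    def to_json(self, **meta) -> str:
        payload = asdict(self)
        payload.update(meta)
        return json.dumps(payload, indent=2, sort_keys=True)


def emit_equation(combined_ratio: float, acute_phase: str,
                  decimals: int | None = None,
                  provenance: list[CohortRatio] | None = None) -> ScoreEquation:
    """Final score equation from a combined coefficient ratio.

    The acute-phase weight is the reciprocal of the combined ratio,
    rounded (1 decimal for CRP, 2 for ESR, matching the precision the
    score is meant to be used at)."""
    if combined_ratio <= 0:
        raise ValueError("combined ratio must be positive")
    if decimals is None:
        decimals = _DEFAULT_DECIMALS[acute_phase]
    weight = round(1.0 / combined_ratio, decimals)
    return ScoreEquation(
        acute_phase=acute_phase,
        weight_ap=weight,
        combined_ratio=combined_ratio,
        decimals=decimals,
        provenance=list(provenance or []),
    )


def derive_equation(ratios: list[CohortRatio], acute_phase: str,
                    decimals: int | None = None) -> ScoreEquation:
    """coefficient ratios -> combined ratio -> emitted equation."""
    combined = combine_ratios(ratios)
    return emit_equation(combined, acute_phase, decimals, provenance=ratios)
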