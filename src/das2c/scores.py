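"""Composite disease-activity scores for rheumatoid arthritis.

All scores are computed from the DAS28 core components: 28-joint tender
and swollen counts (TJC28, SJC28), an acute-phase reactant (CRP in mg/L
or ESR in mm/h) and the patient's general-health visual analogue scale
(GHVAS, 0-100 mm).

Conventional definitions (CRP in mg/L, GHVAS in mm)::

    4C-DAS28CRP = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28)
                  + 0.36*ln(CRP+1) + 0.014*GHVAS + 0.96
    4C-DAS28ESR = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28)
                  + 0.70*ln(ESR)   + 0.014*GHVAS
    3C-DAS28CRP = [0.56*sqrt(TJC28) + 0.28*sqrt(SJC28)
                  + 0.36*ln(CRP+1)] * 1.10 + 1.15

Two-component scores re-weighted against ultrasound synovitis::

    2C-DAS28CRP = sqrt(SJC28) + 0.6  * ln(CRP+1)
    2C-DAS28ESR = sqrt(SJC28) + 0.32 * ln(ESR)

The 2C scores are deliberately not rescaled onto the conventional DAS28
range, so conventional remission/activity cut-offs do not apply to them.

Partial SDAI/CDAI (physician global VAS unavailable) use CRP in mg/dL
and GHVAS in cm; inputs here are mg/L and mm and are converted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClinicalComponents",
    "resolve_censored_crp",
    "das28_4c_crp",
    "das28_4c_esr",
    "das28_3c_crp",
    "das28_2c_crp",
    "das28_2c_esr",
    "partial_sdai",
    "partial_cdai",
    "SCORE_FUNCTIONS",
    "add_score_columns",
]

#: Default single substitute (mg/L) for CRP reported below the assay limit.
DEFAULT_CRP_SUBSTITUTE = 2.0


def _ln_esr(esr):
    """ln(ESR) with the standard DAS28 convention ESR=0 -> 1 mm/h."""
    esr = np.asarray(esr, dtype=float)
    if np.any(esr < 0):
        raise ValueError("ESR must be non-negative")
    return np.log(np.maximum(esr, 1.0))


def _check(name, x, lo, hi):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (x < lo) | (x > hi)
    if np.any(bad & ~np.isnan(x)):
        raise ValueError(f"{name} outside [{lo}, {hi}]")
    return x


def resolve_censored_crp(crp, censored, substitute: float = DEFAULT_CRP_SUBSTITUTE):
    """Replace left-censored CRP observations by a single substitute value.

    Parameters
    ----------
    crp
        CRP in mg/L; censored entries conventionally carry the assay
        threshold rather than a measurement.
    censored
        Boolean flag(s), True where the value is below the reporting limit.
    substitute
        Value (mg/L) standing in for censored observations; default 2.
    """
    if substitute <= 0:
        raise ValueError("substitute must be positive")
    crp = np.asarray(crp, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    out = np.where(censored, float(substitute), crp)
    return out if out.ndim else float(out)


def das28_4c_crp(tjc28, sjc28, crp, ghvas):
    """Four-component DAS28 with CRP (mg/L) and GHVAS (mm)."""
    tjc28 = _check("TJC28", tjc28, 0, 28)
    sjc28 = _check("SJC28", sjc28, 0, 28)
    crp = _check("CRP", crp, 0, np.inf)
    ghvas = _check("GHVAS", ghvas, 0, 100)
    return (0.56 * np.sqrt(tjc28) + 0.28 * np.sqrt(sjc28)
            + 0.36 * np.log(crp + 1.0) + 0.014 * ghvas + 0.96)


def das28_4c_esr(tjc28, sjc28, esr, ghvas):
    """Four-component DAS28 with ESR (mm/h) and GHVAS (mm)."""
    tjc28 = _check("TJC28", tjc28, 0, 28)
    sjc28 = _check("SJC28", sjc28, 0, 28)
    ghvas = _check("GHVAS", ghvas, 0, 100)
    return (0.56 * np.sqrt(tjc28) + 0.28 * np.sqrt(sjc28)
            + 0.70 * _ln_esr(esr) + 0.014 * ghvas)


def das28_3c_crp(tjc28, sjc28, crp):
    """Three-component DAS28-CRP (no patient global)."""
    tjc28 = _check("TJC28", tjc28, 0, 28)
    sjc28 = _check("SJC28", sjc28, 0, 28)
    crp = _check("CRP", crp, 0, np.inf)
    inner = (0.56 * np.sqrt(tjc28) + 0.28 * np.sqrt(sjc28)
             + 0.36 * np.log(crp + 1.0))
    return inner * 1.10 + 1.15


def das28_2c_crp(sjc28, crp, crp_weight: float = 0.6):
    """Two-component score: sqrt(SJC28) + crp_weight * ln(CRP+1).

    ``crp_weight`` defaults to the published 0.6 but may be replaced by a
    freshly derived weight (see :mod:`das2c.derivation`).
    """
    sjc28 = _check("SJC28", sjc28, 0, 28)
    crp = _check("CRP", crp, 0, np.inf)
    return np.sqrt(sjc28) + crp_weight * np.log(crp + 1.0)


def das28_2c_esr(sjc28, esr, esr_weight: float = 0.32):
    """Two-component score: sqrt(SJC28) + esr_weight * ln(ESR)."""
    sjc28 = _check("SJC28", sjc28, 0, 28)
    return np.sqrt(sjc28) + esr_weight * _ln_esr(esr)


def partial_sdai(tjc28, sjc28, crp, ghvas):
    """Partial SDAI = TJC28 + SJC28 + CRP(mg/dL) + GHVAS(cm).

    Inputs are mg/L and mm; both are divided by 10 before summing.
    """
    tjc28 = _check("TJC28", tjc28, 0, 28)
    sjc28 = _check("SJC28", sjc28, 0, 28)
    crp = _check("CRP", crp, 0, np.inf)
    ghvas = _check("GHVAS", ghvas, 0, 100)
    return tjc28 + sjc28 + crp / 10.0 + ghvas / 10.0


def partial_cdai(tjc28, sjc28, ghvas):
    """Partial CDAI = TJC28 + SJC28 + GHVAS(cm)."""
    tjc28 = _check("TJC28", tjc28, 0, 28)
    sjc28 = _check("SJC28", sjc28, 0, 28)
    ghvas = _check("GHVAS", ghvas, 0, 100)
    return tjc28 + sjc28 + ghvas / 10.0


@dataclass
class ClinicalComponents:
    """One visit's DAS28 components with censoring metadata."""

    tjc28: float
    sjc28: float
    crp: float | None = None
    crp_censored: bool = False
    esr: float | None = None
    ghvas: float | None = None
    crp_threshold: float = 5.0

    def resolved_crp(self, substitute: float = DEFAULT_CRP_SUBSTITUTE) -> float:
        if self.crp is None:
            raise ValueError("CRP not recorded")
        return float(resolve_censored_crp(self.crp, self.crp_censored, substitute))

    def das28_4c_crp(self, substitute: float = DEFAULT_CRP_SUBSTITUTE) -> float:
        return float(das28_4c_crp(self.tjc28, self.sjc28,
                                  self.resolved_crp(substitute), self._ghvas()))

    def das28_4c_esr(self) -> float:
        return float(das28_4c_esr(self.tjc28, self.sjc28, self._esr(), self._ghvas()))

    def das28_3c_crp(self, substitute: float = DEFAULT_CRP_SUBSTITUTE) -> float:
        return float(das28_3c_crp(self.tjc28, self.sjc28, self.resolved_crp(substitute)))

    def das28_2c_crp(self, substitute: float = DEFAULT_CRP_SUBSTITUTE,
                     crp_weight: float = 0.6) -> float:
        return float(das28_2c_crp(self.sjc28, self.resolved_crp(substitute), crp_weight))

    def das28_2c_esr(self, esr_weight: float = 0.32) -> float:
        return float(das28_2c_esr(self.sjc28, self._esr(), esr_weight))

    def _esr(self) -> float:
        if self.esr is None:
            raise ValueError("ESR not recorded")
        return self.esr

    def _ghvas(self) -> float:
        if self.ghvas is None:
            raise ValueError("GHVAS not recorded")
        return self.ghvas


def _score_2c_crp(df, substitute):
    crp = resolve_censored_crp(df["crp"], df.get("crp_censored", False), substitute)
    return das28_2c_crp(df["sjc28"], crp)


def _score_3c_crp(df, substitute):
    crp = resolve_censored_crp(df["crp"], df.get("crp_censored", False), substitute)
    return das28_3c_crp(df["tjc28"], df["sjc28"], crp)


def _score_4c_crp(df, substitute):
    crp = resolve_censored_crp(df["crp"], df.get("crp_censored", False), substitute)
    return das28_4c_crp(df["tjc28"], df["sjc28"], crp, df["ghvas"])


SCORE_FUNCTIONS = {
    "das28_2c_crp": _score_2c_crp,
    "das28_2c_esr": lambda df, s: das28_2c_esr(df["sjc28"], df["esr"]),
    "das28_3c_crp": _score_3c_crp,
    "das28_4c_crp": _score_4c_crp,
    "das28_4c_esr": lambda df, s: das28_4c_esr(
        df["tjc28"], df["sjc28"], df["esr"], df["ghvas"]),
    "partial_sdai": lambda df, s: partial_sdai(
        df["tjc28"], df["sjc28"],
        resolve_censored_crp(df["crp"], df.get("crp_censored", False), s),
        df["ghvas"]),
    "partial_cdai": lambda df, s: partial_cdai(
        df["tjc28"], df["sjc28"], df["ghvas"]),
}


def add_score_columns(visits, scores=None,
                      crp_substitute: float = DEFAULT_CRP_SUBSTITUTE):
    """Append requested score columns to a per-visit table.

    ``visits`` must carry ``tjc28, sjc28, crp, crp_censored, esr, ghvas``
    as needed by the requested scores.  Rows with missing inputs yield NaN.
    """
    scores = list(SCORE_FUNCTIONS) if scores is None else list(scores)
    out = visits.copy()
    for name in scores:
        if name not in SCORE_FUNCTIONS:
            raise KeyError(f"unknown score {name!r}")
        out[name] = np.asarray(SCORE_FUNCTIONS[name](out, crp_substitute), dtype=float)
    return out
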