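"""Joint-level ultrasound synovitis scoring.

Grey-scale (GS) synovial hypertrophy and power Doppler (PD) signal are
graded semi-quantitatively per joint.  Two conventions for reducing the
joint-level grades to a scalar GSPD outcome are supported:

``composite22``
    The OMERACT-EULAR combined PDUS grade is formed at each joint (0 when
    both GS and PD are absent, otherwise the worse of the two grades) and
    summed over a 22-joint set: wrists, MCPs 2-3, PIPs 2-3, knees and
    MTPs 1-5, bilaterally.  With 0-3 grades the maximum total is 66.

``sum10``
    GS and PD grades are summed separately over bilateral MCPs 1-5
    (10 joints).  With 0-4 grades the maximum total is 80.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COMPOSITE22_JOINTS",
    "SUM10_JOINTS",
    "JointScan",
    "UltrasoundExam",
    "combine_joint",
    "gspd_total",
    "gspd_max",
    "gspd_from_table",
]


def _bilateral(names: list[str]) -> tuple[str, ...]:
    return tuple(f"{side}_{n}" for side in ("r", "l") for n in names)


COMPOSITE22_JOINTS: tuple[str, ...] = _bilateral(
    ["wrist", "mcp2", "mcp3", "pip2", "pip3", "knee",
     "mtp1", "mtp2", "mtp3", "mtp4", "mtp5"]
)
SUM10_JOINTS: tuple[str, ...] = _bilateral(
    ["mcp1", "mcp2", "mcp3", "mcp4", "mcp5"]
)

_METHOD_JOINTS = {"composite22": COMPOSITE22_JOINTS, "sum10": SUM10_JOINTS}


def _check_grade(value: int, scale_max: int, name: str) -> int:
    if not float(value).is_integer():
        raise ValueError(f"{name} grade must be an integer, got {value!r}")
    value = int(value)
    if not 0 <= value <= scale_max:
        raise ValueError(f"{name} grade {value} outside 0-{scale_max}")
    return value


@dataclass(frozen=True)
class JointScan:
    """GS and PD grades for one joint."""

    joint: str
    gs: int
    pd: int

    def validate(self, scale_max: int = 3) -> None:
        _check_grade(self.gs, scale_max, "GS")
        _check_grade(self.pd, scale_max, "PD")


@dataclass
class UltrasoundExam:
    """All joint scans for one patient visit."""

    patient_id: str
    week: float
    scans: list[JointScan]
    method: str = "composite22"
    scale_max: int = 3

    def __post_init__(self) -> None:
        if self.method not in _METHOD_JOINTS:
            raise ValueError(f"unknown GSPD method {self.method!r}")

    @property
    def joints(self) -> set[str]:
        return {s.joint for s in self.scans}


def combine_joint(gs: int, pd: int, scale_max: int = 3) -> int:
    """Combined PDUS grade for one joint.

    Zero is reserved for joints with neither GS hypertrophy nor PD signal;
    any synovitis is graded by the worse of the two findings, so the
    combined grade is ``max(gs, pd)``.  The rule is monotone in both
    arguments and symmetric.
    """
    gs = _check_grade(gs, scale_max, "GS")
    pd = _check_grade(pd, scale_max, "PD")
    if gs == 0 and pd > 0:
        # PD signal without any GS hypertrophy is anatomically atypical.
        logger.debug("atypical scan: PD=%d with GS=0", pd)
    return max(gs, pd)


def gspd_max(method: str, scale_max: int = 3) -> int:
    """Largest attainable GSPD total for a scoring convention."""
    joints = _METHOD_JOINTS[method]
    per_joint = scale_max if method == "composite22" else 2 * scale_max
    return per_joint * len(joints)


def gspd_total(exam: UltrasoundExam) -> int:
    """Scalar GSPD for one exam under its cohort's convention."""
    expected = set(_METHOD_JOINTS[exam.method])
    if exam.joints != expected:
        missing = sorted(expected - exam.joints)
        extra = sorted(exam.joints - expected)
        raise ValueError(
            f"joint set does not match method {exam.method!r}: "
            f"missing={missing} unexpected={extra}"
        )
    if len(exam.scans) != len(expected):
        raise ValueError("duplicate joints in exam")
    for scan in exam.scans:
        scan.validate(exam.scale_max)
    if exam.method == "composite22":
        return sum(combine_joint(s.gs, s.pd, exam.scale_max) for s in exam.scans)
    return sum(s.gs + s.pd for s in exam.scans)


def gspd_from_table(
    ultrasound: pd.DataFrame, method: str, scale_max: int = 3
) -> pd.DataFrame:
    """Reduce a long joint-level table to per-visit GSPD totals.

    Parameters
    ----------
    ultrasound
        Long table with columns ``patient_id, week, joint, gs, pd``.
    method
        ``"composite22"`` or ``"sum10"``.
    scale_max
        Top grade of the GS/PD scales (3 or 4).

    Returns
    -------
    DataFrame with columns ``patient_id, week, gspd, method``.
    """
    required = {"patient_id", "week", "joint", "gs", "pd"}
    if not required.issubset(ultrasound.columns):
        raise ValueError(f"ultrasound table needs columns {sorted(required)}")
    rows = []
    for (pid, week), grp in ultrasound.groupby(["patient_id", "week"], sort=True):
        exam = UltrasoundExam(
            patient_id=pid,
            week=week,
            scans=[
                JointScan(r.joint, int(r.gs), int(r.pd))
                for r in grp.itertuples(index=False)
            ],
            method=method,
            scale_max=scale_max,
        )
        rows.append((pid, week, gspd_total(exam), method))
    return pd.DataFrame(rows, columns=["patient_id", "week", "gspd", "method"])
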