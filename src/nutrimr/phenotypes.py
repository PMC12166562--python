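"""CKD-EPI eGFR computation and incident-CKD case ascertainment.

The estimated glomerular filtration rate follows the CKD-EPI creatinine
equation (2009 form, no race coefficient):

    eGFR = 141 · min(Scr/k, 1)^alpha · max(Scr/k, 1)^(−1.209)
               · 0.993^Age · 1.018 [if female]

with k = 0.7 (female) / 0.9 (male) and alpha = −0.329 (female) / −0.411
(male); Scr is serum creatinine in mg/dL, age in years, and the result in
mL/min/1.73 m². Incident chronic kidney disease is a first crossing below
60 mL/min/1.73 m² during follow-up among subjects at or above 60 at baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EgfrParams",
    "SubjectVisits",
    "CkdStatus",
    "egfr_ckd_epi",
    "creatinine_for_egfr",
    "classify_incident_ckd",
    "classify_cohort",
]

CKD_EGFR_THRESHOLD = 60.0


@dataclass(frozen=True)
class EgfrParams:
    """Constants of the CKD-EPI creatinine equation."""

    scale: float = 141.0
    k_female: float = 0.7
    k_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    max_exponent: float = -1.209
    age_base: float = 0.993
    female_factor: float = 1.018


_DEFAULT_PARAMS = EgfrParams()


def _sex_is_female(sex: str) -> bool:
    s = str(sex).strip().lower()
    if s in ("female", "f"):
        return True
    if s in ("male", "m"):
        return False
    raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")


def egfr_ckd_epi(scr, age, sex: str, params: EgfrParams = _DEFAULT_PARAMS):
    """CKD-EPI eGFR in mL/min/1.73 m² (scalar or elementwise on arrays).

    ``scr`` is serum creatinine in mg/dL and must be positive, as must age.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    female = _sex_is_female(sex)
    k = params.k_female if female else params.k_male
    alpha = params.alpha_female if female else params.alpha_male
    ratio = scr / k
    egfr = (
        params.scale
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** params.max_exponent
        * params.age_base**age
    )
    if female:
        egfr = egfr * params.female_factor
    return float(egfr) if egfr.ndim == 0 else egfr


def creatinine_for_egfr(target_egfr, age, sex: str, params: EgfrParams = _DEFAULT_PARAMS):
    """Invert the CKD-EPI equation: creatinine (mg/dL) giving ``target_egfr``.

    Exact inverse on both branches (eGFR is strictly decreasing in Scr), used
    by the synthetic-cohort generator to manufacture trajectories with
    prescribed eGFR values.
    """
    target = np.asarray(target_egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target eGFR must be positive")
    female = _sex_is_female(sex)
    k = params.k_female if female else params.k_male
    alpha = params.alpha_female if female else params.alpha_male
    base = params.scale * params.age_base**age * (params.female_factor if female else 1.0)
    ratio_t = target / base  # eGFR at Scr = k is exactly `base`
    scr = np.where(
        ratio_t >= 1.0,
        k * ratio_t ** (1.0 / alpha),  # Scr below k
        k * ratio_t ** (1.0 / params.max_exponent),  # Scr above k
    )
    return float(scr) if scr.ndim == 0 else scr


class CkdStatus(str, enum.Enum):
    EXCLUDED_BASELINE = "excluded_baseline"
    INCIDENT_CASE = "incident_case"
    NON_CASE = "non_case"


@dataclass(frozen=True)
class SubjectVisits:
    """One subject's longitudinal creatinine record.

    ``visits`` is an ordered sequence of (time in years from baseline,
    serum creatinine in mg/dL, age in years); the first visit must be the
    baseline at time 0 and times must be strictly increasing.
    """

    subject_id: str
    sex: str
    visits: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"{self.subject_id}: at least one (baseline) visit is required")
        times = [v[0] for v in self.visits]
        if times[0] != 0.0:
            raise ValueError(f"{self.subject_id}: first visit must be at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.subject_id}: visit times must be strictly increasing")


def classify_incident_ckd(subject: SubjectVisits, threshold: float = CKD_EGFR_THRESHOLD) -> CkdStatus:
    """Classify one subject from their creatinine trajectory.

    ``excluded_baseline`` if baseline eGFR < threshold, ``incident_case`` if
    baseline eGFR ≥ threshold and any follow-up eGFR < threshold (first
    qualifying visit; no confirmatory measurement required), ``non_case``
    otherwise. eGFR is not rounded before comparison.
    """
    egfrs = [egfr_ckd_epi(scr, age, subject.sex) for (_t, scr, age) in subject.visits]
    if egfrs[0] < threshold:
        return CkdStatus.EXCLUDED_BASELINE
    if any(e < threshold for e in egfrs[1:]):
        return CkdStatus.INCIDENT_CASE
    return CkdStatus.NON_CASE


def classify_cohort(visits: pd.DataFrame, threshold: float = CKD_EGFR_THRESHOLD) -> pd.DataFrame:
    """Classify every subject in a long-format visit table.

    ``visits`` needs columns subject_id, time, age, sex, scr. Returns one row
    per subject with the subject's status; the three categories partition the
    cohort.
    """
    required = {"subject_id", "time", "age", "sex", "scr"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing column(s) {sorted(missing)}")
    out = []
    for subject_id, grp in visits.groupby("subject_id", sort=False):
        grp = grp.sort_values("time")
        subj = SubjectVisits(
            subject_id=str(subject_id),
            sex=str(grp["sex"].iloc[0]),
            visits=tuple(zip(grp["time"].astype(float), grp["scr"].astype(float), grp["age"].astype(float))),
        )
        out.append({"subject_id": str(subject_id), "status": classify_incident_ckd(subj, threshold).value})
    return pd.DataFrame(out, columns=["subject_id", "status"])
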