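"""Per-patient glycemic summaries, Charlson comorbidity score and cohort filters.

The central quantity is the estimated pre-hospital glycemic coefficient of
variation: the in-hospital glucose standard deviation divided by the
pre-admission mean glucose inferred from HbA1c, expressed as a percentage.
Because numerator and denominator share units (mg/dl), the index links the
dispersion of inpatient glycemia to the patient's chronic glycemic burden.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import PatientRecord

# ADAG linear regression between HbA1c (%) and estimated average glucose
# (mg/dl): eAG = 28.7 * A1c - 46.7.  Swappable for other linear maps.
ADAG_SLOPE = 28.7
ADAG_INTERCEPT = -46.7

HBA1C_DOMAIN = (4.0, 15.0)


class InsufficientDataError(ValueError):
    """Raised when a glucose series is too short to summarize."""


def hba1c_to_mean_glucose(
    hba1c: float, slope: float = ADAG_SLOPE, intercept: float = ADAG_INTERCEPT
) -> float:
    """Convert an HbA1c percentage to estimated average glucose in mg/dl.

    Uses the linear ADAG regression ``eAG = 28.7 * A1c - 46.7`` by default;
    ``slope`` and ``intercept`` allow other published linear maps.

    Parameters
    ----------
    hba1c : float
        Glycated hemoglobin, percent. Must lie in the physiologic window
        [4, 15] — outside it the linear relationship is not credible.

    Returns
    -------
    float
        Estimated average (pre-admission) blood glucose, mg/dl.
    """
    lo, hi = HBA1C_DOMAIN
    if not (lo <= hba1c <= hi):
        raise ValueError(
            f"hba1c={hba1c!r} outside the supported domain [{lo}, {hi}] percent"
        )
    return slope * hba1c + intercept


@dataclass(frozen=True)
class GlycemicSummary:
    """Derived glycemic indexes for one admission.

    Attributes
    ----------
    pre_mean_glucose : float
        HbA1c-derived pre-admission mean glucose, mg/dl.
    in_mean, in_median : float
        Mean and median of the in-hospital glucose series, mg/dl.
    in_sd : float
        Sample standard deviation (n-1 denominator) of the series, mg/dl —
        the "glycemic variability" index.
    in_cv : float
        In-hospital coefficient of variation, percent: 100 * in_sd / in_mean.
    est_pre_cv : float
        Estimated pre-hospital CV, percent: 100 * in_sd / pre_mean_glucose.
    ratio_in_pre : float
        In-hospital mean over pre-hospital mean glucose (dimensionless).
    hirsch_ok : bool
        True when in_sd * 3 <= in_mean (SD no more than one third of the
        mean — Hirsch's glycemic-control heuristic).
    n_measurements : int
        Number of glucose values summarized.
    """

    pre_mean_glucose: float
    in_mean: float
    in_median: float
    in_sd: float
    in_cv: float
    est_pre_cv: float
    ratio_in_pre: float
    hirsch_ok: bool
    n_measurements: int


def summarize_glycemia(
    record: PatientRecord, ddof: int = 1, conversion: Mapping[str, float] | None = None
) -> GlycemicSummary:
    """Compute all glycemic indexes for one patient.

    ``ddof=1`` (sample SD): the inpatient series is treated as a sample of
    the patient's underlying glycemic process.  ``conversion`` may override
    the HbA1c->glucose map with ``{"slope": ..., "intercept": ...}``.
    """
    series = list(record.glucose_series)
    if len(series) < 2:
        raise InsufficientDataError(
            f"patient {record.patient_id}: need >= 2 glucose values, got {len(series)}"
        )
    conv = conversion or {}
    pre_mean = hba1c_to_mean_glucose(
        record.hba1c,
        slope=conv.get("slope", ADAG_SLOPE),
        intercept=conv.get("intercept", ADAG_INTERCEPT),
    )
    in_mean = statistics.fmean(series)
    in_median = statistics.median(series)
    in_sd = statistics.stdev(series) if ddof == 1 else statistics.pstdev(series)
    return GlycemicSummary(
        pre_mean_glucose=pre_mean,
        in_mean=in_mean,
        in_median=in_median,
        in_sd=in_sd,
        in_cv=100.0 * in_sd / in_mean,
        est_pre_cv=100.0 * in_sd / pre_mean,
        ratio_in_pre=in_mean / pre_mean,
        hirsch_ok=in_sd * 3.0 <= in_mean,
        n_measurements=len(series),
    )


# Original Charlson weights, keyed by the cohort's comorbidity flags.  The
# two diabetes terms are handled separately (exactly one may contribute).
CHARLSON_WEIGHTS: dict[str, int] = {
    "ischemic_heart_disease": 1,   # myocardial infarction / IHD
    "heart_failure": 1,
    "pad": 1,
    "stroke_tia": 1,
    "dementia": 1,
    "copd": 1,
    "rheumatological_disease": 1,
    "mild_hepatopathy": 1,
    "hemiplegia": 2,
    "ckd": 2,                      # moderate or severe chronic kidney disease
    "localized_malignancy": 2,     # localized solid or hematological
    "severe_hepatopathy": 3,
    "metastatic_malignancy": 6,
}
CHARLSON_DIABETES_WEIGHTS = {"t2dm_uncomplicated": 1, "t2dm_complicated": 2}


def charlson_index(
    flags: Mapping[str, bool], age: float | None = None, age_adjusted: bool = False
) -> int:
    """Charlson Comorbidity Index from boolean comorbidity flags.

    Weights are the original ones (1 point: infarction/ischemic heart
    disease, heart failure, peripheral artery disease, stroke/TIA, dementia,
    COPD, rheumatological disease, mild liver disease, uncomplicated
    diabetes; 2: hemiplegia, moderate/severe CKD, complicated diabetes,
    localized/hematological malignancy; 3: severe liver disease;
    6: metastatic malignancy).  Unknown flag names are ignored so the same
    mapping accepts richer phenotype dictionaries.

    If ``age_adjusted``, one point is added per decade of age from 50
    upwards, capped at 4 (i.e. ages 50-59 add 1, ..., >= 80 add 4).
    """
    if flags.get("t2dm_uncomplicated") and flags.get("t2dm_complicated"):
        raise ValueError("at most one of t2dm_uncomplicated / t2dm_complicated may be set")
    score = sum(w for name, w in CHARLSON_WEIGHTS.items() if flags.get(name))
    score += sum(w for name, w in CHARLSON_DIABETES_WEIGHTS.items() if flags.get(name))
    if age_adjusted:
        if age is None:
            raise ValueError("age required when age_adjusted=True")
        score += min(max(int(age) // 10 - 4, 0), 4)
    return score


# Exclusion reasons, checked in this order; a record is tagged with the
# first rule it fails.
_FILTERS = (
    ("insufficient_glucose_measurements", lambda r: len(r.glucose_series) < 12),
    ("stay_shorter_than_48h", lambda r: r.length_of_stay < 2),
    ("missing_hba1c", lambda r: r.hba1c is None),
)


def apply_inclusion_filters(
    cohort: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Split a cohort into included records and (record, reason) exclusions.

    Mirrors the study's inclusion rules: at least 12 consecutive pre-prandial
    glucose determinations, at least a 48-hour stay, and an admission HbA1c.
    """
    included: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, str]] = []
    for rec in cohort:
        for reason, fails in _FILTERS:
            if fails(rec):
                excluded.append((rec, reason))
                break
        else:
            included.append(rec)
    return included, excluded


def summarize_cohort(
    cohort: Sequence[PatientRecord], age_adjusted_cci: bool = False
) -> pd.DataFrame:
    """One row per patient: every glycemic index plus the Charlson score."""
    rows = []
    for rec in cohort:
        summ = asdict(summarize_glycemia(rec))
        summ["patient_id"] = rec.patient_id
        summ["age"] = rec.age
        summ["length_of_stay"] = rec.length_of_stay
        summ["cci"] = charlson_index(rec.comorbidities, rec.age, age_adjusted_cci)
        summ["died_30d"] = rec.died_30d
        rows.append(summ)
    df = pd.DataFrame(rows)
    cols = ["patient_id"] + [c for c in df.columns if c != "patient_id"]
    return df[cols]
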