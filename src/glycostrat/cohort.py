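"""Seeded synthetic cohorts of hospitalized T2DM patients.

No patient-level dataset is distributed with the analysis this package
re-implements, so every downstream stage is exercised on cohorts drawn from
this generator.  Its defaults emulate the published descriptive marginals of
a 120-patient internal-medicine cohort (age 78.4 +/- 8.9 y, HbA1c 7.0 +/-
1.6 %, ~14 % 30-day mortality, stated comorbidity and home-treatment
prevalences) and the generator plants user-chosen log-odds effects of any
covariate — including the latent glycemic indexes — on the 30-day death
indicator through a logistic model whose intercept is calibrated to hit the
requested marginal mortality rate.

The per-patient glycemic process is latent-first: each patient receives a
pre-admission mean glucose from their drawn HbA1c, an in-hospital mean equal
to that value times a drawn in/pre ratio, and a target coefficient of
variation; the observed series is then lognormal noise around those targets,
four slots per day of stay (breakfast, lunch, dinner, bedtime).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

GLUCOSE_SLOTS = ("breakfast", "lunch", "dinner", "bedtime")
SLOTS_PER_DAY = len(GLUCOSE_SLOTS)

TREATMENT_CATEGORIES = (
    "diet",
    "metformin",
    "sulphonylureas",
    "dpp4i",
    "glp1ra",
    "insulin",
    "sglt2i",
    "other",
)

# Published cohort marginals (counts out of n=120) used as defaults.
_DEFAULT_COMORBIDITY_PREV = {
    "hypertension": 92 / 120,
    "ischemic_heart_disease": 28 / 120,
    "heart_failure": 16 / 120,
    "ckd": 32 / 120,
    "stroke_tia": 19 / 120,
    "pad": 14 / 120,
    "copd": 31 / 120,
    "mild_hepatopathy": 2 / 120,
    "severe_hepatopathy": 1 / 120,
    "hemiplegia": 5 / 120,
    "localized_malignancy": 27 / 120,
    "metastatic_malignancy": 7 / 120,
    "dementia": 31 / 120,
    "rheumatological_disease": 2 / 120,
    "t2dm_complicated": 64 / 120,
}

# Printed home-treatment counts sum to 119/120; normalized here.
_RAW_TREATMENT_COUNTS = (14, 31, 2, 4, 1, 26, 5, 36)
_DEFAULT_TREATMENT_DIST = {
    cat: cnt / sum(_RAW_TREATMENT_COUNTS)
    for cat, cnt in zip(TREATMENT_CATEGORIES, _RAW_TREATMENT_COUNTS)
}

# Default planted mortality effects (log-odds): hemiplegia, dementia and
# male sex as categorical risk factors and the estimated pre-hospital CV as
# a continuous one (per percentage point), mirroring the directions the
# source analysis reports.
_DEFAULT_EFFECTS = {
    "hemiplegia": 2.5,
    "dementia": 1.3,
    "male": 1.0,
    "est_pre_cv": 0.06,
}

HBA1C_BOUNDS = (4.0, 15.0)  # physiologic window for the linear conversion
RATIO_BOUNDS = (0.3, 3.0)
GLUCOSE_BOUNDS = (30.0, 600.0)


class CohortValidationError(ValueError):
    """A CohortSpec field violates its invariant."""


class CalibrationError(RuntimeError):
    """The requested marginal mortality rate cannot be attained."""


@dataclass(frozen=True)
class PatientRecord:
    """One hospital admission of a T2DM patient."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    smoker: bool
    comorbidities: dict[str, bool]
    home_treatment: str
    hba1c: float | None
    glucose_series: list[float]
    glucose_slots: list[str]
    length_of_stay: float  # days; for deceased patients, the day of death
    died_30d: bool


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the published cohort's marginals."""

    n_patients: int = 120
    mortality_rate: float = 17 / 120
    age_mean: float = 78.4
    age_sd: float = 8.9
    male_fraction: float = 72 / 120
    smoker_fraction: float = 44 / 120
    hba1c_mean: float = 7.0
    hba1c_sd: float = 1.6
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_PREV)
    )
    treatment_distribution: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TREATMENT_DIST)
    )
    ratio_mean: float = 1.12
    ratio_sd: float = 0.27
    within_patient_cv_range: tuple[float, float] = (10.0, 45.0)  # percent
    stay_mean_survivor: float = 15.5
    stay_sd_survivor: float = 12.6
    stay_mean_deceased: float = 9.3
    stay_sd_deceased: float = 4.6
    effect_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise CohortValidationError("n_patients must be >= 2")
        for name in ("mortality_rate", "male_fraction", "smoker_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortValidationError(f"{name}={v} not a probability")
        if not 0.0 < self.mortality_rate < 1.0:
            raise CohortValidationError("mortality_rate must lie strictly in (0, 1)")
        for name, p in self.comorbidity_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise CohortValidationError(
                    f"comorbidity_prevalences[{name!r}]={p} not a probability"
                )
        tot = sum(self.treatment_distribution.values())
        if abs(tot - 1.0) > 1e-9:
            raise CohortValidationError(
                f"treatment_distribution sums to {tot}, expected 1"
            )
        lo, hi = self.within_patient_cv_range
        if not (0.0 < lo <= hi):
            raise CohortValidationError(
                f"within_patient_cv_range={self.within_patient_cv_range} must be positive"
            )
        for name in (
            "age_sd",
            "hba1c_sd",
            "ratio_sd",
            "stay_mean_survivor",
            "stay_mean_deceased",
        ):
            if getattr(self, name) <= 0:
                raise CohortValidationError(f"{name} must be positive")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws whose *post-truncation* moments match mean/sd.

    Asymmetric truncation shifts the moments of a naive truncated normal
    (e.g. N(7, 1.6) truncated at 4 has mean ~7.15), so the location and
    scale are solved by root-finding to make the truncated distribution
    itself carry the requested mean and SD.
    """
    from scipy.optimize import root

    def gap(params):
        loc, log_scale = params
        scale = float(np.exp(log_scale))
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = root(gap, [mean, np.log(sd)], tol=1e-10)
    loc, scale = (sol.x[0], float(np.exp(sol.x[1]))) if sol.success else (mean, sd)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def calibrate_intercept(
    effect_log_odds: Mapping[str, float],
    covariate_sample: pd.DataFrame,
    target_rate: float,
) -> float:
    """Intercept making the mean logistic probability equal ``target_rate``.

    Solves ``mean(expit(c + X @ beta)) = target_rate`` for ``c`` by monotone
    root-finding (the mean probability is strictly increasing in ``c``).
    """
    if not 0.0 < target_rate < 1.0:
        raise CalibrationError(f"target_rate={target_rate} must lie in (0, 1)")
    eta = np.zeros(len(covariate_sample))
    for name, beta in effect_log_odds.items():
        if name not in covariate_sample.columns:
            raise CohortValidationError(
                f"effect_log_odds references unknown covariate {name!r}"
            )
        eta = eta + beta * covariate_sample[name].to_numpy(dtype=float)
    if not np.all(np.isfinite(eta)):
        raise CalibrationError("non-finite linear predictor; cannot calibrate")

    def gap(c):
        return float(np.mean(expit(c + eta))) - target_rate

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target rate {target_rate} unattainable over the given covariates"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _lognormal_params(mean: np.ndarray, sd: np.ndarray):
    """Mu/sigma of a lognormal with the given arithmetic mean and SD."""
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_cohort(
    spec: CohortSpec, include_records: bool = True
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a cohort and return it with its latent covariate frame.

    The covariate frame holds, per patient, every value the logistic death
    model could see: demographics, comorbidity flags, and the *latent*
    glycemic targets (pre/in-hospital mean, SD, CVs, ratio) before
    measurement noise.  Refitting planted effects against this frame avoids
    the attenuation that re-estimated sample summaries would introduce.
    ``include_records=False`` skips building the PatientRecord objects (the
    random stream is identical either way), which speeds up repeated-seed
    recovery studies that only need the covariate frame.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, 18.0, 110.0, n)
    male = rng.random(n) < spec.male_fraction
    smoker = rng.random(n) < spec.smoker_fraction

    flags = {
        name: rng.random(n) < p for name, p in spec.comorbidity_prevalences.items()
    }
    if "t2dm_complicated" in flags:
        flags["t2dm_uncomplicated"] = ~flags["t2dm_complicated"]

    cats = list(spec.treatment_distribution)
    probs = np.array([spec.treatment_distribution[c] for c in cats])
    treatment = rng.choice(cats, size=n, p=probs / probs.sum())

    hba1c = _truncated_normal(rng, spec.hba1c_mean, spec.hba1c_sd, *HBA1C_BOUNDS, n)
    # Local import: indices depends on PatientRecord from this module.
    from .indices import hba1c_to_mean_glucose

    pre_mean = np.array([hba1c_to_mean_glucose(a) for a in hba1c])
    ratio = _truncated_normal(rng, spec.ratio_mean, spec.ratio_sd, *RATIO_BOUNDS, n)
    cv_lo, cv_hi = spec.within_patient_cv_range
    in_cv = rng.uniform(cv_lo, cv_hi, size=n)  # percent
    in_mean = pre_mean * ratio
    in_sd = in_cv / 100.0 * in_mean
    est_pre_cv = 100.0 * in_sd / pre_mean  # == in_cv * ratio

    covariates = pd.DataFrame(
        {
            "age": age,
            "male": male.astype(float),
            "smoker": smoker.astype(float),
            "hba1c": hba1c,
            "pre_mean_glucose": pre_mean,
            "in_mean": in_mean,
            "in_sd": in_sd,
            "in_cv": in_cv,
            "est_pre_cv": est_pre_cv,
            "ratio_in_pre": ratio,
            **{name: arr.astype(float) for name, arr in flags.items()},
        }
    )

    intercept = calibrate_intercept(
        spec.effect_log_odds, covariates, spec.mortality_rate
    )
    eta = np.full(n, intercept)
    for name, beta in spec.effect_log_odds.items():
        eta += beta * covariates[name].to_numpy(dtype=float)
    p_death = expit(eta)
    died = rng.random(n) < p_death

    stay_mean = np.where(died, spec.stay_mean_deceased, spec.stay_mean_survivor)
    stay_sd = np.where(died, spec.stay_sd_deceased, spec.stay_sd_survivor)
    mu, sigma = _lognormal_params(stay_mean, stay_sd)
    stay = np.maximum(np.rint(rng.lognormal(mu, sigma)), 2.0)

    lengths = (stay * SLOTS_PER_DAY).astype(int)
    gmu, gsigma = _lognormal_params(in_mean, in_sd)
    total = int(lengths.sum())
    draws = rng.lognormal(np.repeat(gmu, lengths), np.repeat(gsigma, lengths), total)
    draws = np.clip(draws, *GLUCOSE_BOUNDS)
    offsets = np.concatenate(([0], np.cumsum(lengths)))

    covariates["died_30d"] = died.astype(float)
    covariates["p_death"] = p_death
    covariates["length_of_stay"] = stay

    records: list[PatientRecord] = []
    if not include_records:
        return records, covariates
    width = len(str(n))
    for i in range(n):
        series = draws[offsets[i] : offsets[i + 1]]
        slots = [GLUCOSE_SLOTS[k % SLOTS_PER_DAY] for k in range(lengths[i])]
        records.append(
            PatientRecord(
                patient_id=f"SYN-{i:0{width}d}",
                age=float(age[i]),
                sex="male" if male[i] else "female",
                smoker=bool(smoker[i]),
                comorbidities={name: bool(arr[i]) for name, arr in flags.items()},
                home_treatment=str(treatment[i]),
                hba1c=float(hba1c[i]),
                glucose_series=[float(v) for v in series],
                glucose_slots=slots,
                length_of_stay=float(stay[i]),
                died_30d=bool(died[i]),
            )
        )
    return records, covariates


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a seeded synthetic cohort of PatientRecord objects."""
    return simulate_cohort(spec)[0]


def simulate_survival_times(
    linear_predictor: np.ndarray,
    baseline_rate: float,
    rng: np.random.Generator,
    horizon: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards event times, censored at ``horizon``.

    Hazard for subject i is ``baseline_rate * exp(linear_predictor[i])``;
    returns (time, event) with administrative censoring at the horizon.
    Used to plant known log-hazard effects when validating the Cox fitter.
    """
    eta = np.asarray(linear_predictor, dtype=float)
    raw = rng.exponential(1.0 / (baseline_rate * np.exp(eta)))
    event = raw <= horizon
    return np.minimum(raw, horizon), event


# ---------------------------------------------------------------------------
# CSV round-trip.  Wide format, one row per patient; the glucose series and
# its slot labels are semicolon-delimited fields.

_SCHEMA_VERSION = "glycostrat-cohort-v1"
_BASE_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "smoker",
    "home_treatment",
    "hba1c",
    "length_of_stay",
    "died_30d",
    "glucose_series",
    "glucose_slots",
]


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    """Write a cohort as CSV (schema version in a leading comment line)."""
    comorb_names = sorted(
        {name for rec in cohort for name in rec.comorbidities}
    ) or sorted(_DEFAULT_COMORBIDITY_PREV)
    cols = _BASE_COLUMNS[:8] + comorb_names + _BASE_COLUMNS[8:]
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {_SCHEMA_VERSION}\n")
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for rec in cohort:
            row = {
                "patient_id": rec.patient_id,
                "age": repr(rec.age),
                "sex": rec.sex,
                "smoker": int(rec.smoker),
                "home_treatment": rec.home_treatment,
                "hba1c": "" if rec.hba1c is None else repr(rec.hba1c),
                "length_of_stay": repr(rec.length_of_stay),
                "died_30d": int(rec.died_30d),
                "glucose_series": ";".join(repr(v) for v in rec.glucose_series),
                "glucose_slots": ";".join(rec.glucose_slots),
            }
            for name in comorb_names:
                row[name] = int(rec.comorbidities.get(name, False))
            writer.writerow(row)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    with open(path, newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(lines)))
    missing = [c for c in _BASE_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    comorb_names = [c for c in reader.fieldnames if c not in _BASE_COLUMNS]
    records = []
    for row in reader:
        series = [float(v) for v in row["glucose_series"].split(";") if v]
        slots = [s for s in row["glucose_slots"].split(";") if s]
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                age=float(row["age"]),
                sex=row["sex"],
                smoker=bool(int(row["smoker"])),
                comorbidities={n: bool(int(row[n])) for n in comorb_names},
                home_treatment=row["home_treatment"],
                hba1c=float(row["hba1c"]) if row["hba1c"] else None,
                glucose_series=series,
                glucose_slots=slots,
                length_of_stay=float(row["length_of_stay"]),
                died_30d=bool(int(row["died_30d"])),
            )
        )
    return records


def spec_to_json_dict(spec: CohortSpec) -> dict:
    """JSON-serializable form of a CohortSpec (for configs and manifests)."""
    d = asdict(spec)
    d["within_patient_cv_range"] = list(spec.within_patient_cv_range)
    return d


def spec_from_json_dict(d: Mapping) -> CohortSpec:
    kwargs = dict(d)
    if "within_patient_cv_range" in kwargs:
        kwargs["within_patient_cv_range"] = tuple(kwargs["within_patient_cv_range"])
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec
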