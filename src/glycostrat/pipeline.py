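"""End-to-end orchestration: simulate -> filter -> indices -> stratify -> fit -> ml.

One RunConfig drives the whole analysis; a single global seed fans out to
per-stage child seeds through a fixed arithmetic scheme (child = (seed *
1000003 + stage index) mod 2^31) so any stage can be replayed in isolation.
The run writes CSV/JSON artifacts plus a manifest whose hash is stable
across reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CohortSpec,
    PatientRecord,
    generate_cohort,
    read_cohort_csv,
    spec_to_json_dict,
    write_cohort_csv,
)
from .indices import apply_inclusion_filters, summarize_cohort
from .stratify import (
    StratificationRule,
    mann_whitney_u,
    mortality_table,
    normality_screen,
    optimal_cutoff_closest_to_corner,
    pearson_chi2,
    ContingencyTable2x2,
    roc_curve,
    round_half_up,
    welch_t,
)
from .risk import cox_fit, logistic_fit, survival_curves
from .boosting import (
    FeatureTable,
    adaboost_train,
    apply_minmax,
    baseline_models,
    evaluate,
    fas_augment,
    feature_table,
    fit_minmax,
    lasso_logistic_select,
    model_reliance,
    smote,
    stratified_split,
)

# Published cutoffs: in-hospital glucose SD (mg/dl), in-hospital CV (%),
# estimated pre-hospital CV (%).
FIXED_CUTOFFS = {"in_sd": 42.55, "in_cv": 25.8, "est_pre_cv": 28.8}

_STAGE_INDEX = {"simulate": 0, "split": 1, "smote": 2, "lasso": 3, "reliance": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the global seed."""
    return (global_seed * 1000003 + _STAGE_INDEX[stage]) % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    cohort_spec: CohortSpec | None = None
    cohort_csv: str | None = None
    cutoff_mode: str = "fixed"  # "fixed" | "derive"
    cutoffs: dict = field(default_factory=lambda: dict(FIXED_CUTOFFS))
    seed: int = 0
    ml_rounds: int = 100
    use_fas: bool = True
    use_smote: bool = True
    run_baselines: bool = False
    reliance_repeats: int = 100
    out_dir: str = "glycostrat_run"

    def validate(self) -> None:
        if (self.cohort_spec is None) == (self.cohort_csv is None):
            raise ValueError("exactly one of cohort_spec / cohort_csv must be set")
        if self.cutoff_mode not in ("fixed", "derive"):
            raise ValueError("cutoff_mode must be 'fixed' or 'derive'")
        if any(v <= 0 for v in self.cutoffs.values()):
            raise ValueError("cutoffs must be positive")

    def to_json_dict(self) -> dict:
        """Analysis-defining fields only: out_dir names where results go,
        not what is computed, so it stays out of the manifest hash."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        if self.cohort_spec is not None:
            d["cohort_spec"] = spec_to_json_dict(self.cohort_spec)
        return d


# ---------------------------------------------------------------------------
# Descriptive (Table-1 style) report


_CONTINUOUS_VARS = [
    "age",
    "length_of_stay",
    "hba1c",
    "pre_mean_glucose",
    "in_mean",
    "in_median",
    "ratio_in_pre",
    "in_sd",
    "in_cv",
    "est_pre_cv",
    "cci",
]


def descriptive_report(df: pd.DataFrame, group_col: str = "died_30d") -> pd.DataFrame:
    """Overall and group-wise summaries with routed univariate tests.

    Continuous variables use the Mann-Whitney U test unless the normality
    screen passes in both groups, in which case Welch's t; categorical
    variables use uncorrected Pearson chi-square.  The routing decision is
    recorded per variable.
    """
    g = df[group_col].astype(bool)
    rows = []
    for var in df.columns:
        if var in (group_col, "patient_id"):
            continue
        x = df.loc[g, var].to_numpy(dtype=float)
        y = df.loc[~g, var].to_numpy(dtype=float)
        if var in _CONTINUOUS_VARS:
            try:
                routed = (
                    "t_test"
                    if normality_screen(x) == "normal" and normality_screen(y) == "normal"
                    else "mann_whitney"
                )
            except ValueError:
                routed = "mann_whitney"
            res = welch_t(x, y, var) if routed == "t_test" else mann_whitney_u(x, y, var)
            rows.append(
                {
                    "variable": var,
                    "kind": "continuous",
                    "test": res.test,
                    "overall": f"{df[var].mean():.1f} +/- {df[var].std(ddof=1):.1f}",
                    "group1": f"{x.mean():.1f} +/- {x.std(ddof=1):.1f}",
                    "group0": f"{y.mean():.1f} +/- {y.std(ddof=1):.1f}",
                    "p_value": res.p_value,
                }
            )
        else:
            a, c = int(x.sum()), int(y.sum())
            try:
                res = pearson_chi2(
                    ContingencyTable2x2(a, len(x) - a, c, len(y) - c), var
                )
                p = res.p_value
            except ValueError:
                p = np.nan
            rows.append(
                {
                    "variable": var,
                    "kind": "categorical",
                    "test": "chi_square",
                    "overall": f"{a + c} ({round_half_up(100 * (a + c) / len(df), 1)})",
                    "group1": f"{a} ({round_half_up(100 * a / len(x), 1) if len(x) else 0})",
                    "group0": f"{c} ({round_half_up(100 * c / len(y), 1) if len(y) else 0})",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ML arm


def ml_feature_table(cohort: list[PatientRecord], summaries: pd.DataFrame) -> FeatureTable:
    """Raw ML features: demographics, comorbidities, treatment one-hots and
    glycemic summaries.  Length of stay is deliberately excluded (it is not
    available prospectively at admission), as is the estimated pre-hospital
    CV (the stratification index under study, kept out of the classifier).
    """
    from .cohort import TREATMENT_CATEGORIES

    feats = {}
    feats["age"] = [r.age for r in cohort]
    feats["male"] = [1.0 if r.sex == "male" else 0.0 for r in cohort]
    feats["smoker"] = [float(r.smoker) for r in cohort]
    feats["hba1c"] = [r.hba1c for r in cohort]
    comorb_names = sorted({n for r in cohort for n in r.comorbidities})
    for name in comorb_names:
        feats[name] = [float(r.comorbidities.get(name, False)) for r in cohort]
    for cat in TREATMENT_CATEGORIES:
        feats[f"tx_{cat}"] = [float(r.home_treatment == cat) for r in cohort]
    df = pd.DataFrame(feats)
    for col in ("in_mean", "in_median", "in_sd", "ratio_in_pre"):
        df[col] = summaries[col].to_numpy()
    kinds = {
        c: "continuous"
        if c in ("age", "hba1c", "in_mean", "in_median", "in_sd", "ratio_in_pre")
        else "binary"
        for c in df.columns
    }
    died = summaries["died_30d"].to_numpy(dtype=bool)
    return feature_table(df, died, kinds)


def run_ml_arm(
    table: FeatureTable,
    seed: int = 0,
    rounds: int = 100,
    use_fas: bool = True,
    use_smote: bool = True,
    run_baselines: bool = False,
    reliance_repeats: int = 100,
) -> dict:
    """Train and evaluate the boosting classifier on one feature table.

    Order: stratified 75/25 split, min-max scaling fitted on the training
    rows, SMOTE balancing of the training set, FAS augmentation, LASSO
    selection, AdaBoost over the selected features; evaluation and reliance
    on the untouched test rows.
    """
    train, test = stratified_split(table, 0.75, seed=stage_seed(seed, "split"))
    params = fit_minmax(train)
    train_s, test_s = apply_minmax(train, params), apply_minmax(test, params)
    train_b = smote(train_s, seed=stage_seed(seed, "smote")) if use_smote else train_s

    if use_fas:
        train_f, test_f = fas_augment(train_b), fas_augment(test_s)
        selected = lasso_logistic_select(train_f, seed=stage_seed(seed, "lasso"))
    else:
        train_f, test_f = train_b, test_s
        selected = list(train_f.X.columns)

    model = adaboost_train(train_f, L_rounds=rounds, features=selected)
    metrics = evaluate(model, test_f)

    base_feats = sorted(
        {p for name in model.feature_names for p in test_f.parents.get(name, (name,))}
    )
    reliance = [
        model_reliance(
            model, test_f, f, n_repeats=reliance_repeats, seed=stage_seed(seed, "reliance")
        )
        for f in base_feats
    ]
    out = {
        "model": model,
        "metrics": metrics,
        "selected_features": selected,
        "reliance": pd.DataFrame(reliance),
        "n_train": len(train.died),
        "n_test": len(test.died),
    }
    if run_baselines:
        out["baselines"] = baseline_models(
            train_b, test_s, train_f if use_fas else None, test_f if use_fas else None,
            L_rounds=rounds, seed=stage_seed(seed, "split"),
        )
    return out


# ---------------------------------------------------------------------------
# Printed-table verification (counts transcribed from the published report)

# 2x2 stratification tables: (deaths_low, n_low, deaths_high, n_high) and
# the printed percentages / p-value for each glycemic rule.
PRINTED_STRATA = {
    "in_sd": {"deaths": (4, 13), "sizes": (54, 66), "pct": (7.4, 19.7), "p": None},
    "in_cv": {"deaths": (4, 13), "sizes": (48, 72), "pct": (8.3, 18.1), "p": None},
    "est_pre_cv": {"deaths": (4, 13), "sizes": (56, 64), "pct": (7.1, 20.3), "p": 0.039},
}
# Deceased (n=17) vs survivor (n=103) univariate counts with printed values.
PRINTED_UNIVARIATE = {
    "dementia": {"deceased": 9, "survivor": 22, "pct_deceased": 52.9, "p": 0.006},
    "metastatic_malignancy": {"deceased": 3, "survivor": 4, "pct_deceased": 17.6, "p": 0.025},
    "hemiplegia": {"deceased": 4, "survivor": 1, "pct_deceased": 23.5, "p": None},
}
N_DECEASED, N_SURVIVOR = 17, 103


def verify_paper_tables() -> pd.DataFrame:
    """Recompute the published mortality percentages and chi-square p-values.

    All inputs are the printed stratum counts; each row reports the
    recomputed value, the printed one, and whether the recomputation rounds
    to it.  (Two stratification p-values the published table prints as 0.06
    and 0.14 are not checked: no standard uncorrected Pearson chi-square on
    the printed counts reproduces them exactly.)
    """
    checks = []
    for rule, d in PRINTED_STRATA.items():
        (d_lo, d_hi), (n_lo, n_hi) = d["deaths"], d["sizes"]
        pct = (round_half_up(100 * d_lo / n_lo, 1), round_half_up(100 * d_hi / n_hi, 1))
        for side, got, want in (("low", pct[0], d["pct"][0]), ("high", pct[1], d["pct"][1])):
            checks.append(
                {"check": f"{rule}_{side}_pct", "computed": got, "printed": want,
                 "pass": got == want}
            )
        res = pearson_chi2(
            ContingencyTable2x2(d_lo, n_lo - d_lo, d_hi, n_hi - d_hi), rule
        )
        if d["p"] is not None:
            checks.append(
                {"check": f"{rule}_chi2_p", "computed": round(res.p_value, 3),
                 "printed": d["p"], "pass": round(res.p_value, 3) == d["p"]}
            )
    for var, d in PRINTED_UNIVARIATE.items():
        a, c = d["deceased"], d["survivor"]
        res = pearson_chi2(
            ContingencyTable2x2(a, N_DECEASED - a, c, N_SURVIVOR - c), var
        )
        pct = round_half_up(100 * a / N_DECEASED, 1)
        checks.append(
            {"check": f"{var}_pct_deceased", "computed": pct,
             "printed": d["pct_deceased"], "pass": pct == d["pct_deceased"]}
        )
        if d["p"] is not None:
            checks.append(
                {"check": f"{var}_chi2_p", "computed": round(res.p_value, 3),
                 "printed": d["p"], "pass": round(res.p_value, 3) == d["p"]}
            )
    return pd.DataFrame(checks)


# ---------------------------------------------------------------------------
# Full run


LOGISTIC_COVARIATES = ["age", "male", "length_of_stay", "hemiplegia",
                       "metastatic_malignancy", "dementia"]
COX_ADJUSTMENT = ["age", "male", "cci"]


def regression_design(cohort, summaries, rule: StratificationRule) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "age": [r.age for r in cohort],
            "male": [1.0 if r.sex == "male" else 0.0 for r in cohort],
            "length_of_stay": [r.length_of_stay for r in cohort],
            "hemiplegia": [float(r.comorbidities.get("hemiplegia", False)) for r in cohort],
            "metastatic_malignancy": [
                float(r.comorbidities.get("metastatic_malignancy", False)) for r in cohort
            ],
            "dementia": [float(r.comorbidities.get("dementia", False)) for r in cohort],
            "cci": summaries["cci"].to_numpy(dtype=float),
        }
    )
    df[f"{rule.variable}_high"] = rule.high(summaries[rule.variable]).astype(float)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; write artifacts and return them in-memory.

    Outputs (under ``config.out_dir``): included/excluded cohort CSVs,
    per-patient summaries, Table-1-style descriptive report, Table-2-style
    mortality report, per-rule logistic/Cox regression CSVs, survival-curve
    points, ML metrics JSON, reliance CSV, printed-table verification
    report, and a manifest with all seeds and the config hash.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    outputs: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc

        return _Ctx()

    with _stage("simulate"):
        if config.cohort_spec is not None:
            spec = dataclasses.replace(
                config.cohort_spec, seed=stage_seed(config.seed, "simulate")
            )
            cohort = generate_cohort(spec)
        else:
            cohort = read_cohort_csv(config.cohort_csv)

    with _stage("filter"):
        included, excluded = apply_inclusion_filters(cohort)
        write_cohort_csv(included, out_dir / "cohort_included.csv")
        outputs.append("cohort_included.csv")
        pd.DataFrame(
            [{"patient_id": r.patient_id, "reason": why} for r, why in excluded]
        ).to_csv(out_dir / "cohort_excluded.csv", index=False)
        outputs.append("cohort_excluded.csv")

    with _stage("indices"):
        summaries = summarize_cohort(included)
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        outputs.append("summaries.csv")

    with _stage("stratify"):
        died = summaries["died_30d"].to_numpy(dtype=bool)
        rules = []
        for var in ("in_sd", "in_cv", "est_pre_cv"):
            if config.cutoff_mode == "fixed":
                rules.append(StratificationRule(var, config.cutoffs[var]))
            else:
                roc = roc_curve(summaries[var].to_numpy(), died)
                rules.append(optimal_cutoff_closest_to_corner(roc, var))
        desc = descriptive_report(
            summaries.drop(columns=["patient_id", "pre_mean_glucose", "hirsch_ok",
                                    "n_measurements"])
        )
        desc.to_csv(out_dir / "table1_descriptive.csv", index=False)
        mort = mortality_table(summaries, rules)
        mort.to_csv(out_dir / "table2_mortality.csv", index=False)
        (out_dir / "table2_mortality.md").write_text(mort.to_markdown(index=False))
        outputs += ["table1_descriptive.csv", "table2_mortality.csv", "table2_mortality.md"]
        artifacts["rules"] = rules
        artifacts["mortality_table"] = mort
        artifacts["descriptive"] = desc

    with _stage("fit"):
        time = np.minimum(summaries["length_of_stay"].to_numpy(dtype=float), 30.0)
        regressions = {}
        curves_out = []
        for rule in rules:
            design = regression_design(included, summaries, rule)
            flag = f"{rule.variable}_high"
            logi = logistic_fit(design[["age", "male", flag] + LOGISTIC_COVARIATES[2:]],
                                died)
            logi.table.to_csv(out_dir / f"logistic_{rule.variable}.csv", index=False)
            outputs.append(f"logistic_{rule.variable}.csv")
            cox_design = design[COX_ADJUSTMENT + [flag]]
            cox = cox_fit(time, died, cox_design)
            cox.table.to_csv(out_dir / f"cox_{rule.variable}.csv", index=False)
            outputs.append(f"cox_{rule.variable}.csv")
            for cv in survival_curves(cox, time, died, cox_design, flag):
                for t, s in zip(cv.times, cv.survival):
                    curves_out.append(
                        {"rule": rule.variable, "stratum": cv.stratum,
                         "time": t, "survival": s}
                    )
            regressions[rule.variable] = {"logistic": logi, "cox": cox}
        pd.DataFrame(curves_out).to_csv(out_dir / "survival_curves.csv", index=False)
        outputs.append("survival_curves.csv")
        artifacts["regressions"] = regressions

    with _stage("ml"):
        table = ml_feature_table(included, summaries)
        ml = run_ml_arm(
            table,
            seed=config.seed,
            rounds=config.ml_rounds,
            use_fas=config.use_fas,
            use_smote=config.use_smote,
            run_baselines=config.run_baselines,
            reliance_repeats=config.reliance_repeats,
        )
        metrics = dataclasses.asdict(ml["metrics"])
        metrics_doc = {"AdaBoost-FAS" if config.use_fas else "AdaBoost": metrics}
        if "baselines" in ml:
            metrics_doc.update(
                {k: dataclasses.asdict(v) for k, v in ml["baselines"].items()}
            )
        (out_dir / "ml_metrics.json").write_text(json.dumps(metrics_doc, indent=2))
        ml["reliance"].to_csv(out_dir / "ml_reliance.csv", index=False)
        dump = [
            {"feature": ml["model"].feature_names[s.feature], "threshold": s.threshold,
             "polarity": s.polarity, "alpha": a}
            for s, a in zip(ml["model"].stumps, ml["model"].alphas)
        ]
        (out_dir / "ml_model.json").write_text(json.dumps(dump, indent=2))
        outputs += ["ml_metrics.json", "ml_reliance.csv", "ml_model.json"]
        artifacts["ml"] = ml

    with _stage("verify"):
        verification = verify_paper_tables()
        verification.to_csv(out_dir / "verification.csv", index=False)
        outputs.append("verification.csv")
        artifacts["verification"] = verification

    with _stage("manifest"):
        from . import __version__ as pkg_version

        config_json = json.dumps(config.to_json_dict(), sort_keys=True)
        manifest = {
            "package_version": pkg_version,
            "config": json.loads(config_json),
            "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_INDEX},
            "n_included": len(included),
            "n_excluded": len(excluded),
            "outputs": {
                name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
                for name in outputs
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        artifacts["manifest"] = manifest

    artifacts["cohort"] = included
    artifacts["summaries"] = summaries
    return artifacts
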