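"""ROC cutoff selection and univariate group comparisons.

The stratification logic mirrors the classical arm of the analysis: for each
glycemic index (in-hospital SD, in-hospital CV, estimated pre-hospital CV) a
ROC curve against 30-day death is built, the cutoff closest to the top-left
corner of the unit square is chosen, the cohort is split above/below it, and
the two strata are compared with Pearson chi-square for categorical
variables and Mann-Whitney / Welch t-tests for continuous ones (routed by a
Kolmogorov-Smirnov + Shapiro-Wilk normality screen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


class DegenerateInputError(ValueError):
    """Raised for single-class outcomes, zero-margin tables and the like."""


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered by strictly increasing threshold.

    Each point is ``(threshold, sensitivity, specificity)`` for the rule
    "score >= threshold predicts the positive outcome".  Thresholds are
    midpoints between adjacent distinct observed scores, bracketed by
    -inf (everything positive: sens 1, spec 0) and +inf (nothing positive:
    sens 0, spec 1).
    """

    points: tuple[tuple[float, float, float], ...]
    positive_label: object = True

    def auc(self) -> float:
        """Area under the curve by the trapezoid rule.

        Points are stored in increasing threshold order, i.e. decreasing
        false-positive rate; reversing them yields the staircase path from
        (0,0) to (1,1) without re-sorting (a value sort could shuffle the
        corners of zero-width vertical segments).
        """
        fpr = np.array([1.0 - sp for _, _, sp in self.points])[::-1]
        tpr = np.array([se for _, se, _ in self.points])[::-1]
        return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class StratificationRule:
    """A variable plus cutoff; values >= cutoff form the "high" stratum."""

    variable: str
    cutoff: float
    direction: str = ">="

    def high(self, values) -> np.ndarray:
        return np.asarray(values, dtype=float) >= self.cutoff


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): rows = strata, columns = died / survived."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DegenerateInputError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str  # mann_whitney | t_test | chi_square
    statistic: float
    p_value: float
    group_summaries: dict
    note: str = ""


def roc_curve(scores: Sequence[float], outcomes: Sequence[bool]) -> RocCurve:
    """ROC curve treating higher scores as higher risk of the positive outcome."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D and of equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("need at least one positive and one negative outcome")
    uniq = np.unique(s)
    thresholds = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf])
    )
    points = []
    for t in thresholds:
        pred = s >= t
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        points.append((float(t), sens, spec))
    return RocCurve(points=tuple(points))


def optimal_cutoff_closest_to_corner(
    roc: RocCurve, variable: str = "score"
) -> StratificationRule:
    """Finite threshold minimizing the distance to the (0, 1) ROC corner.

    Distance is ``sqrt((1-sens)^2 + (1-spec)^2)``; ties break toward the
    lower threshold (the more sensitive rule).  The two infinite endpoint
    thresholds never define a two-group split and are not candidates.
    """
    finite = [(t, se, sp) for t, se, sp in roc.points if math.isfinite(t)]
    if not finite:
        raise DegenerateInputError("no finite thresholds on the ROC curve")
    best_t, best_d = None, math.inf
    for t, se, sp in finite:  # increasing threshold order
        d = math.hypot(1.0 - se, 1.0 - sp)
        if d < best_d - 1e-15:
            best_t, best_d = t, d
    return StratificationRule(variable=variable, cutoff=best_t)


def pearson_chi2(table: ContingencyTable2x2, variable: str = "") -> UnivariateResult:
    """Pearson chi-square on a 2x2 table, df=1, without continuity correction."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    row_tot = arr.sum(axis=1)
    return UnivariateResult(
        variable=variable,
        test="chi_square",
        statistic=float(stat),
        p_value=float(p),
        group_summaries={
            "stratum_sizes": [int(v) for v in row_tot],
            "deaths": [int(table.a), int(table.c)],
            "death_pct": [
                round_half_up(100.0 * table.a / row_tot[0], 1) if row_tot[0] else None,
                round_half_up(100.0 * table.c / row_tot[1], 1) if row_tot[1] else None,
            ],
        },
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> UnivariateResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both groups have n <= 8 (and no ties force
    the normal approximation); otherwise the tie-corrected normal
    approximation.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return UnivariateResult(
        variable=variable,
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_summaries=_cont_summary(x, y),
        note=method,
    )


def welch_t(x: Sequence[float], y: Sequence[float], variable: str = "") -> UnivariateResult:
    """Welch two-sample t-test (Satterthwaite degrees of freedom), two-sided."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return UnivariateResult(variable, "t_test", 0.0, 1.0, _cont_summary(x, y))
        return UnivariateResult(
            variable, "t_test", math.inf, 0.0, _cont_summary(x, y), note="degenerate"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return UnivariateResult(
        variable=variable,
        test="t_test",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=_cont_summary(x, y),
    )


def _cont_summary(x, y) -> dict:
    return {
        "mean": [float(x.mean()), float(y.mean())],
        "sd": [
            float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        ],
        "n": [int(len(x)), int(len(y))],
    }


def normality_screen(x: Sequence[float], alpha: float = 0.05) -> str:
    """Route a continuous variable: ``"normal"`` or ``"non_normal"``.

    Rejects normality when either the Lilliefors (Kolmogorov-Smirnov with
    estimated parameters) or the Shapiro-Wilk test rejects at ``alpha``.
    A constant sample is non-normal by convention.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("normality screening needs n >= 3")
    if np.ptp(x) == 0.0:
        return "non_normal"
    _, p_sw = stats.shapiro(x)
    _, p_ks = lilliefors(x, dist="norm")
    return "non_normal" if (p_sw < alpha or p_ks < alpha) else "normal"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, matching the printed one-decimal percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def mortality_table(
    summaries: pd.DataFrame, rules: Sequence[StratificationRule]
) -> pd.DataFrame:
    """30-day mortality per stratum for each rule, with chi-square p-values.

    ``summaries`` must carry a boolean ``died_30d`` column plus each rule's
    variable.  Returns one overall row and two rows (low / high stratum) per
    rule with n, deaths, death percentage (one decimal, half-up) and the
    uncorrected Pearson chi-square p for the 2x2 stratum-by-outcome table;
    the p is omitted (NaN) when a stratum is empty.
    """
    died = summaries["died_30d"].astype(bool).to_numpy()
    rows = [
        {
            "rule": "overall",
            "stratum": "all",
            "n": len(summaries),
            "deaths": int(died.sum()),
            "death_pct": round_half_up(100.0 * died.mean(), 1) if len(summaries) else None,
            "p_value": np.nan,
        }
    ]
    for rule in rules:
        high = rule.high(summaries[rule.variable])
        parts = {"low": ~high, "high": high}
        counts = {k: (int(m.sum()), int(died[m].sum())) for k, m in parts.items()}
        if min(n for n, _ in counts.values()) == 0:
            p = np.nan
        else:
            tab = ContingencyTable2x2(
                a=counts["low"][1],
                b=counts["low"][0] - counts["low"][1],
                c=counts["high"][1],
                d=counts["high"][0] - counts["high"][1],
            )
            p = pearson_chi2(tab, variable=rule.variable).p_value
        for name in ("low", "high"):
            n, d = counts[name]
            rows.append(
                {
                    "rule": f"{rule.variable} {rule.direction} {rule.cutoff:g}",
                    "stratum": name,
                    "n": n,
                    "deaths": d,
                    "death_pct": round_half_up(100.0 * d / n, 1) if n else None,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
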