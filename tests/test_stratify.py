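"""ROC construction, corner cutoffs and univariate test wrappers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from glycostrat import (
    ContingencyTable2x2,
    StratificationRule,
    mann_whitney_u,
    mortality_table,
    normality_screen,
    optimal_cutoff_closest_to_corner,
    pearson_chi2,
    roc_curve,
    welch_t,
)
from glycostrat.stratify import DegenerateInputError, round_half_up


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
        assert roc.auc() == pytest.approx(1.0)
        assert len(roc.points) == 5  # 3 midpoints + two infinite endpoints

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1.0, 2.0], [True, True])

    def test_auc_equals_mann_whitney_concordance(self, rng):
        """Trapezoid AUC == U/(n1*n0), and matches the sklearn oracle."""
        for _ in range(10):
            scores = rng.normal(size=60)
            y = rng.random(60) < 0.4
            if y.all() or not y.any():
                continue
            roc = roc_curve(scores, y)
            u = stats.mannwhitneyu(scores[y], scores[~y], alternative="two-sided").statistic
            assert roc.auc() == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)
            assert roc.auc() == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_independent_scores_auc_near_half(self, rng):
        n = 10_000
        scores = rng.normal(size=n)
        y = rng.random(n) < 0.3
        # 3x the asymptotic SE of the AUC for uninformative scores
        n1, n0 = int(y.sum()), int((~y).sum())
        se = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(roc_curve(scores, y).auc() - 0.5) < 3 * se


class TestOptimalCutoff:
    def test_perfect_separator_attains_corner(self):
        roc = roc_curve([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
        rule = optimal_cutoff_closest_to_corner(roc)
        assert rule.cutoff == pytest.approx(2.5)

    def test_example_between_observed_values(self):
        roc = roc_curve(
            [10.0, 20.0, 30.0, 40.0, 50.0], [False, False, False, True, True]
        )
        rule = optimal_cutoff_closest_to_corner(roc)
        assert 30.0 < rule.cutoff < 40.0

    def test_brute_force_distance_oracle(self, rng):
        """Chosen threshold minimizes corner distance over all candidates."""
        for _ in range(20):
            scores = rng.normal(size=25)
            y = rng.random(25) < 0.5
            if y.all() or not y.any():
                continue
            roc = roc_curve(scores, y)
            rule = optimal_cutoff_closest_to_corner(roc)
            dists = {
                t: math.hypot(1 - se, 1 - sp)
                for t, se, sp in roc.points
                if math.isfinite(t)
            }
            assert dists[rule.cutoff] == pytest.approx(min(dists.values()), abs=1e-12)

    def test_tie_breaks_toward_lower_threshold(self):
        # thresholds 1.5 and 2.5 both at distance 0.5 from the corner
        roc = roc_curve([1.0, 2.0, 2.0, 3.0], [False, True, False, True])
        rule = optimal_cutoff_closest_to_corner(roc)
        assert rule.cutoff == pytest.approx(1.5)

    def test_invariant_under_monotone_transform(self, rng):
        """The selected stratum split is unchanged by exp() on the scores."""
        scores = rng.normal(size=40)
        y = rng.random(40) < 0.4
        if y.all() or not y.any():
            y[:2] = [True, False]
        r1 = optimal_cutoff_closest_to_corner(roc_curve(scores, y))
        r2 = optimal_cutoff_closest_to_corner(roc_curve(np.exp(scores), y))
        np.testing.assert_array_equal(scores >= r1.cutoff, np.exp(scores) >= r2.cutoff)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table,p",
        [
            ((4, 52, 13, 51), 0.039),   # estimated pre-hospital CV strata
            ((9, 8, 22, 81), 0.006),    # dementia, deceased vs survivors
            ((3, 14, 4, 99), 0.025),    # metastatic malignancy
        ],
    )
    def test_published_p_values(self, table, p):
        res = pearson_chi2(ContingencyTable2x2(*table))
        assert round(res.p_value, 3) == p

    def test_closed_form_identity(self, rng):
        """Pearson statistic equals N(ad-bc)^2 / product of margins."""
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            res = pearson_chi2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            n = a + b + c + d
            want = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(want, rel=1e-12)

    def test_null_table(self):
        res = pearson_chi2(ContingencyTable2x2(10, 30, 5, 15))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi2(ContingencyTable2x2(0, 5, 0, 7))


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(1.0, abs=0.02)

    def test_exact_small_sample_enumeration(self):
        """U=0 for fully shifted triples; p = 2*C(6,3)^-1*... = 0.1 exactly."""
        res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.note == "exact"
        # independent enumeration over all C(6,3) rank assignments
        pooled = [1, 2, 3, 4, 5, 6]
        u_obs = 0
        more_extreme = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for xi in xs for yi in ys if xi > yi)
            total += 1
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                more_extreme += 1
        assert more_extreme / total == pytest.approx(0.1)

    def test_power_on_large_shift(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1.5, 1, 200)
        assert mann_whitney_u(x, y).p_value < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_formula(self):
        """Statistic and Satterthwaite df recomputed from the raw formula."""
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 100.0])
        res = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_degenerate_zero_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        res = welch_t([2.0, 2.0], [3.0, 3.0])
        assert res.p_value == 0.0 and res.note == "degenerate"

    def test_equal_variance_limit_agrees_with_pooled_t(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0.1, 1, 2000)
        welch = welch_t(x, y)
        pooled = stats.ttest_ind(x, y, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, rel=1e-3)
        assert welch.p_value == pytest.approx(pooled.pvalue, rel=1e-2, abs=1e-4)


class TestNormalityScreen:
    def test_normal_sample_passes(self, rng):
        passes = sum(
            normality_screen(np.random.default_rng(s).normal(size=300)) == "normal"
            for s in range(20)
        )
        assert passes >= 18  # joint two-test type-I rate < 10%

    def test_exponential_sample_rejected(self, rng):
        assert normality_screen(rng.exponential(size=300)) == "non_normal"

    def test_constant_and_short_samples(self):
        assert normality_screen([5.0, 5.0, 5.0]) == "non_normal"
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])


class TestMortalityTable:
    def test_counts_and_percentages(self):
        df = pd.DataFrame(
            {
                "in_sd": np.r_[np.full(30, 30.0), np.full(30, 60.0)],
                "died_30d": np.r_[np.zeros(30), np.ones(15), np.zeros(15)].astype(bool),
            }
        )
        out = mortality_table(df, [StratificationRule("in_sd", 42.55)])
        overall = out[out["rule"] == "overall"].iloc[0]
        assert overall["deaths"] == 15
        low = out[(out["stratum"] == "low") & (out["rule"] != "overall")].iloc[0]
        high = out[out["stratum"] == "high"].iloc[0]
        assert low["death_pct"] == 0.0
        assert high["death_pct"] == 50.0  # 2x the overall 25%
        # stratum deaths always sum to total deaths
        assert low["deaths"] + high["deaths"] == overall["deaths"]

    def test_empty_stratum_flagged(self):
        df = pd.DataFrame(
            {"in_sd": [10.0, 20.0], "died_30d": [True, False]}
        )
        out = mortality_table(df, [StratificationRule("in_sd", 99.0)])
        assert np.isnan(out[out["stratum"] == "high"].iloc[0]["p_value"])

    def test_round_half_up_matches_printed_convention(self):
        assert round_half_up(7.45, 1) == 7.5
        assert round_half_up(100 * 13 / 64, 1) == 20.3
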