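"""SMOTE, FAS, LASSO selection, AdaBoost stumps and model reliance."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from glycostrat import (
    adaboost_train,
    apply_minmax,
    evaluate,
    fas_augment,
    fit_minmax,
    lasso_logistic_select,
    model_reliance,
    predict,
    smote,
    stratified_split,
)
from glycostrat.boosting import (
    AdaBoostModel,
    Stump,
    best_stump,
    compute_metrics,
    feature_table,
)


def make_table(X, died, kinds=None):
    return feature_table(pd.DataFrame(X), died, kinds)


def random_table(rng, n=40, p=3, death_rate=0.4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    died = rng.random(n) < death_rate
    if died.all() or not died.any():
        died[:2] = [True, False]
    return feature_table(X, died)


class TestStratifiedSplit:
    def test_published_class_sizes(self, rng):
        """103 survivors / 17 deceased split close to per-class 75/25."""
        died = np.r_[np.zeros(103, bool), np.ones(17, bool)]
        t = make_table({"x": rng.normal(size=120)}, died)
        train, test = stratified_split(t, 0.75, seed=0)
        assert int((~train.died).sum()) in (77, 78)
        assert int(train.died.sum()) in (12, 13)
        assert len(train.died) + len(test.died) == 120

    def test_divisible_case_exact(self, rng):
        died = np.r_[np.zeros(8, bool), np.ones(8, bool)]
        t = make_table({"x": rng.normal(size=16)}, died)
        train, test = stratified_split(t, 0.75, seed=1)
        assert int(train.died.sum()) == 6 and int((~train.died).sum()) == 6
        assert int(test.died.sum()) == 2 and int((~test.died).sum()) == 2

    def test_deterministic_given_seed(self, rng):
        t = random_table(rng, n=50)
        a1, b1 = stratified_split(t, seed=9)
        a2, b2 = stratified_split(t, seed=9)
        pd.testing.assert_frame_equal(a1.X, a2.X)
        np.testing.assert_array_equal(b1.died, b2.died)

    def test_singleton_class_rejected(self, rng):
        died = np.r_[np.zeros(10, bool), [True]]
        t = make_table({"x": rng.normal(size=11)}, died)
        with pytest.raises(ValueError, match="need >= 2"):
            stratified_split(t)


class TestMinMax:
    def test_affine_map_and_clipping(self):
        tr = make_table({"x": [10.0, 20.0, 30.0]}, [False, True, False],
                        kinds={"x": "continuous"})
        te = make_table({"x": [35.0, 5.0]}, [False, True], kinds={"x": "continuous"})
        params = fit_minmax(tr)
        np.testing.assert_allclose(
            apply_minmax(tr, params).X["x"], [0.0, 0.5, 1.0]
        )
        np.testing.assert_allclose(apply_minmax(te, params).X["x"], [1.0, 0.0])

    def test_constant_continuous_dropped_with_warning(self):
        tr = make_table(
            {"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 3.0]},
            [False, True, False],
            kinds={"x": "continuous", "y": "continuous"},
        )
        with pytest.warns(UserWarning, match="constant"):
            params = fit_minmax(tr)
        assert "x" not in params
        assert list(apply_minmax(tr, params).X.columns) == ["y"]

    def test_binary_passthrough(self):
        tr = make_table({"b": [0.0, 1.0, 1.0]}, [False, True, False])
        out = apply_minmax(tr, fit_minmax(tr))
        np.testing.assert_array_equal(out.X["b"], [0.0, 1.0, 1.0])


class TestSmote:
    def test_counts_balanced(self, rng):
        died = np.r_[np.zeros(90, bool), np.ones(10, bool)]
        t = make_table({"x": rng.random(100), "y": rng.random(100)}, died)
        out = smote(t, seed=0)
        assert int(out.died.sum()) == 90 and int((~out.died).sum()) == 90
        assert int(out.synthetic.sum()) == 80
        assert not out.synthetic[: len(t.died)].any()  # originals unflagged

    def test_coincident_minority_points(self):
        X = {"x": [0.1] * 2 + [0.5] * 8}
        died = np.r_[np.ones(2, bool), np.zeros(8, bool)]
        out = smote(make_table(X, died, kinds={"x": "continuous"}), seed=1)
        synth = out.X["x"].to_numpy()[out.synthetic]
        np.testing.assert_allclose(synth, 0.1)

    def test_synthetic_points_in_minority_convex_hull(self, rng):
        from scipy.spatial import Delaunay

        n_min = 12
        minority = rng.random((n_min, 2))
        majority = rng.random((60, 2)) + 2.0
        X = pd.DataFrame(np.vstack([minority, majority]), columns=["a", "b"])
        died = np.r_[np.ones(n_min, bool), np.zeros(60, bool)]
        t = feature_table(X, died, kinds={"a": "continuous", "b": "continuous"})
        out = smote(t, seed=2)
        hull = Delaunay(minority)
        synth = out.X[out.synthetic].to_numpy()
        assert (hull.find_simplex(synth - 1e-12) >= 0).all() or (
            hull.find_simplex(synth) >= 0
        ).all()

    def test_binary_features_rounded(self, rng):
        died = np.r_[np.ones(5, bool), np.zeros(20, bool)]
        t = make_table(
            {"b": (rng.random(25) < 0.5).astype(float)}, died, kinds={"b": "binary"}
        )
        out = smote(t, seed=3)
        assert set(np.unique(out.X["b"])) <= {0.0, 1.0}

    def test_tiny_minority_rejected(self, rng):
        died = np.r_[np.ones(1, bool), np.zeros(10, bool)]
        t = make_table({"x": rng.random(11)}, died)
        with pytest.raises(ValueError, match="minority"):
            smote(t)


class TestFasAugment:
    def test_combinatorial_feature_count(self, rng):
        p_cont, q_bin = 3, 4
        X = pd.DataFrame(
            np.hstack(
                [rng.random((20, p_cont)), (rng.random((20, q_bin)) < 0.5).astype(float)]
            ),
            columns=[f"c{i}" for i in range(p_cont)] + [f"b{i}" for i in range(q_bin)],
        )
        t = feature_table(X, rng.random(20) < 0.5)
        out = fas_augment(t)
        added = out.X.shape[1] - X.shape[1]
        assert added == p_cont + math.comb(p_cont + q_bin, 2)

    def test_smallest_case_names(self, rng):
        t = make_table(
            {"a": rng.random(10), "b": rng.random(10)},
            rng.random(10) < 0.5,
            kinds={"a": "continuous", "b": "continuous"},
        )
        out = fas_augment(t)
        assert set(out.X.columns) == {"a", "b", "a^2", "b^2", "a*b"}
        np.testing.assert_allclose(out.X["a^2"], out.X["a"] ** 2)

    def test_binary_product_is_logical_and(self, rng):
        a = (rng.random(30) < 0.5).astype(float)
        b = (rng.random(30) < 0.5).astype(float)
        t = make_table({"a": a, "b": b}, rng.random(30) < 0.5)
        out = fas_augment(t)
        np.testing.assert_array_equal(out.X["a*b"], np.logical_and(a, b).astype(float))
        assert out.kinds["a*b"] == "binary"
        assert out.parents["a*b"] == ("a", "b")


class TestLassoSelect:
    def test_full_shrinkage_fallback_single_feature(self, rng):
        t = random_table(rng, n=40, p=4)
        sel = lasso_logistic_select(t, lambda_grid=[1e6], cv_folds=2, seed=0)
        assert len(sel) == 1

    def test_signal_features_selected_noise_excluded(self, rng):
        n = 2000
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        noise = rng.normal(size=(n, 3))
        eta = 1.5 * x1 + 2.0 * x1 * x2
        died = rng.random(n) < 1 / (1 + np.exp(-eta))
        X = pd.DataFrame(
            {"x1": x1, "x2": x2, "n0": noise[:, 0], "n1": noise[:, 1], "n2": noise[:, 2]}
        )
        t = fas_augment(feature_table(X, died))
        sel = lasso_logistic_select(t, cv_folds=3, seed=1)
        assert "x1" in sel and "x1*x2" in sel
        assert not {"n0", "n1", "n2"} & set(sel)


def brute_force_best_stump(X, y_pm, w):
    """Independent exhaustive stump search (naive double loop), including
    the constant (both-leaves-same-class) stumps a depth-1 CART allows."""
    w = w / w.sum()
    w_pos = w[y_pm > 0].sum()
    if 1.0 - w_pos <= w_pos:
        best, best_err = (0, np.inf, 1), 1.0 - w_pos
    else:
        best, best_err = (0, np.inf, -1), w_pos
    for j in range(X.shape[1]):
        vals = np.sort(np.unique(X[:, j]))
        for t in (vals[:-1] + vals[1:]) / 2.0:
            for pol in (1, -1):
                pred = np.where(X[:, j] <= t, pol, -pol)
                err = w[pred != y_pm].sum()
                if err < best_err - 1e-12:
                    best, best_err = (j, t, pol), err
    return best, best_err


class TestAdaBoost:
    def test_separable_data_single_stump(self):
        t = make_table(
            {"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]},
            [True, True, True, False, False, False],
            kinds={"x": "continuous"},
        )
        model = adaboost_train(t, L_rounds=50)
        assert len(model.stumps) == 1
        assert (predict(model, t) == t.y_pm).all()

    def test_first_round_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n, p = int(rng.integers(8, 50)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, p))
            y_pm = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            if len(np.unique(y_pm)) < 2:
                continue
            w = rng.random(n) + 0.01
            stump, err = best_stump(X, y_pm, w)
            (j, t, pol), err_ref = brute_force_best_stump(X, y_pm, w)
            assert err == pytest.approx(err_ref, abs=1e-12)
            assert (stump.feature, stump.polarity) == (j, pol)
            assert stump.threshold == pytest.approx(t)

    def test_weighted_error_below_half_and_alpha_formula(self, rng):
        t = random_table(rng, n=80, p=4)
        model = adaboost_train(t, L_rounds=20)
        for alpha, eps in zip(model.alphas, model.train_errors):
            assert eps < 0.5
            if eps > 0:
                assert alpha == pytest.approx(0.5 * math.log((1 - eps) / eps))

    def test_exponential_loss_nonincreasing(self, rng):
        t = random_table(rng, n=60, p=3)
        model = adaboost_train(t, L_rounds=15)
        X = t.X.to_numpy()
        y = t.y_pm
        margins = np.zeros(len(y))
        losses = []
        for a, s in zip(model.alphas, model.stumps):
            margins += a * s.predict(X)
            losses.append(np.mean(np.exp(-y * margins)))
        assert all(b <= a + 1e-10 for a, b in zip(losses, losses[1:]))

    def test_ensemble_equation_fidelity(self, rng):
        """predict == sign(sum alpha*g), with margin 0 sent to survivors."""
        for _ in range(10):
            p = 4
            stumps = [
                Stump(int(rng.integers(0, p)), float(rng.normal()), int(rng.choice([-1, 1])))
                for _ in range(12)
            ]
            model = AdaBoostModel(
                stumps=stumps,
                alphas=list(rng.random(12)),
                feature_names=[f"f{i}" for i in range(p)],
            )
            X = rng.normal(size=(30, p))
            agg = sum(a * s.predict(X) for a, s in zip(model.alphas, model.stumps))
            want = np.where(agg < 0, -1.0, 1.0)
            np.testing.assert_array_equal(model.predict_pm(X), want)

    def test_xor_needs_interaction_features(self, rng):
        """Raw stumps plateau at chance on XOR; FAS products solve it."""
        a = np.repeat([0.0, 0.0, 1.0, 1.0], 10)
        b = np.tile([0.0, 1.0], 20)
        died = np.logical_xor(a, b)
        t = feature_table(pd.DataFrame({"a": a, "b": b}), died)
        raw_model = adaboost_train(t, L_rounds=50)
        raw_acc = float((predict(raw_model, t) == t.y_pm).mean())
        assert raw_acc == pytest.approx(0.5, abs=1e-12)
        t_fas = fas_augment(t)
        fas_model = adaboost_train(t_fas, L_rounds=50)
        fas_acc = float((predict(fas_model, t_fas) == t_fas.y_pm).mean())
        assert fas_acc == 1.0


class TestEvaluation:
    def test_majority_classifier_arithmetic(self):
        died = np.r_[np.ones(17, bool), np.zeros(103, bool)]
        m = compute_metrics(died, np.zeros(120, bool))
        assert m.accuracy == pytest.approx(103 / 120)
        assert m.sensitivity == 0.0 and m.specificity == 1.0
        assert m.balanced_accuracy == 0.5

    def test_balanced_accuracy_identity(self, rng):
        died = rng.random(200) < 0.3
        pred = rng.random(200) < 0.5
        m = compute_metrics(died, pred)
        assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)

    def test_perfect_classifier(self, rng):
        t = make_table(
            {"x": [0.0, 0.1, 0.9, 1.0]}, [True, True, False, False],
            kinds={"x": "continuous"},
        )
        model = adaboost_train(t, L_rounds=5)
        m = evaluate(model, t)
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1.0, 1.0, 1.0, 1.0)

    def test_synthetic_rows_never_evaluated(self, rng):
        died = np.r_[np.ones(4, bool), np.zeros(16, bool)]
        t = make_table({"x": rng.random(20)}, died)
        aug = smote(t, seed=0)
        model = adaboost_train(aug, L_rounds=5)
        with pytest.raises(ValueError, match="synthetic"):
            evaluate(model, aug)


class TestModelReliance:
    def test_unused_feature_reliance_one(self, rng):
        t = random_table(rng, n=60, p=3)
        model = AdaBoostModel(
            stumps=[Stump(0, 0.0, 1)], alphas=[1.0], feature_names=["f0", "f1", "f2"]
        )
        if float(np.mean(model.predict_pm(t) != t.y_pm)) == 0.0:
            pytest.skip("degenerate: zero baseline error")
        rep = model_reliance(model, t, "f2", n_repeats=50, seed=0)
        assert rep["reliance"] == pytest.approx(1.0, abs=1e-12)
        assert rep["se"] == pytest.approx(0.0, abs=1e-12)

    def test_sole_informative_feature_reliance_above_one(self, rng):
        n = 200
        x = rng.normal(size=n)
        died = x < 0.0
        died[:6] = ~died[:6]  # leave some baseline error
        t = make_table(
            {"x": x, "z": rng.normal(size=n)}, died,
            kinds={"x": "continuous", "z": "continuous"},
        )
        model = AdaBoostModel(stumps=[Stump(0, 0.0, -1)], alphas=[1.0],
                              feature_names=["x", "z"])
        rep = model_reliance(model, t, "x", n_repeats=100, seed=1)
        assert rep["reliance"] > 1.0

    def test_derived_features_recomputed_with_parent(self, rng):
        n = 100
        x = rng.random(n)
        died = x**2 > 0.5
        died[:4] = ~died[:4]
        t = fas_augment(
            make_table({"x": x, "z": rng.random(n)}, died,
                       kinds={"x": "continuous", "z": "continuous"})
        )
        model = adaboost_train(t, L_rounds=10, features=["x^2"])
        rep = model_reliance(model, t, "x", n_repeats=50, seed=2)
        assert rep["reliance"] > 1.0  # perturbing x must propagate into x^2

    def test_zero_baseline_error_reported_infinite(self, rng):
        t = make_table({"x": [0.0, 1.0, 0.0, 1.0]}, [True, False, True, False],
                       kinds={"x": "continuous"})
        model = adaboost_train(t, L_rounds=3)
        rep = model_reliance(model, t, "x", n_repeats=5, seed=0)
        assert math.isinf(rep["reliance"])

    def test_unknown_feature_rejected(self, rng):
        t = random_table(rng)
        model = adaboost_train(t, L_rounds=2)
        with pytest.raises(KeyError):
            model_reliance(model, t, "nope", n_repeats=2)
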