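"""AdaBoost-FAS: boosting over decision stumps with feature augmentation.

The classifier follows the printed ensemble rule

    G(x) = sign( sum_l alpha_l * g_l(x) )

where each weak learner g_l is a decision stump (one threshold on one
feature), alpha_l = 0.5 * ln((1 - eps_l) / eps_l) from the stump's weighted
training error, and the sign maps negative margins to the deceased class
(-1) and positive ones to survivors (+1).  Around the boosting core sit the
preprocessing stages of the ML arm: min-max scaling to [0, 1], a stratified
75/25 split, SMOTE oversampling of the deceased minority (training only),
FAS — squared terms for continuous features and products for every feature
pair, pruned by L1-penalized logistic regression — and a permutation
model-reliance analysis that measures how much the classification error
grows when one base feature is resampled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

DECEASED, SURVIVING = -1, 1


@dataclass
class FeatureTable:
    """Patient-by-feature matrix plus the metadata the ML arm needs.

    ``X`` holds the feature values; ``died`` is the boolean label vector
    (True = death within 30 days, encoded -1 inside the ensemble).  ``kinds``
    maps each feature to "continuous" or "binary"; ``provenance`` to "raw",
    "squared" or "interaction"; ``parents`` records the raw parents of each
    derived feature.  ``synthetic`` flags SMOTE-generated rows so they can
    be audited out of any evaluation.
    """

    X: pd.DataFrame
    died: np.ndarray
    kinds: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)
    parents: dict[str, tuple] = field(default_factory=dict)
    synthetic: np.ndarray = None
    scaling: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        self.died = np.asarray(self.died, dtype=bool)
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.died), dtype=bool)
        if len(self.X) != len(self.died):
            raise ValueError("X and label lengths differ")
        if len(set(self.X.columns)) != len(self.X.columns):
            raise ValueError("feature names must be unique")
        for name in self.X.columns:
            self.provenance.setdefault(name, "raw")

    @property
    def y_pm(self) -> np.ndarray:
        """Labels on the {-1 deceased, +1 surviving} encoding."""
        return np.where(self.died, DECEASED, SURVIVING).astype(float)

    def take(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X.iloc[idx].reset_index(drop=True),
            died=self.died[idx],
            kinds=dict(self.kinds),
            provenance=dict(self.provenance),
            parents=dict(self.parents),
            synthetic=self.synthetic[idx],
            scaling=self.scaling,
        )


def feature_table(
    features: pd.DataFrame, died: Sequence[bool], kinds: dict[str, str] | None = None
) -> FeatureTable:
    """Build a raw FeatureTable; kinds default to binary for {0,1} columns."""
    if kinds is None:
        kinds = {
            c: "binary" if set(np.unique(features[c])) <= {0.0, 1.0} else "continuous"
            for c in features.columns
        }
    return FeatureTable(X=features.astype(float).copy(), died=np.asarray(died), kinds=kinds)


def stratified_split(
    table: FeatureTable, train_fraction: float = 0.75, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class random split keeping ``train_fraction`` of each class."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in (False, True):
        members = np.flatnonzero(table.died == label)
        if len(members) < 2:
            raise ValueError(
                f"class died={label} has {len(members)} member(s); need >= 2 to split"
            )
        members = rng.permutation(members)
        k = int(round(train_fraction * len(members)))
        k = min(max(k, 1), len(members) - 1)  # both sides keep the class
        train_idx.extend(members[:k])
        test_idx.extend(members[k:])
    return table.take(sorted(train_idx)), table.take(sorted(test_idx))


def fit_minmax(train: FeatureTable) -> dict[str, tuple[float, float]]:
    """Per-feature (min, max) of the continuous training columns.

    Constant continuous columns carry no information at unit scale; they are
    excluded from the parameters (and dropped by :func:`apply_minmax`) with
    a warning.
    """
    params = {}
    for name in train.X.columns:
        if train.kinds.get(name) != "continuous":
            continue
        lo, hi = float(train.X[name].min()), float(train.X[name].max())
        if hi == lo:
            warnings.warn(f"dropping constant continuous feature {name!r}")
            continue
        params[name] = (lo, hi)
    return params


def apply_minmax(table: FeatureTable, params: dict[str, tuple[float, float]]) -> FeatureTable:
    """Scale continuous features to [0, 1] with train parameters, clipping.

    Binary features pass through; continuous features without parameters
    (constant on train) are dropped.
    """
    X = table.X.copy()
    drop = [
        c for c in X.columns if table.kinds.get(c) == "continuous" and c not in params
    ]
    X = X.drop(columns=drop)
    for name, (lo, hi) in params.items():
        if name in X.columns:
            X[name] = ((X[name] - lo) / (hi - lo)).clip(0.0, 1.0)
    out = FeatureTable(
        X=X,
        died=table.died,
        kinds={c: table.kinds[c] for c in X.columns},
        provenance={c: table.provenance.get(c, "raw") for c in X.columns},
        parents={c: p for c, p in table.parents.items() if c in X.columns},
        synthetic=table.synthetic.copy(),
        scaling=params,
    )
    return out


def smote(train: FeatureTable, k_neighbors: int = 5, seed: int = 0) -> FeatureTable:
    """Oversample the minority class to parity by neighbour interpolation.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of ``x``
    (Euclidean distance on the scaled features).  Binary features are set by
    rounding the interpolated value at 0.5.  Synthetic rows are flagged so
    they can never enter an evaluation set.
    """
    died = train.died
    n_pos, n_neg = int(died.sum()), int((~died).sum())
    if n_pos == n_neg:
        return train.take(np.arange(len(died)))
    minority_label = n_pos < n_neg
    minority = np.flatnonzero(died == minority_label)
    n_needed = abs(n_neg - n_pos)
    if len(minority) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = min(k_neighbors, len(minority) - 1)
    if k < k_neighbors:
        warnings.warn(f"SMOTE k reduced from {k_neighbors} to {k} (minority size)")
    rng = np.random.default_rng(seed)
    M = train.X.iloc[minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(M)
    _, neigh = nn.kneighbors(M)  # first neighbour is the point itself

    base = rng.integers(0, len(minority), size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    u = rng.random(n_needed)
    x = M[base]
    x_nn = M[neigh[base, pick]]
    synth = x + u[:, None] * (x_nn - x)
    binary_cols = [
        j for j, c in enumerate(train.X.columns) if train.kinds.get(c) == "binary"
    ]
    synth[:, binary_cols] = (synth[:, binary_cols] >= 0.5).astype(float)

    X_aug = pd.concat(
        [train.X, pd.DataFrame(synth, columns=train.X.columns)], ignore_index=True
    )
    return FeatureTable(
        X=X_aug,
        died=np.concatenate([died, np.full(n_needed, minority_label)]),
        kinds=dict(train.kinds),
        provenance=dict(train.provenance),
        parents=dict(train.parents),
        synthetic=np.concatenate([train.synthetic, np.ones(n_needed, dtype=bool)]),
        scaling=train.scaling,
    )


def _derived_value(X: pd.DataFrame, provenance: str, parents: tuple) -> pd.Series:
    if provenance == "squared":
        return X[parents[0]] ** 2
    return X[parents[0]] * X[parents[1]]


def fas_augment(table: FeatureTable) -> FeatureTable:
    """Add squared terms (continuous features) and all pairwise products.

    Squared features are named ``"X^2"``; interactions ``"Y*Z"`` with
    parents in sorted order.  Products of two binary flags are logical ANDs
    and stay binary; every other derived feature is continuous.
    """
    raw = [c for c in table.X.columns if table.provenance.get(c, "raw") == "raw"]
    kinds = dict(table.kinds)
    provenance = dict(table.provenance)
    parents = dict(table.parents)
    new_cols = {}
    for c in raw:
        if table.kinds.get(c) == "continuous":
            name = f"{c}^2"
            new_cols[name] = table.X[c] ** 2
            kinds[name] = "continuous"
            provenance[name] = "squared"
            parents[name] = (c,)
    for i, a in enumerate(raw):
        for b in raw[i + 1 :]:
            pa, pb = sorted((a, b))
            name = f"{pa}*{pb}"
            new_cols[name] = table.X[pa] * table.X[pb]
            kinds[name] = (
                "binary"
                if table.kinds.get(pa) == table.kinds.get(pb) == "binary"
                else "continuous"
            )
            provenance[name] = "interaction"
            parents[name] = (pa, pb)
    X = pd.concat([table.X, pd.DataFrame(new_cols)], axis=1)
    return FeatureTable(
        X=X,
        died=table.died.copy(),
        kinds=kinds,
        provenance=provenance,
        parents=parents,
        synthetic=table.synthetic.copy(),
        scaling=table.scaling,
    )


def recompute_derived(table: FeatureTable) -> FeatureTable:
    """Recompute every squared/interaction column from the raw columns."""
    X = table.X.copy()
    for name, prov in table.provenance.items():
        if prov != "raw" and name in X.columns:
            X[name] = _derived_value(X, prov, table.parents[name])
    return replace(table, X=X)


def lasso_logistic_select(
    train: FeatureTable,
    lambda_grid: Sequence[float] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    return_info: bool = False,
):
    """Feature names with nonzero L1-logistic coefficients at the CV-best lambda.

    The penalty strength is chosen by stratified ``cv_folds``-fold
    cross-validated log-loss over ``lambda_grid`` (default: 20 points,
    log-spaced over [1e-4, 10] per unit-scaled feature) with the
    one-standard-error rule: the sparsest lambda whose mean CV loss is
    within one SE of the minimum (the plain CV minimum notoriously drags
    pure-noise features along).  If the winning lambda shrinks everything
    to zero, the single largest-|coefficient| feature at the smallest
    lambda is returned so selection never comes back empty.
    """
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 1, 20)
    lambda_grid = sorted(float(l) for l in lambda_grid)
    y = train.died.astype(int)
    counts = np.bincount(y, minlength=2)
    folds = min(cv_folds, counts.min())
    if folds < 2:
        raise ValueError("need at least 2 members per class for cross-validation")
    Xm = train.X.to_numpy(dtype=float)
    n = len(y)

    def _fit(lam, X, yy):
        # random_state pins liblinear's internal coordinate shuffling;
        # without it repeated fits in one process can drift.
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (lam * len(yy)),
            solver="liblinear",
            max_iter=5000,
            random_state=seed,
        )
        clf.fit(X, yy)
        return clf

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_losses = np.zeros((folds, len(lambda_grid)))
    for k, (tr, va) in enumerate(skf.split(Xm, y)):
        for j, lam in enumerate(lambda_grid):
            clf = _fit(lam, Xm[tr], y[tr])
            p = np.clip(clf.predict_proba(Xm[va])[:, 1], 1e-12, 1 - 1e-12)
            fold_losses[k, j] = -np.mean(
                y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p)
            )
    mean_loss = fold_losses.mean(axis=0)
    j_min = int(np.argmin(mean_loss))
    se_min = fold_losses[:, j_min].std(ddof=1) / math.sqrt(folds)
    within = np.flatnonzero(mean_loss <= mean_loss[j_min] + se_min)
    best_lam = lambda_grid[int(within.max())]  # sparsest admissible lambda
    clf = _fit(best_lam, Xm, y)
    coefs = clf.coef_.ravel()
    selected = [c for c, b in zip(train.X.columns, coefs) if b != 0.0]
    if not selected:
        clf0 = _fit(lambda_grid[0], Xm, y)
        selected = [train.X.columns[int(np.argmax(np.abs(clf0.coef_.ravel())))]]
    if return_info:
        return selected, {
            "lambda": best_lam,
            "cv_logloss": dict(zip(lambda_grid, mean_loss)),
            "n_selected": len(selected),
        }
    return selected


# ---------------------------------------------------------------------------
# Discrete AdaBoost over decision stumps


@dataclass(frozen=True)
class Stump:
    """One-split weak learner: predicts ``polarity`` where value <= threshold.

    ``polarity`` is +1 or -1 on the {-1 deceased, +1 surviving} label
    encoding; values above the threshold get ``-polarity``.  Thresholds are
    midpoints between adjacent observed training values, with one special
    case: ``threshold = +inf`` is the constant ("bias") stump predicting
    ``polarity`` everywhere — the stump a depth-1 CART produces when both
    leaves share a majority class.  Without it the ensemble has no
    intercept and cannot represent class-prior offsets.
    """

    feature: int
    threshold: float
    polarity: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        below = X[:, self.feature] <= self.threshold
        return np.where(below, self.polarity, -self.polarity).astype(float)


@dataclass
class AdaBoostModel:
    """Weighted stump ensemble implementing G(x) = sign(sum alpha_l g_l(x)).

    Stump feature indices refer to positions in ``feature_names``; when a
    FeatureTable is passed for prediction, those columns are selected by
    name, so tables carrying extra (e.g. unselected raw) columns are fine.
    """

    stumps: list[Stump]
    alphas: list[float]
    feature_names: list[str]
    train_errors: list[float] = field(default_factory=list)

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, FeatureTable):
            return data.X[self.feature_names].to_numpy(dtype=float)
        if isinstance(data, pd.DataFrame):
            return data[self.feature_names].to_numpy(dtype=float)
        return np.asarray(data, dtype=float)

    def margin(self, data) -> np.ndarray:
        X = self._matrix(data)
        out = np.zeros(len(X))
        for a, s in zip(self.alphas, self.stumps):
            out += a * s.predict(X)
        return out

    def predict_pm(self, data) -> np.ndarray:
        """sign of the margin; ties (margin 0) go to the surviving class."""
        m = self.margin(data)
        return np.where(m < 0.0, DECEASED, SURVIVING).astype(float)


def best_stump(
    X: np.ndarray, y_pm: np.ndarray, weights: np.ndarray
) -> tuple[Stump, float]:
    """Exhaustive search for the minimum weighted-error stump.

    Candidates are every midpoint between adjacent distinct values of every
    feature, at both polarities, plus the two constant stumps.  Ties break
    toward the lower feature index, then the lower threshold, then polarity
    +1, for determinism; constants are considered first so a split must
    strictly beat the class prior.
    """
    w = weights / weights.sum()
    n, p = X.shape
    w_pos_tot = float(w[y_pm > 0].sum())
    # constant stumps: predict +1 (error = negative-class weight) or -1
    if 1.0 - w_pos_tot <= w_pos_tot:
        best, best_err = Stump(0, math.inf, 1), 1.0 - w_pos_tot
    else:
        best, best_err = Stump(0, math.inf, -1), w_pos_tot
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        is_pos = y_pm[order] > 0
        w_pos = np.where(is_pos, ws, 0.0).cumsum()
        w_neg = np.where(~is_pos, ws, 0.0).cumsum()
        tot_pos, tot_neg = w_pos[-1], w_neg[-1]
        splits = np.flatnonzero(xs[:-1] < xs[1:])
        for k in splits:
            t = (xs[k] + xs[k + 1]) / 2.0
            # polarity +1: predict +1 (surviving) when x <= t
            err_plus = w_neg[k] + (tot_pos - w_pos[k])
            for polarity, err in ((1, err_plus), (-1, 1.0 - err_plus)):
                if err < best_err - 1e-12:
                    best, best_err = Stump(j, float(t), polarity), float(err)
    return best, float(best_err)


_ALPHA_CAP = 0.5 * math.log((1.0 - 1e-10) / 1e-10)


def adaboost_train(
    train: FeatureTable,
    L_rounds: int = 100,
    features: Sequence[str] | None = None,
    verbose: bool = False,
) -> AdaBoostModel:
    """Discrete AdaBoost with exhaustive stump search.

    Each round reweights samples by ``exp(-alpha * y * g(x))`` and stops
    early on a perfect stump (weighted error 0; its alpha is capped) or when
    no stump beats chance (weighted error >= 0.5).  ``features`` restricts
    training to a named column subset (e.g. the LASSO-selected set).
    """
    names = list(features) if features is not None else list(train.X.columns)
    X = train.X[names].to_numpy(dtype=float)
    y = train.y_pm
    if len(np.unique(train.died)) < 2:
        raise ValueError("both classes must be present to boost")
    n = len(y)
    w = np.full(n, 1.0 / n)
    model = AdaBoostModel(stumps=[], alphas=[], feature_names=names)
    for _ in range(L_rounds):
        stump, eps = best_stump(X, y, w)
        if eps >= 0.5:
            break
        if eps <= 0.0:
            model.stumps.append(stump)
            model.alphas.append(_ALPHA_CAP)
            model.train_errors.append(0.0)
            if verbose:
                warnings.warn("perfect stump found; alpha capped, stopping early")
            break
        alpha = 0.5 * math.log((1.0 - eps) / eps)
        model.stumps.append(stump)
        model.alphas.append(alpha)
        model.train_errors.append(eps)
        w = w * np.exp(-alpha * y * stump.predict(X))
        w /= w.sum()
    return model


def predict(model: AdaBoostModel, table: FeatureTable) -> np.ndarray:
    """Hard {-1, +1} labels for every row of ``table``."""
    return model.predict_pm(table)


@dataclass(frozen=True)
class EvalMetrics:
    """Test metrics with the deceased class as the positive class."""

    accuracy: float
    balanced_accuracy: float
    sensitivity: float  # recall on deceased
    specificity: float  # recall on surviving
    auc: float | None
    confusion: dict  # tp, fn, tn, fp (positive = deceased)


def compute_metrics(
    died_true: np.ndarray, died_pred: np.ndarray, death_score: np.ndarray | None = None
) -> EvalMetrics:
    died_true = np.asarray(died_true, dtype=bool)
    died_pred = np.asarray(died_pred, dtype=bool)
    tp = int((died_true & died_pred).sum())
    fn = int((died_true & ~died_pred).sum())
    tn = int((~died_true & ~died_pred).sum())
    fp = int((~died_true & died_pred).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = None
    if death_score is not None and 0 < died_true.sum() < len(died_true):
        auc = float(roc_auc_score(died_true, death_score))
    return EvalMetrics(
        accuracy=(tp + tn) / len(died_true),
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )


def evaluate(model: AdaBoostModel, test: FeatureTable) -> EvalMetrics:
    """Metrics on the non-synthetic rows of ``test``.

    AUC is computed from the real-valued ensemble margin (negated, so a
    higher score means higher death risk), not from hard labels.
    """
    if test.synthetic.any():
        raise ValueError("synthetic SMOTE rows must never enter evaluation")
    margin = model.margin(test)
    died_pred = margin < 0.0
    return compute_metrics(test.died, died_pred, death_score=-margin)


def model_reliance(
    model: AdaBoostModel,
    test: FeatureTable,
    feature: str,
    n_repeats: int = 100,
    seed: int = 0,
) -> dict:
    """Error-ratio reliance of the model on one base feature.

    Each repeat resamples the feature's test column with replacement from
    its own values, recomputes every derived (squared/interaction) feature
    of that parent, and re-evaluates the classification error.  Reliance is
    the mean perturbed error divided by the baseline error; when the
    baseline error is zero the ratio is undefined and reported infinite.
    """
    if feature not in test.X.columns:
        raise KeyError(f"unknown feature {feature!r}")
    rng = np.random.default_rng(seed)
    baseline = float(np.mean(model.predict_pm(test) != test.y_pm))
    dependents = [
        name
        for name, prov in test.provenance.items()
        if prov != "raw" and feature in test.parents.get(name, ()) and name in test.X.columns
    ]
    errors = np.empty(n_repeats)
    for r in range(n_repeats):
        Xp = test.X.copy()
        Xp[feature] = rng.choice(Xp[feature].to_numpy(), size=len(Xp), replace=True)
        for name in dependents:
            Xp[name] = _derived_value(Xp, test.provenance[name], test.parents[name])
        errors[r] = np.mean(model.predict_pm(Xp) != test.y_pm)
    if baseline == 0.0:
        return {
            "feature": feature,
            "reliance": math.inf,
            "se": math.nan,
            "n_repeats": n_repeats,
            "baseline_error": 0.0,
        }
    rel = errors / baseline
    return {
        "feature": feature,
        "reliance": float(rel.mean()),
        "se": float(rel.std(ddof=1) / math.sqrt(n_repeats)) if n_repeats > 1 else math.nan,
        "n_repeats": n_repeats,
        "baseline_error": baseline,
    }


def baseline_models(
    train: FeatureTable,
    test: FeatureTable,
    train_fas: FeatureTable | None = None,
    test_fas: FeatureTable | None = None,
    L_rounds: int = 100,
    max_depth: int = 5,
    seed: int = 0,
) -> dict[str, EvalMetrics]:
    """Reference classifiers evaluated with the common metric set.

    Majority (always predicts survival — the majority class), DecTree (CART,
    Gini, depth-limited), AdaBoost without FAS, and — when the FAS tables
    are supplied — DecTree-FAS and LASSO-FAS (logistic regression on the
    LASSO-selected features, thresholded at 0.5).
    """
    out: dict[str, EvalMetrics] = {}
    died_te = test.died
    out["Majority"] = compute_metrics(
        died_te, np.zeros(len(died_te), dtype=bool), death_score=np.zeros(len(died_te))
    )

    def _tree(tr: FeatureTable, te: FeatureTable) -> EvalMetrics:
        clf = DecisionTreeClassifier(
            criterion="gini", max_depth=max_depth, random_state=seed
        )
        clf.fit(tr.X, tr.died.astype(int))
        score = clf.predict_proba(te.X)[:, 1]
        return compute_metrics(te.died, clf.predict(te.X).astype(bool), score)

    out["DecTree"] = _tree(train, test)
    out["AdaBoost"] = evaluate(adaboost_train(train, L_rounds=L_rounds), test)

    if train_fas is not None and test_fas is not None:
        out["DecTree-FAS"] = _tree(train_fas, test_fas)
        selected = lasso_logistic_select(train_fas, seed=seed)
        clf = LogisticRegression(C=np.inf, max_iter=5000)
        clf.fit(train_fas.X[selected], train_fas.died.astype(int))
        score = clf.predict_proba(test_fas.X[selected])[:, 1]
        out["LASSO-FAS"] = compute_metrics(test_fas.died, score >= 0.5, score)
    return out
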