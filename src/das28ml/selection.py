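"""Supervised distillation of the most informative DAS28-CRP items.

The pipeline mirrors a strict train/validate discipline for small cohorts:

1. A class-proportional holdout split reserves one third of the cases for
   validation; the remaining two thirds ("pool") carry feature selection and
   classifier training.
2. Random forests are tuned by seeded random search over a documented grid,
   scored by stratified 5-fold balanced accuracy.
3. Permutation importance (mean score drop over 50 column shuffles, scored
   by balanced accuracy) ranks the items, and a computed ABC (cABC)
   analysis cuts the ranking into the "important few" (set A), an
   intermediate set B and the "trivial many" (set C).
4. Nested Monte-Carlo cross-validation (4 outer x 25 inner = 100 runs)
   resamples the pool, re-tunes and retrains per run, and scores balanced
   accuracy and ROC-AUC on fresh random 80% subsamples of the untouched
   validation third.  Training with per-column permuted features provides an
   overfitting control expected to perform at the 50% guessing level.

Random forests, stratified splitting, permutation importance and both
performance scores come from scikit-learn; the cABC construction and the
nested Monte-Carlo harness are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

__all__ = [
    "ABCPartition",
    "CVScheme",
    "ImportanceTable",
    "PerformanceDistribution",
    "balanced_accuracy",
    "cabc",
    "cluster_membership_importance",
    "nested_cv_evaluate",
    "permutation_importance",
    "roc_auc",
    "split_holdout",
    "tune_and_train",
]


class SelectionError(ValueError):
    """Invalid input to a supervised-analysis operation."""


@dataclass(frozen=True)
class CVScheme:
    """Nested Monte-Carlo cross-validation scheme.

    ``outer_repeats * inner_repeats`` runs in total (default 4 x 25 = 100).
    Each run retrains on a stratified ``pool_subsample`` fraction of the
    2/3 training/test pool and scores on a stratified
    ``validation_subsample`` fraction of the 1/3 holdout.  ``tuning_budget``
    counts random-search draws, each scored by ``tuning_folds``-fold
    cross-validated balanced accuracy.
    """

    holdout_fraction: float = 1 / 3
    outer_repeats: int = 4
    inner_repeats: int = 25
    pool_subsample: float = 0.8
    validation_subsample: float = 0.8
    tuning_budget: int = 50
    tuning_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("holdout_fraction", "pool_subsample", "validation_subsample"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise SelectionError(f"{name} must be in (0, 1), got {v}")
        if self.outer_repeats < 1 or self.inner_repeats < 1:
            raise SelectionError("repeats must be >= 1")
        if self.tuning_budget < 1 or self.tuning_folds < 2:
            raise SelectionError("tuning_budget >= 1 and tuning_folds >= 2 required")

    @property
    def n_runs(self) -> int:
        return self.outer_repeats * self.inner_repeats


@dataclass
class ImportanceTable:
    """Per-feature mean permutation importance and its dispersion."""

    table: pd.DataFrame  # columns: feature, mean_importance, sd
    n_repeats: int

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("mean_importance", ascending=False).reset_index(
            drop=True
        )

    def top_feature(self) -> str:
        return str(self.ranked().iloc[0]["feature"])


@dataclass
class ABCPartition:
    """Computed ABC categorization of positive item values."""

    a: list[str]
    b: list[str]
    c: list[str]
    curve: np.ndarray  # (n+1, 2): cumulative item fraction, cumulative value fraction
    ab_boundary: int  # items in A
    bc_boundary: int  # items in A + B

    def sets(self) -> dict[str, list[str]]:
        return {"A": self.a, "B": self.b, "C": self.c}


@dataclass
class PerformanceDistribution:
    """Per-run balanced accuracy and ROC-AUC with medians and 95% intervals."""

    balanced_accuracy: np.ndarray
    roc_auc: np.ndarray

    def summary(self) -> dict[str, float]:
        ba, auc = self.balanced_accuracy, self.roc_auc
        return {
            "balanced_accuracy_median": float(np.median(ba)),
            "balanced_accuracy_q025": float(np.percentile(ba, 2.5)),
            "balanced_accuracy_q975": float(np.percentile(ba, 97.5)),
            "roc_auc_median": float(np.median(auc)),
            "roc_auc_q025": float(np.percentile(auc, 2.5)),
            "roc_auc_q975": float(np.percentile(auc, 97.5)),
            "n_runs": int(ba.size),
        }


# ---------------------------------------------------------------------------
# scores


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise SelectionError("empty input")
    if y_true.shape != y_pred.shape:
        raise SelectionError("y_true and y_pred must have the same length")
    return float(balanced_accuracy_score(y_true, y_pred))


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve (Mann-Whitney normalization; ties count 1/2)."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise SelectionError("roc_auc needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# splitting and tuning


def split_holdout(X: pd.DataFrame, y: np.ndarray, scheme: CVScheme):
    """Class-proportional split into a 2/3 pool and a 1/3 validation set.

    Returns ``(X_pool, y_pool, X_val, y_val)``; deterministic given
    ``scheme.seed``.
    """
    scheme.validate()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise SelectionError("holdout split needs both classes present")
    X_pool, X_val, y_pool, y_val = train_test_split(
        X,
        y,
        test_size=scheme.holdout_fraction,
        stratify=y,
        random_state=scheme.seed % (2**32),
    )
    return X_pool, y_pool, X_val, y_val


#: Random-search grid for the random-forest hyperparameters.
RF_GRID: dict[str, list] = {
    "n_estimators": [50, 100, 200],
    "max_depth": [None, 2, 4, 8],
    "max_features": ["sqrt", 0.25, 0.5],
    "min_samples_leaf": [1, 2, 5],
}


def tune_and_train(
    X, y, scheme: CVScheme, grid: dict[str, list] | None = None
) -> RandomForestClassifier:
    """Seeded random search over ``RF_GRID``, scored by k-fold balanced accuracy.

    The best configuration is refit on all of ``X``.  Deterministic given
    ``scheme.seed``.
    """
    scheme.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise SelectionError("tune_and_train needs >= 2 classes")
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[1] == 0:
        raise SelectionError("X must be n x d with one row per label and d >= 1")
    grid = grid or RF_GRID
    rng = np.random.default_rng(scheme.seed)
    keys = sorted(grid)
    min_class = np.bincount(pd.factorize(y)[0]).min()
    n_folds = min(scheme.tuning_folds, max(int(min_class), 2))
    best_score, best_params = -np.inf, None
    for _ in range(scheme.tuning_budget):
        params = {k: grid[k][rng.integers(len(grid[k]))] for k in keys}
        clf = RandomForestClassifier(random_state=scheme.seed % (2**32), **params)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=scheme.seed % (2**32))
        score = cross_val_score(clf, X, y, cv=cv, scoring="balanced_accuracy").mean()
        if score > best_score:
            best_score, best_params = score, params
    best = RandomForestClassifier(random_state=scheme.seed % (2**32), **best_params)
    best.fit(X, y)
    return best


def permutation_importance(
    classifier, X, y, feature_names=None, n_repeats: int = 50, seed: int = 0
) -> ImportanceTable:
    """Mean drop in balanced accuracy over ``n_repeats`` shuffles per feature."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    res = _sk_permutation_importance(
        classifier,
        X,
        np.asarray(y),
        scoring="balanced_accuracy",
        n_repeats=n_repeats,
        random_state=seed % (2**32),
    )
    table = pd.DataFrame(
        {
            "feature": list(feature_names),
            "mean_importance": res.importances_mean,
            "sd": res.importances_std,
        }
    )
    return ImportanceTable(table=table, n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# computed ABC analysis


def cabc(values, names=None) -> ABCPartition:
    """Computed ABC analysis: split positive values into sets A, B and C.

    Items are sorted in decreasing order and the ABC curve (cumulative item
    fraction vs cumulative value fraction) is built.  The A|B boundary is
    the curve point closest to the ideal (0, 1); the B|C boundary is the
    first point after which the chord slope drops below parity (a further
    item adds less than an equal share).  Negative values are clipped to 0
    with a warning; an all-nonpositive input is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise SelectionError("cabc needs a nonempty 1-D array of values")
    if names is None:
        names = [f"item{i}" for i in range(v.size)]
    names = list(names)
    if len(names) != v.size:
        raise SelectionError("names must match values in length")
    if np.any(v < 0):
        warnings.warn("negative values clipped to 0 for cABC", stacklevel=2)
        v = np.clip(v, 0.0, None)
    if v.sum() <= 0:
        raise SelectionError("cabc needs at least one strictly positive value")
    order = np.argsort(-v, kind="stable")
    sorted_v = v[order]
    n = v.size
    frac_items = np.arange(n + 1) / n
    frac_value = np.concatenate([[0.0], np.cumsum(sorted_v)]) / sorted_v.sum()
    curve = np.column_stack([frac_items, frac_value])

    interior = np.arange(1, n + 1)
    dist2 = frac_items[interior] ** 2 + (1.0 - frac_value[interior]) ** 2
    ab = int(interior[np.argmin(dist2)])

    slopes = np.diff(frac_value) / np.diff(frac_items)  # chord slope per item
    below = np.flatnonzero(slopes < 1.0 - 1e-12)
    bc = int(below[0] + 1) if below.size else n

    ab, bc = min(ab, bc), max(ab, bc)
    ordered_names = [names[i] for i in order]
    return ABCPartition(
        a=ordered_names[:ab],
        b=ordered_names[ab:bc],
        c=ordered_names[bc:],
        curve=curve,
        ab_boundary=ab,
        bc_boundary=bc,
    )


# ---------------------------------------------------------------------------
# nested Monte-Carlo cross-validation


def _stratified_subsample(rng: np.random.Generator, y: np.ndarray, fraction: float):
    """Indices of a class-proportional subsample (>= 1 case per class)."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(int(round(fraction * members.size)), 1)
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def nested_cv_evaluate(
    X_pool,
    y_pool,
    X_val,
    y_val,
    scheme: CVScheme,
    feature_subset=None,
    permute_features: bool = False,
) -> PerformanceDistribution:
    """Nested Monte-Carlo cross-validated performance on the holdout.

    Runs ``scheme.n_runs`` times: resample the pool (stratified
    ``pool_subsample``), re-tune and train a random forest, then score
    balanced accuracy and ROC-AUC on a fresh stratified
    ``validation_subsample`` of the untouched holdout.  With
    ``permute_features`` each feature column of the training data is
    independently shuffled before fitting (overfitting control; expected to
    score at the 50% guessing level).
    """
    scheme.validate()
    X_pool = pd.DataFrame(X_pool)
    X_val = pd.DataFrame(X_val)
    y_pool = np.asarray(y_pool)
    y_val = np.asarray(y_val)
    if np.unique(y_val).size < 2:
        raise SelectionError("validation set must contain both classes")
    if feature_subset is not None:
        X_pool = X_pool[list(feature_subset)]
        X_val = X_val[list(feature_subset)]
    Xp = X_pool.to_numpy(dtype=float)
    Xv = X_val.to_numpy(dtype=float)
    bas, aucs = [], []
    for run in range(scheme.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, run]))
        run_seed = int(rng.integers(2**31))
        sub = _stratified_subsample(rng, y_pool, scheme.pool_subsample)
        X_train, y_train = Xp[sub], y_pool[sub]
        if permute_features:
            X_train = X_train.copy()
            for j in range(X_train.shape[1]):
                rng.shuffle(X_train[:, j])
        run_scheme = CVScheme(
            holdout_fraction=scheme.holdout_fraction,
            outer_repeats=scheme.outer_repeats,
            inner_repeats=scheme.inner_repeats,
            pool_subsample=scheme.pool_subsample,
            validation_subsample=scheme.validation_subsample,
            tuning_budget=scheme.tuning_budget,
            tuning_folds=scheme.tuning_folds,
            seed=run_seed,
        )
        clf = tune_and_train(X_train, y_train, run_scheme)
        vsub = _stratified_subsample(rng, y_val, scheme.validation_subsample)
        y_v = y_val[vsub]
        pred = clf.predict(Xv[vsub])
        bas.append(balanced_accuracy(y_v, pred))
        proba = clf.predict_proba(Xv[vsub])[:, -1]
        aucs.append(roc_auc(y_v, proba))
    return PerformanceDistribution(
        balanced_accuracy=np.array(bas), roc_auc=np.array(aucs)
    )


def cluster_membership_importance(
    components: pd.DataFrame,
    cluster_labels: np.ndarray,
    scheme: CVScheme,
    importance_repeats: int = 50,
) -> dict[int, dict]:
    """One-vs-rest feature attribution for each (equalized) cluster.

    For every cluster id: label the rows cluster-vs-rest on the d = 4
    components, reserve a class-proportional holdout, tune and train a
    random forest on the pool, compute permutation importance, and evaluate
    the single most important feature in nested Monte-Carlo CV.  Returns a
    mapping ``cluster_id -> {"importance", "top_feature", "performance"}``.
    """
    scheme.validate()
    X = pd.DataFrame(components).reset_index(drop=True)
    labels = np.asarray(cluster_labels)
    results: dict[int, dict] = {}
    for cluster_id in sorted(np.unique(labels)):
        y = (labels == cluster_id).astype(int)
        # both sides need enough members to stratify the holdout and folds
        if min(y.sum(), (1 - y).sum()) < 6:
            warnings.warn(
                f"cluster {cluster_id}: one-vs-rest task too small, skipped", stacklevel=2
            )
            continue
        X_pool, y_pool, X_val, y_val = split_holdout(X, y, scheme)
        clf = tune_and_train(X_pool, y_pool, scheme)
        imp = permutation_importance(
            clf,
            X_pool,
            y_pool,
            feature_names=X.columns,
            n_repeats=importance_repeats,
            seed=scheme.seed,
        )
        top = imp.top_feature()
        perf = nested_cv_evaluate(
            X_pool, y_pool, X_val, y_val, scheme, feature_subset=[top]
        )
        results[int(cluster_id)] = {
            "importance": imp,
            "top_feature": top,
            "performance": perf,
        }
    return results
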