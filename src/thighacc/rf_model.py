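"""Feature selection and Random-Forest intensity classification.

Two selection stages precede the forest, mirroring common practice in
accelerometry feature pipelines:

1. *Correlation pruning*: while any feature pair has |r| > 0.75, drop the
   member of the worst-offending pair with the larger mean absolute
   correlation to all remaining features.
2. *Shadow-feature relevance* (a Boruta-style wrapper): every feature is
   duplicated as a row-permuted "shadow"; a forest is trained on the
   joint table and a feature scores a hit when its importance exceeds
   the best shadow importance.  Over the iterations, a two-sided
   binomial test at alpha = 0.05 confirms features that hit
   significantly more often than chance and rejects those that hit
   significantly less often; undecided ("tentative") features are
   resolved at the end by comparing their median importance with the
   median best-shadow importance.

The classifier itself is a 100-tree Random Forest with the original
Breiman defaults (sqrt(p) candidate features per split, unlimited depth,
bootstrap sample of size n).  Ties in the majority vote break toward the
earlier class in the canonical order (Sedentary, Standing, LIPA, MVPA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from . import CLASSES

__all__ = [
    "FeatureSelection",
    "ForestModel",
    "prune_correlated",
    "shadow_select",
    "train_forest",
    "predict_forest",
]


@dataclass
class FeatureSelection:
    """Outcome of the two-stage feature-selection procedure."""

    pruned_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    confirmed_features: list[str] = field(default_factory=list)
    iterations: int = 0


@dataclass
class ForestModel:
    """A trained Random Forest with its feature schema and OOB error curve."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    class_labels: list[str]
    oob_error_curve: np.ndarray
    seed: int
    n_trees: int = 100


def _correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    # Pearson; correlations involving a constant column are defined as 0
    corr = table.corr(method="pearson")
    return corr.fillna(0.0)


def prune_correlated(
    features: pd.DataFrame, r_threshold: float = 0.75
) -> FeatureSelection:
    """Greedily drop features until no pair has |r| above the threshold.

    Of the most-correlated offending pair, the member with the larger
    mean absolute correlation to all remaining features is removed; the
    procedure is deterministic.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 feature columns")
    table = features.astype(float)
    removed: list[tuple[str, str, float]] = []
    corr = _correlation_matrix(table).abs()
    np.fill_diagonal(corr.values, 0.0)
    while True:
        max_r = corr.values.max()
        if max_r <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        drop, keep = (a, b) if corr[a].mean() >= corr[b].mean() else (b, a)
        removed.append((keep, drop, float(max_r)))
        corr = corr.drop(index=drop, columns=drop)
    kept = [c for c in table.columns if c not in {d for _, d, _ in removed}]
    return FeatureSelection(pruned_pairs=removed, confirmed_features=kept)


def shadow_select(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    seed: int = 0,
    alpha: float = 0.05,
    max_iter: int = 100,
    n_trees: int = 50,
) -> FeatureSelection:
    """Confirm relevant features against permuted shadow copies.

    Returns the confirmed feature set; reproducible for a fixed seed.
    """
    y = np.asarray(labels)
    if features.shape[0] != y.shape[0]:
        raise ValueError("labels not aligned with feature rows")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes for supervised selection")
    rng = np.random.default_rng(seed)
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    names = list(features.columns)

    undecided = np.ones(p, dtype=bool)
    confirmed = np.zeros(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    importance_history: list[np.ndarray] = []
    shadow_history: list[float] = []
    iteration = 0

    while undecided.any() and iteration < max_iter:
        iteration += 1
        shadows = X.copy()
        for col in range(p):
            rng.shuffle(shadows[:, col])
        joint = np.hstack([X, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(joint, y)
        imp = forest.feature_importances_
        real_imp, shadow_max = imp[:p], float(imp[p:].max())
        importance_history.append(real_imp)
        shadow_history.append(shadow_max)
        hits += (real_imp > shadow_max).astype(int)

        # two-sided binomial test against chance hitting (p = 0.5)
        for col in np.where(undecided)[0]:
            res = binomtest(int(hits[col]), iteration, 0.5)
            if res.pvalue < alpha:
                if hits[col] > iteration / 2:
                    confirmed[col] = True
                undecided[col] = False

    # resolve tentative features by median-importance comparison
    if undecided.any() and importance_history:
        med_imp = np.median(np.vstack(importance_history), axis=0)
        med_shadow = float(np.median(shadow_history))
        confirmed |= undecided & (med_imp > med_shadow)

    return FeatureSelection(
        confirmed_features=[names[i] for i in np.where(confirmed)[0]],
        iterations=iteration,
    )


def train_forest(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_trees: int = 100,
    seed: int = 0,
) -> ForestModel:
    """Train the 100-tree Random Forest and record its OOB error curve.

    The out-of-bag error is evaluated cumulatively after each tree by
    majority vote over the trees for which a sample was out of bag.
    """
    y = np.asarray(labels)
    if features.shape[0] != y.shape[0]:
        raise ValueError(
            f"{features.shape[0]} feature rows vs {len(y)} labels"
        )
    present = [c for c in CLASSES if c in set(y)]
    if len(present) < 2:
        raise ValueError("need at least 2 classes to train")
    X = features.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(X, y)
    oob_curve = _oob_error_curve(forest, X, y)
    return ForestModel(
        estimator=forest,
        feature_names=list(features.columns),
        class_labels=present,
        oob_error_curve=oob_curve,
        seed=seed,
        n_trees=n_trees,
    )


def _oob_error_curve(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Cumulative out-of-bag error after each tree (NaN until any sample votes)."""
    from sklearn.ensemble._forest import _generate_unsampled_indices

    n = X.shape[0]
    ms = forest.max_samples
    if ms is None:
        n_boot = n
    elif isinstance(ms, float):
        n_boot = max(1, round(n * ms))
    else:
        n_boot = int(ms)
    votes = np.zeros((n, len(forest.classes_)))
    errors = np.empty(len(forest.estimators_))
    y_idx = np.searchsorted(forest.classes_, y)
    for t, tree in enumerate(forest.estimators_):
        try:
            oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        except TypeError:  # older sklearn without the sample_weight argument
            oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot)
        # sub-trees are trained on the encoded labels: they predict indices
        # into forest.classes_
        pred_idx = tree.predict(X[oob_idx]).astype(int)
        votes[oob_idx, pred_idx] += 1
        voted = votes.sum(axis=1) > 0
        errors[t] = (
            float(np.mean(np.argmax(votes[voted], axis=1) != y_idx[voted]))
            if voted.any()
            else np.nan
        )
    return errors


def predict_forest(model: ForestModel, features: pd.DataFrame) -> np.ndarray:
    """Predict one intensity class per row; ties break by canonical class order."""
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if features.shape[0] == 0:
        return np.array([], dtype=object)
    X = features[model.feature_names].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    # reorder columns into canonical order so argmax ties break deterministically
    order = [list(model.estimator.classes_).index(c) for c in CLASSES
             if c in model.estimator.classes_]
    canon = [c for c in CLASSES if c in model.estimator.classes_]
    picked = np.argmax(proba[:, order], axis=1)
    return np.array([canon[i] for i in picked], dtype=object)
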