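"""Balanced random forest for rare-outcome classification.

Each tree trains on a balanced bootstrap: the bootstrap has a fixed
case:non-case composition (default 1:4), achieved by random undersampling of
the majority class — a per-tree majority pool is drawn without replacement,
then the bootstrap samples with replacement from cases and from that pool.
Tree induction itself is standard CART (Gini, no depth limit) via
scikit-learn; each tree also sees only a random subset of the features
(default 50%).  The ensemble's case probability is the mean over trees.

Unlike naive-Bayes scoring, trees condition on feature combinations, so the
ensemble can exploit interactions — e.g. between coded (structured) and
note-derived (unstructured) features — that additive odds-ratio scores
cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cohort import FeatureMatrix
from .metrics import roc_auc


@dataclass
class BrfcConfig:
    n_trees: int = 30
    feature_fraction: float = 0.5
    bootstrap_size: int | None = None  # defaults to the training n
    case_to_noncase_ratio: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must lie in (0, 1]")
        rc, rn = self.case_to_noncase_ratio
        if rc <= 0 or rn <= 0:
            raise ValueError("ratio parts must be positive integers")
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, tree_index)))


def balanced_bootstrap_sample(
    labels: np.ndarray, config: BrfcConfig, tree_index: int
) -> np.ndarray:
    """Indices of one balanced bootstrap with exact case:non-case composition.

    Cases are drawn with replacement from all cases; non-cases with
    replacement from a per-tree undersampled majority pool.  The case count
    is ``round(size * rc / (rc + rn))``.
    """
    labels = np.asarray(labels)
    case_idx = np.flatnonzero(labels == 1)
    noncase_idx = np.flatnonzero(labels == 0)
    if len(case_idx) == 0:
        raise ValueError("training data has no cases")
    rc, rn = config.case_to_noncase_ratio
    size = config.bootstrap_size or len(labels)
    if size < rc + rn:
        raise ValueError(f"bootstrap size {size} too small for ratio {rc}:{rn}")
    n_case = int(round(size * rc / (rc + rn)))
    n_noncase = size - n_case
    rng = _tree_rng(config.seed, tree_index)
    # undersampled majority pool, sized to the ratio against available cases
    pool_size = min(len(noncase_idx), max(1, int(round(len(case_idx) * rn / rc))))
    pool = rng.choice(noncase_idx, size=pool_size, replace=False)
    return np.concatenate(
        [
            rng.choice(case_idx, size=n_case, replace=True),
            rng.choice(pool, size=n_noncase, replace=True),
        ]
    )


class BalancedRandomForest:
    """Ensemble of CART trees on balanced bootstraps and feature subsets."""

    def __init__(self, config: BrfcConfig | None = None):
        self.config = config or BrfcConfig()
        self._trees: list[tuple[DecisionTreeClassifier, np.ndarray]] = []

    def fit(self, X, y) -> "BalancedRandomForest":
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
        p = X.shape[1]
        n_feat = math.ceil(self.config.feature_fraction * p)
        self._trees = []
        for t in range(self.config.n_trees):
            rng = _tree_rng(self.config.seed, t)
            cols = np.sort(rng.choice(p, size=n_feat, replace=False))
            rows = balanced_bootstrap_sample(y, self.config, t)
            if len(np.unique(y[rows])) < 2:
                raise ValueError("degenerate single-class bootstrap")
            tree = DecisionTreeClassifier(
                criterion="gini",
                random_state=int(rng.integers(2**31 - 1)),
            )
            Xt = X[rows][:, cols]
            tree.fit(Xt.toarray() if sp.issparse(Xt) else Xt, y[rows])
            self._trees.append((tree, cols))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Mean over trees of the per-tree case probability."""
        if not self._trees:
            raise RuntimeError("forest is not fitted")
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
        total = np.zeros(X.shape[0])
        for tree, cols in self._trees:
            Xt = X[:, cols]
            proba = tree.predict_proba(Xt.toarray() if sp.issparse(Xt) else Xt)
            case_col = list(tree.classes_).index(1) if 1 in tree.classes_ else None
            total += proba[:, case_col] if case_col is not None else 0.0
        return total / len(self._trees)


def fit_balanced_forest(
    train: FeatureMatrix, config: BrfcConfig | None = None
) -> BalancedRandomForest:
    return BalancedRandomForest(config).fit(train.counts, train.labels)


def grid_search_brfc(
    X,
    y,
    grid: list[BrfcConfig],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[BrfcConfig, list[float]]:
    """Pick the configuration with the best mean cross-validated AUC."""
    y = np.asarray(y)
    X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mean_aucs = []
    for config in grid:
        aucs = []
        for train_idx, val_idx in cv.split(X, y):
            model = BalancedRandomForest(config).fit(X[train_idx], y[train_idx])
            aucs.append(roc_auc(model.predict_proba(X[val_idx]), y[val_idx]))
        mean_aucs.append(float(np.mean(aucs)))
    return grid[int(np.argmax(mean_aucs))], mean_aucs


def run_feature_set_comparison(
    train: FeatureMatrix,
    test: FeatureMatrix,
    config: BrfcConfig | None = None,
    alpha: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Fit NBC and the balanced forest on unstructured / structured / both.

    Returns ``{(model, feature_set): EvalReport}`` plus the raw test scores
    under ``("scores", model, feature_set)`` for downstream paired
    comparisons.
    """
    from .cohort import UNSTRUCTURED
    from .metrics import evaluate_scores
    from .nbc import fit_nbc, score_matrix

    config = config or BrfcConfig()
    masks = {
        "unstructured": np.asarray(train.kinds) == UNSTRUCTURED,
        "structured": np.asarray(train.kinds) != UNSTRUCTURED,
        "both": np.ones(len(train.feature_ids), dtype=bool),
    }
    out: dict = {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"feature subset {name!r} is empty")
        tr = train.select_features(mask)
        te = test.select_features(mask)
        nbc = fit_nbc(tr, alpha=alpha)
        nbc_scores = score_matrix(nbc, te)
        forest = fit_balanced_forest(tr, config)
        rf_scores = forest.predict_proba(te.counts)
        out[("nbc", name)] = evaluate_scores(
            nbc_scores, te.labels, n_boot=n_boot, seed=seed
        )
        out[("brfc", name)] = evaluate_scores(
            rf_scores, te.labels, n_boot=n_boot, seed=seed
        )
        out[("scores", "nbc", name)] = nbc_scores
        out[("scores", "brfc", name)] = rf_scores
    return out
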