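"""Naive-Bayes risk scoring from case/non-case prevalence odds.

Each feature gets an additive risk score equal to the smoothed log odds
ratio of its first-occurrence prevalence between cases and non-cases:

    score(f) = log[ ((k1 + a) / (n1 - k1 + a)) / ((k0 + a) / (n0 - k0 + a)) ]

with pseudocount ``a`` (default 0.5, the Haldane–Anscombe correction) so the
score stays finite at k = 0 and k = n.  A patient's cumulative risk is the
sum of the scores of every (feature, visit) occurrence in their history, so
a predictor recorded at several visits counts several times.  Conditional
independence of features is assumed throughout — interactions contribute
nothing to this score, which is exactly what makes the model a useful
baseline against interaction-capturing ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import FeatureMatrix


@dataclass
class NbcModel:
    feature_ids: list[str]
    scores: np.ndarray  # natural-log odds-ratio risk score per feature
    k_case: np.ndarray
    k_noncase: np.ndarray
    smoothing: float
    n_case: int
    n_noncase: int

    def __post_init__(self) -> None:
        self._col = {f: j for j, f in enumerate(self.feature_ids)}

    def score_of(self, feature_id: str) -> float:
        return float(self.scores[self._col[feature_id]])


def fit_nbc(train: FeatureMatrix, alpha: float = 0.5) -> NbcModel:
    """Fit per-feature risk scores on first-occurrence prevalence.

    Prevalence is computed on the binary (subject-level first occurrence)
    view; per-visit multiplicity only enters at scoring time.
    """
    if alpha <= 0:
        raise ValueError("smoothing pseudocount must be positive")
    y = np.asarray(train.labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("training data must contain both cases and non-cases")
    binary = train.binary
    k1 = np.asarray(binary[y == 1].sum(axis=0)).ravel().astype(float)
    k0 = np.asarray(binary[y == 0].sum(axis=0)).ravel().astype(float)
    scores = np.log(
        ((k1 + alpha) / (n1 - k1 + alpha)) / ((k0 + alpha) / (n0 - k0 + alpha))
    )
    return NbcModel(
        feature_ids=list(train.feature_ids),
        scores=scores,
        k_case=k1,
        k_noncase=k0,
        smoothing=alpha,
        n_case=n1,
        n_noncase=n0,
    )


def score_patient(model: NbcModel, occurrences: dict[str, int]) -> float:
    """Cumulative risk of one patient from their (feature -> visit count) map.

    Unknown features contribute zero.
    """
    total = 0.0
    for fid, mult in occurrences.items():
        j = model._col.get(fid)
        if j is not None:
            total += model.scores[j] * mult
    return total


def score_matrix(model: NbcModel, matrix: FeatureMatrix) -> np.ndarray:
    """Vectorised cumulative risk for every subject in ``matrix``.

    Features of the matrix absent from the model contribute zero; model
    features absent from the matrix are ignored.
    """
    w = np.zeros(len(matrix.feature_ids))
    for j, fid in enumerate(matrix.feature_ids):
        k = model._col.get(fid)
        if k is not None:
            w[j] = model.scores[k]
    return np.asarray(matrix.counts @ w).ravel()


def top_features(model: NbcModel, k: int = 200) -> list[str]:
    """The k features with the largest |score|, ties broken lexicographically."""
    if k > len(model.feature_ids):
        warnings.warn(
            f"k={k} exceeds the {len(model.feature_ids)}-feature universe; "
            "returning the full ranking",
            stacklevel=2,
        )
        k = len(model.feature_ids)
    order = sorted(
        range(len(model.feature_ids)),
        key=lambda j: (-abs(model.scores[j]), model.feature_ids[j]),
    )
    return [model.feature_ids[j] for j in order[:k]]
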