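"""ROC/AUC, operating-point metrics at fixed specificity, and percentile
bootstrap confidence intervals and paired AUC comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

SPEC_LEVELS = (0.99, 0.95, 0.90, 0.80)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability P(score_case > score_noncase) plus
    half the probability of a tie.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def metrics_at_specificity(
    scores, labels, spec_levels=SPEC_LEVELS
) -> pd.DataFrame:
    """PPV and sensitivity at score cuts meeting each specificity level.

    For each level the threshold is the smallest score cut whose specificity
    is at least the level (classification rule: positive iff score >= cut);
    rows where even the strictest cut cannot reach the level are flagged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    neg = np.sort(scores[labels == 0])
    pos = scores[labels == 1]
    cuts = np.unique(scores)
    # specificity at cut t: fraction of non-cases with score < t
    spec = np.searchsorted(neg, cuts, side="left") / len(neg)
    rows = []
    for level in spec_levels:
        ok = np.flatnonzero(spec >= level)
        if len(ok) == 0:
            rows.append((level, np.nan, np.nan, np.nan, False))
            continue
        t = cuts[ok[0]]
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        ppv = tp / (tp + fp) if tp + fp else np.nan
        sens = tp / len(pos)
        rows.append((level, t, ppv, sens, True))
    return pd.DataFrame(
        rows, columns=["specificity", "threshold", "ppv", "sensitivity", "attained"]
    )


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile-bootstrap 95% CI for the AUC.

    Subjects are resampled with replacement; single-class resamples are
    redrawn.  Returns (point estimate, lower, upper).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    point = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
        stats[b] = roc_auc(scores[idx], labels[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, float(lo), float(hi)


def compare_auc(
    scores_m1, scores_m2, labels, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Paired percentile bootstrap test of the AUC difference of two models.

    Both score vectors must be defined on the same subjects; each resample
    reuses the same subject indices for both models, so the sampling
    variation of the difference is the paired one.  Returns
    ``(delta_auc, two_sided_p)`` where p = 2 * min(frac <= 0, frac >= 0),
    capped at 1 (resamples exactly at zero count toward both tails).
    """
    s1 = np.asarray(scores_m1, dtype=float)
    s2 = np.asarray(scores_m2, dtype=float)
    labels = np.asarray(labels)
    if len(s1) != len(s2) or len(s1) != len(labels):
        raise ValueError("paired comparison requires scores on identical subjects")
    delta = roc_auc(s1, labels) - roc_auc(s2, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
        deltas[b] = roc_auc(s1[idx], labels[idx]) - roc_auc(s2[idx], labels[idx])
    p = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return float(delta), float(min(p, 1.0))


@dataclass
class EvalReport:
    """AUC with percentile-bootstrap CI and the fixed-specificity rows."""

    auc: float
    auc_ci: tuple[float, float]
    at_specificity: pd.DataFrame
    comparisons: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.at_specificity.copy()
        df["auc"] = self.auc
        return df


def evaluate_scores(
    scores, labels, n_boot: int = 1000, seed: int = 0
) -> EvalReport:
    auc, lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return EvalReport(
        auc=auc, auc_ci=(lo, hi), at_specificity=metrics_at_specificity(scores, labels)
    )
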