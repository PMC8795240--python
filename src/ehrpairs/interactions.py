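"""Stratified contingency analysis of structured-unstructured feature pairs.

For a structured feature A and an NLP-derived (unstructured) feature B, two
2x2 first-occurrence tables are built — one in an equal-size case cohort,
one in a non-case cohort.  Four statistics summarise each pair:

* **Chi-squared screen** — the Pearson independence statistic
  T = sum (O - E)^2 / E over the four cells of each stratum's table (1 df),
  flagging pairs whose joint occurrence departs from within-cohort
  independence;
* **Interaction heterogeneity (IH)** — Woolf's homogeneity-of-odds-ratios
  statistic across the two strata,

      IH = sum_i w_i (log OR_i - mean log OR)^2,
      w_i = (1/a_i + 1/b_i + 1/c_i + 1/d_i)^{-1},

  chi-squared with k - 1 = 1 df under equal odds ratios.  Large IH means
  the A-B association itself differs by outcome status — the quantity an
  additive (naive-Bayes) risk score cannot see but an interaction-capturing
  model can exploit;
* **Joint risk** — log10 of the ratio of expected joint counts
  E[a] = (a+c)(a+b)/n between strata, a marginal-association summary to
  contrast with IH;
* **Posterior risk** — P(outcome | A=1, B=1) via Bayes' rule, with the case
  stratum's cells rescaled (default 1/100) to undo the equal-cohort
  sampling and restore the ~1/99 population case:non-case ratio.

Log-odds-ratios use natural log (the Woolf weight formula presumes it);
joint risk uses log10.  Zero cells in a stratum are handled by adding a
Haldane-Anscombe 0.5 to all four of that stratum's cells before the Woolf
computation; the rescaling never touches T or IH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .cohort import STRUCTURED, UNSTRUCTURED, FeatureMatrix
from .nbc import NbcModel, top_features

CASE, NONCASE = "case", "noncase"
POSITIVE_MENTION_SUFFIXES = ("|positive", "|FH")


@dataclass
class StratifiedPair:
    """A feature pair's 2x2 first-occurrence tables in both cohorts.

    Each stratum's table is ``(a, b, c, d)`` = (A&B, A&~B, ~A&B, ~A&~B).
    """

    structured_feature_id: str
    unstructured_feature_id: str
    case: tuple[int, int, int, int]
    noncase: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for cells in (self.case, self.noncase):
            if any(x < 0 for x in cells):
                raise ValueError("cell counts must be nonnegative")

    @classmethod
    def from_margins(
        cls,
        structured_feature_id: str,
        unstructured_feature_id: str,
        case: tuple[int, int, int],
        noncase: tuple[int, int, int],
        n: int,
    ) -> "StratifiedPair":
        """Reconstruct cells from per-stratum margins ``(|A|, |B|, a)`` at
        common cohort size ``n`` — the form in which published pair tables
        usually report them."""

        def cells(n_a, n_b, a):
            b, c, d = n_a - a, n_b - a, n - n_a - n_b + a
            return (a, b, c, d)

        return cls(
            structured_feature_id,
            unstructured_feature_id,
            cells(*case),
            cells(*noncase),
        )

    def cells(self, stratum: str) -> tuple[int, int, int, int]:
        if stratum == CASE:
            return self.case
        if stratum == NONCASE:
            return self.noncase
        raise ValueError(f"unknown stratum {stratum!r}")

    def n(self, stratum: str) -> int:
        return int(sum(self.cells(stratum)))


# ---------------------------------------------------------------------------
# array-level statistics (broadcastable; the per-pair ops wrap these)

def _expected_joint(a, b, c, d):
    n = a + b + c + d
    return (a + c) * (a + b) / n


def _pearson_T(a, b, c, d):
    """Pearson chi-squared over the four cells with margin-based expecteds.

    Returns nan where any expected cell is zero (degenerate margins).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0),
            (a - r1 * c1 / n) ** 2 / (r1 * c1 / n)
            + (b - r1 * c2 / n) ** 2 / (r1 * c2 / n)
            + (c - r2 * c1 / n) ** 2 / (r2 * c1 / n)
            + (d - r2 * c2 / n) ** 2 / (r2 * c2 / n),
            np.nan,
        )
    return t


def _log_or_and_weight(a, b, c, d, zero_cell_correction=0.5):
    """Per-stratum log OR and Woolf inverse-variance weight.

    Where any cell is zero, the correction is added to all four cells of
    that stratum.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    corr = np.where(zero, zero_cell_correction, 0.0)
    a, b, c, d = a + corr, b + corr, c + corr, d + corr
    log_or = np.log(a * d / (b * c))
    w = 1.0 / (1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return log_or, w


def _woolf_ih(case_cells, noncase_cells, zero_cell_correction=0.5):
    l1, w1 = _log_or_and_weight(*case_cells, zero_cell_correction)
    l0, w0 = _log_or_and_weight(*noncase_cells, zero_cell_correction)
    mean = (w1 * l1 + w0 * l0) / (w1 + w0)
    ih = w1 * (l1 - mean) ** 2 + w0 * (l0 - mean) ** 2
    return ih, l1, l0, w1, w0


# ---------------------------------------------------------------------------
# per-pair operations

def expected_count(pair: StratifiedPair, stratum: str) -> float:
    """E[a] = (a+c)(a+b)/n, the joint count expected under independence."""
    cells = pair.cells(stratum)
    if sum(cells) == 0:
        raise ValueError(f"{stratum} stratum is empty")
    return float(_expected_joint(*cells))


def pearson_chi2(pair: StratifiedPair, stratum: str) -> tuple[float, float]:
    """Pearson independence test of one stratum's table; 1 df."""
    t = _pearson_T(*pair.cells(stratum))
    if np.isnan(t):
        raise ValueError(
            f"{stratum} stratum has a zero margin; expected cell counts "
            "degenerate"
        )
    return float(t), float(chi2_dist.sf(t, df=1))


def woolf_ih(
    pair: StratifiedPair, zero_cell_correction: float = 0.5
) -> tuple[float, float]:
    """Interaction heterogeneity: Woolf's test across the two strata; 1 df."""
    if pair.n(CASE) == 0 or pair.n(NONCASE) == 0:
        raise ValueError("both strata must be non-empty")
    ih, *_ = _woolf_ih(pair.case, pair.noncase, zero_cell_correction)
    ih = float(ih)
    return ih, float(chi2_dist.sf(ih, df=1))


def joint_risk(pair: StratifiedPair) -> float:
    """log10 ratio of expected joint counts, case over non-case cohort."""
    e1 = expected_count(pair, CASE)
    e0 = expected_count(pair, NONCASE)
    if e0 == 0:
        raise ValueError("expected joint count is zero in the non-case stratum")
    return float(np.log10(e1 / e0))


def posterior_risk(pair: StratifiedPair, case_scale: float = 1 / 100) -> float:
    """P(outcome | A=1, B=1) with case cells rescaled by ``case_scale``.

    Computed through the full Bayes chain
    P(A|Y,B) * P(Y|B) / P(A|B) and checked against its algebraic
    simplification a1 / (a1 + a0); the two must agree to 1e-12.
    """
    a1, b1, _, _ = (x * case_scale for x in pair.case)
    a0, b0, _, _ = pair.noncase
    if a1 + b1 + a0 + b0 == 0:
        raise ValueError("no subject has feature A in either stratum")
    if a1 + a0 == 0:
        raise ValueError("no subject has both A and B in either stratum")
    p_a_given_yb = a1 / (a1 + b1)
    p_y_given_b = (a1 + b1) / (a0 + b0 + a1 + b1)
    p_a_given_b = (a1 + a0) / (a1 + b1 + a0 + b0)
    chain = p_a_given_yb * p_y_given_b / p_a_given_b
    simplified = a1 / (a1 + a0)
    if abs(chain - simplified) > 1e-12:
        raise AssertionError("Bayes chain and simplified posterior disagree")
    return float(simplified)


def pair_stats(pair: StratifiedPair, case_scale: float = 1 / 100) -> dict:
    """All statistics of one pair, as a plain dict."""
    t1, p1 = pearson_chi2(pair, CASE)
    t0, p0 = pearson_chi2(pair, NONCASE)
    ih, ih_p = woolf_ih(pair)
    l1, w1 = _log_or_and_weight(*pair.case)
    l0, w0 = _log_or_and_weight(*pair.noncase)
    return {
        "A": pair.structured_feature_id,
        "B": pair.unstructured_feature_id,
        "E_case": expected_count(pair, CASE),
        "E_noncase": expected_count(pair, NONCASE),
        "T_case": t1,
        "p_case": p1,
        "T_noncase": t0,
        "p_noncase": p0,
        "log_or_case": float(l1),
        "log_or_noncase": float(l0),
        "w_case": float(w1),
        "w_noncase": float(w0),
        "ih": ih,
        "ih_p": ih_p,
        "joint_risk": joint_risk(pair),
        "posterior": posterior_risk(pair, case_scale),
    }


# ---------------------------------------------------------------------------
# cohort sampling and pair construction from matrices

def sample_equal_cohorts(
    matrix: FeatureMatrix, cohort_size: int | None = None, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Two equal-size, label-pure, without-replacement cohorts.

    ``cohort_size`` defaults to min(#cases, #non-cases).
    """
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(matrix.labels == 1)
    noncase_idx = np.flatnonzero(matrix.labels == 0)
    size = cohort_size or min(len(case_idx), len(noncase_idx))
    if size > min(len(case_idx), len(noncase_idx)):
        raise ValueError(
            f"cohort_size {size} exceeds available; maximum "
            f"{min(len(case_idx), len(noncase_idx))}"
        )
    cases = np.sort(rng.choice(case_idx, size=size, replace=False))
    noncases = np.sort(rng.choice(noncase_idx, size=size, replace=False))
    return matrix.subset_subjects(cases), matrix.subset_subjects(noncases)


def build_contingency(
    case_matrix: FeatureMatrix,
    noncase_matrix: FeatureMatrix,
    structured_feature_id: str,
    unstructured_feature_id: str,
) -> StratifiedPair:
    """2x2 first-occurrence tables of (A, B) in both cohorts."""
    ja = case_matrix.column_index(structured_feature_id)
    jb = case_matrix.column_index(unstructured_feature_id)
    if case_matrix.kinds[ja] != STRUCTURED:
        raise ValueError(f"{structured_feature_id!r} is not a structured feature")
    if case_matrix.kinds[jb] != UNSTRUCTURED:
        raise ValueError(
            f"{unstructured_feature_id!r} is not an unstructured feature"
        )

    def cells(m: FeatureMatrix) -> tuple[int, int, int, int]:
        binary = m.binary
        xa = np.asarray(binary[:, m.column_index(structured_feature_id)].todense()).ravel() > 0
        xb = np.asarray(binary[:, m.column_index(unstructured_feature_id)].todense()).ravel() > 0
        a = int((xa & xb).sum())
        b = int((xa & ~xb).sum())
        c = int((~xa & xb).sum())
        d = int((~xa & ~xb).sum())
        return (a, b, c, d)

    return StratifiedPair(
        structured_feature_id,
        unstructured_feature_id,
        cells(case_matrix),
        cells(noncase_matrix),
    )


def select_pairs(
    case_matrix: FeatureMatrix,
    noncase_matrix: FeatureMatrix,
    model: NbcModel,
    top_k: int | None = 200,
    alpha_chi2: float | None = 0.05,
    alpha_ih: float | None = 0.05,
    min_joint: int = 10,
    mention_suffixes: tuple[str, ...] = POSITIVE_MENTION_SUFFIXES,
    case_scale: float = 1 / 100,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen the structured x unstructured pair universe.

    Filters, in order: the mention-type filter on B (keep only affirmative
    mentions — positive and family-history by default), membership of both A
    and B in the top-``top_k`` features by |NBC risk score| (ranked after
    the mention filter), chi-squared significance in *both* strata at
    ``alpha_chi2``, IH significance at ``alpha_ih``, and at least
    ``min_joint`` joint occurrences in either stratum.  Any threshold can be
    disabled by passing None (or 0 for ``min_joint``).

    Returns the surviving pairs, sorted by (IH desc, joint risk desc, A, B)
    and annotated with every pair statistic, plus a per-filter survival
    count.
    """
    kinds = np.asarray(case_matrix.kinds)
    feature_ids = np.asarray(case_matrix.feature_ids, dtype=object)
    struct_cols = np.flatnonzero(kinds == STRUCTURED)
    unstruct_cols = np.flatnonzero(kinds == UNSTRUCTURED)
    survival: dict[str, int] = {
        "universe": len(struct_cols) * len(unstruct_cols)
    }

    # 1. mention-type filter on the unstructured side
    keep_b = np.array(
        [
            any(str(feature_ids[j]).endswith(s) for s in mention_suffixes)
            for j in unstruct_cols
        ]
    )
    unstruct_cols = unstruct_cols[keep_b]
    survival["mention"] = len(struct_cols) * len(unstruct_cols)

    # 2. top-k by |NBC score| within the mention-filtered universe
    if top_k is not None:
        eligible = set(feature_ids[struct_cols]) | set(feature_ids[unstruct_cols])
        sub_ids = [f for f in model.feature_ids if f in eligible]
        sub_scores = np.array([model.score_of(f) for f in sub_ids])
        order = sorted(
            range(len(sub_ids)), key=lambda j: (-abs(sub_scores[j]), sub_ids[j])
        )
        top = set(sub_ids[j] for j in order[: min(top_k, len(sub_ids))])
        struct_cols = np.array(
            [j for j in struct_cols if feature_ids[j] in top], dtype=int
        )
        unstruct_cols = np.array(
            [j for j in unstruct_cols if feature_ids[j] in top], dtype=int
        )
    survival["top_k"] = len(struct_cols) * len(unstruct_cols)

    if len(struct_cols) == 0 or len(unstruct_cols) == 0:
        return pd.DataFrame(), survival

    # vectorised cell counts for every surviving pair, per stratum
    def stratum_cells(m: FeatureMatrix):
        binary = m.binary
        xa = binary[:, struct_cols]
        xb = binary[:, unstruct_cols]
        a = np.asarray((xa.T @ xb).todense(), dtype=float)
        n_a = np.asarray(xa.sum(axis=0), dtype=float).reshape(-1, 1)
        n_b = np.asarray(xb.sum(axis=0), dtype=float).reshape(1, -1)
        n = m.n_subjects
        return a, n_a - a, n_b - a, n - n_a - n_b + a

    cells1 = stratum_cells(case_matrix)
    cells0 = stratum_cells(noncase_matrix)

    t1 = _pearson_T(*cells1)
    t0 = _pearson_T(*cells0)
    p1 = chi2_dist.sf(t1, df=1)
    p0 = chi2_dist.sf(t0, df=1)
    ih, l1, l0, w1, w0 = _woolf_ih(cells1, cells0)
    ih_p = chi2_dist.sf(ih, df=1)
    e1 = _expected_joint(*cells1)
    e0 = _expected_joint(*cells0)
    with np.errstate(divide="ignore", invalid="ignore"):
        jr = np.log10(e1 / e0)
        a1s = cells1[0] * case_scale
        post = a1s / (a1s + cells0[0])

    keep = np.ones_like(ih, dtype=bool)
    if alpha_chi2 is not None:
        keep &= np.nan_to_num(p1, nan=1.0) < alpha_chi2
        keep &= np.nan_to_num(p0, nan=1.0) < alpha_chi2
    survival["chi2"] = int(keep.sum())
    if alpha_ih is not None:
        keep &= ih_p < alpha_ih
    survival["ih"] = int(keep.sum())
    if min_joint:
        keep &= (cells1[0] >= min_joint) | (cells0[0] >= min_joint)
    survival["min_joint"] = int(keep.sum())

    ia, ib = np.nonzero(keep)
    score_of = {f: model.score_of(f) for f in model.feature_ids}
    rows = pd.DataFrame(
        {
            "A": feature_ids[struct_cols[ia]],
            "B": feature_ids[unstruct_cols[ib]],
            "a_case": cells1[0][keep].astype(int),
            "b_case": cells1[1][keep].astype(int),
            "c_case": cells1[2][keep].astype(int),
            "d_case": cells1[3][keep].astype(int),
            "a_noncase": cells0[0][keep].astype(int),
            "b_noncase": cells0[1][keep].astype(int),
            "c_noncase": cells0[2][keep].astype(int),
            "d_noncase": cells0[3][keep].astype(int),
            "E_case": e1[keep],
            "E_noncase": e0[keep],
            "T_case": t1[keep],
            "p_case": p1[keep],
            "T_noncase": t0[keep],
            "p_noncase": p0[keep],
            "log_or_case": l1[keep],
            "log_or_noncase": l0[keep],
            "ih": ih[keep],
            "ih_p": ih_p[keep],
            "joint_risk": jr[keep],
            "posterior": post[keep],
        }
    )
    rows["score_A"] = rows["A"].map(score_of)
    rows["score_B"] = rows["B"].map(score_of)
    rows = rows.sort_values(
        ["ih", "joint_risk", "A", "B"],
        ascending=[False, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return rows, survival


def rank_report(
    selected: pd.DataFrame, direction: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detail and summary reports for risk-factor or protective pairs.

    ``direction="risk"`` keeps pairs whose structured feature has a positive
    NBC risk score, ``"protective"`` a negative one; pairs with score
    exactly zero appear in neither.  The detail report carries per-stratum
    margins, expected and actual joint counts, and IH; the summary report
    carries joint risk and IH.
    """
    if direction == "risk":
        kept = selected[selected["score_A"] > 0]
    elif direction == "protective":
        kept = selected[selected["score_A"] < 0]
    else:
        raise ValueError("direction must be 'risk' or 'protective'")
    kept = kept.copy()
    kept["nA_case"] = kept["a_case"] + kept["b_case"]
    kept["nB_case"] = kept["a_case"] + kept["c_case"]
    kept["nA_noncase"] = kept["a_noncase"] + kept["b_noncase"]
    kept["nB_noncase"] = kept["a_noncase"] + kept["c_noncase"]
    detail = kept[
        [
            "A",
            "B",
            "nA_case",
            "nB_case",
            "E_case",
            "a_case",
            "nA_noncase",
            "nB_noncase",
            "E_noncase",
            "a_noncase",
            "ih",
        ]
    ].reset_index(drop=True)
    summary = kept[["A", "B", "joint_risk", "ih"]].reset_index(drop=True)
    return detail, summary
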