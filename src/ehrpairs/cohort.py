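"""Cohort construction: inclusion criteria, index-event censoring, feature
expansion and first-occurrence feature matrices.

The processing contract mirrors common EHR risk-modelling practice:

* subjects enter the cohort only with a minimal longitudinal record
  (default: at least 3 distinct encounters spanning at least 30 days);
* cases are censored at their index event — every event dated at or after
  the index encounter is removed, and the prediction point is the
  penultimate visit (the latest remaining encounter), so no post-onset
  information can leak into features;
* lab concepts expand into one dummy feature per value flag
  (``code|L`` … ``code|U``) and NLP concepts into one feature per mention
  type (``code|positive`` … ``code|NFH``);
* the matrix keeps two views of each (subject, feature): a binary
  first-occurrence indicator (the unit of the contingency analysis) and a
  per-visit occurrence count (the unit of cumulative risk scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import train_test_split

STRUCTURED = "STRUCTURED"
UNSTRUCTURED = "UNSTRUCTURED"


@dataclass
class InclusionConfig:
    min_visits: int = 3
    min_span_days: int = 30
    # age filtering is optional: enabled only when birthdates are supplied
    age_window: tuple[float, float] = (10.0, 90.0)
    birthdates: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.min_visits < 1:
            raise ValueError("min_visits must be >= 1")
        if self.min_span_days < 0:
            raise ValueError("min_span_days must be >= 0")


def apply_inclusion_criteria(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    config: InclusionConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Return retained subject ids and an exclusion log.

    A subject is retained iff they have at least ``min_visits`` distinct
    encounters, their record spans at least ``min_span_days`` between first
    and last event date, and — when birthdates are available — at least one
    encounter falls inside the age window.  The log records the first rule
    that fired for each excluded subject.
    """
    config = config or InclusionConfig()
    grouped = events.groupby("subject_id")
    n_enc = grouped["encounter_id"].nunique()
    span = (grouped["date"].max() - grouped["date"].min()).dt.days

    excluded: list[tuple[str, str]] = []
    retained: list[str] = []
    for sid in labels["subject_id"]:
        if sid not in n_enc.index:
            excluded.append((sid, "no events"))
            continue
        if n_enc[sid] < config.min_visits:
            excluded.append((sid, f"fewer than {config.min_visits} visits"))
            continue
        if span[sid] < config.min_span_days:
            excluded.append((sid, f"span under {config.min_span_days} days"))
            continue
        if config.birthdates is not None:
            birth = config.birthdates.get(sid)
            ages = (
                grouped.get_group(sid)["date"] - birth
            ).dt.days / 365.25
            lo, hi = config.age_window
            if not ((ages >= lo) & (ages <= hi)).any():
                excluded.append((sid, "no encounter inside age window"))
                continue
        retained.append(sid)
    log = pd.DataFrame(excluded, columns=["subject_id", "rule"])
    return np.array(retained, dtype=object), log


def censor_case_history(
    events: pd.DataFrame, labels: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Censor cases at their index event and fix each prediction point.

    For cases, drops every event dated at or after the index date (the index
    encounter itself included, so predictions rest on strictly pre-index
    data); the prediction point is the latest remaining encounter date — the
    penultimate visit.  Non-cases keep all events and predict at their last
    visit.  Cases with no pre-index encounters are dropped and logged.

    Returns ``(censored events, prediction points, dropped log)``.
    """
    labels = labels.set_index("subject_id")
    case_ids = labels.index[labels["is_case"] == 1]

    # every case's index date must coincide with one of its encounters
    case_events = events[events["subject_id"].isin(case_ids)]
    last_by_subject = case_events.groupby("subject_id")["date"].agg(set)
    for sid in case_ids:
        idx_date = labels.loc[sid, "index_date"]
        if pd.isna(idx_date):
            raise ValueError(f"case {sid} has no index_date")
        if sid not in last_by_subject.index or idx_date not in last_by_subject[sid]:
            raise ValueError(
                f"case {sid}: index_date {idx_date.date()} matches no encounter"
            )

    is_case_row = events["subject_id"].map(labels["is_case"]).to_numpy() == 1
    index_of_row = events["subject_id"].map(labels["index_date"])
    keep = ~is_case_row | (events["date"] < index_of_row)
    censored = events[keep].reset_index(drop=True)

    pred_rows: list[tuple[str, pd.Timestamp]] = []
    dropped: list[tuple[str, str]] = []
    remaining_last = censored.groupby("subject_id")["date"].max()
    for sid, row in labels.iterrows():
        if row["is_case"] == 1 and sid not in remaining_last.index:
            dropped.append((sid, "no pre-index encounters"))
            continue
        if sid in remaining_last.index:
            pred_rows.append((sid, remaining_last[sid]))
    if dropped:
        drop_ids = {sid for sid, _ in dropped}
        censored = censored[~censored["subject_id"].isin(drop_ids)].reset_index(
            drop=True
        )
    points = pd.DataFrame(pred_rows, columns=["subject_id", "prediction_date"])
    return censored, points, pd.DataFrame(dropped, columns=["subject_id", "reason"])


def expand_features(events: pd.DataFrame) -> pd.DataFrame:
    """Expand lab and NLP concepts into dummy features.

    Lab concept codes become ``code|flag`` (five possible flags), NLP codes
    become ``code|mention_type`` (four possible types); every other domain
    keeps its code.  Adds ``feature_id`` and ``kind`` columns; NLP features
    are UNSTRUCTURED, everything else STRUCTURED.
    """
    is_lab = events["domain"] == "lab"
    is_nlp = events["domain"] == "nlp"
    if (is_lab & (events["value_flag"].fillna("") == "")).any():
        raise ValueError("lab event without value_flag")
    if (is_nlp & (events["mention_type"].fillna("") == "")).any():
        raise ValueError("nlp event without mention_type")
    out = events.copy()
    fid = out["concept_code"].astype(str).copy()
    fid[is_lab] = out.loc[is_lab, "concept_code"] + "|" + out.loc[is_lab, "value_flag"]
    fid[is_nlp] = (
        out.loc[is_nlp, "concept_code"] + "|" + out.loc[is_nlp, "mention_type"]
    )
    out["feature_id"] = fid
    out["kind"] = np.where(is_nlp, UNSTRUCTURED, STRUCTURED)
    return out


@dataclass
class FeatureMatrix:
    """Subjects x expanded features, with binary and occurrence-count views.

    ``counts[i, j]`` is the number of distinct encounters at which subject i
    recorded feature j at or before their prediction point; the binary view
    clips counts to {0, 1} (first-occurrence presence).
    """

    subject_ids: np.ndarray
    feature_ids: list[str]
    kinds: np.ndarray
    counts: sp.csr_matrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature ids must be unique")
        self._col = {f: j for j, f in enumerate(self.feature_ids)}

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def binary(self) -> sp.csr_matrix:
        b = self.counts.copy()
        b.data = np.minimum(b.data, 1)
        return b

    def column_index(self, feature_id: str) -> int:
        if feature_id not in self._col:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self._col[feature_id]

    def subset_subjects(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            subject_ids=np.asarray(self.subject_ids)[idx],
            feature_ids=list(self.feature_ids),
            kinds=self.kinds,
            counts=self.counts[idx],
            labels=np.asarray(self.labels)[idx],
        )

    def select_features(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        cols = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureMatrix(
            subject_ids=self.subject_ids,
            feature_ids=[self.feature_ids[j] for j in cols],
            kinds=self.kinds[cols],
            counts=self.counts[:, cols].tocsr(),
            labels=self.labels,
        )


def build_feature_matrix(
    expanded: pd.DataFrame,
    labels: pd.DataFrame,
    prediction_points: pd.DataFrame,
) -> FeatureMatrix:
    """Assemble the feature matrix from an expanded, censored event stream.

    Only events dated at or before the subject's prediction point count.
    The encounter-marker events emitted by the simulator (domain
    ``demographic``, code ``encounter``) are kept as an ordinary — and
    uninformative — structured feature.
    """
    points = prediction_points.set_index("subject_id")["prediction_date"]
    ev = expanded[expanded["subject_id"].isin(points.index)].copy()
    cutoff = ev["subject_id"].map(points)
    ev = ev[ev["date"] <= cutoff]

    subject_ids = prediction_points["subject_id"].to_numpy()
    label_map = labels.set_index("subject_id")["is_case"]
    y = label_map.loc[subject_ids].to_numpy().astype(int)

    # per-visit multiplicity: distinct encounters per (subject, feature)
    occ = (
        ev.groupby(["subject_id", "feature_id"])["encounter_id"]
        .nunique()
        .reset_index(name="count")
    )
    feature_ids = sorted(ev["feature_id"].unique())
    kind_map = ev.drop_duplicates("feature_id").set_index("feature_id")["kind"]
    sidx = {s: i for i, s in enumerate(subject_ids)}
    fidx = {f: j for j, f in enumerate(feature_ids)}
    counts = sp.coo_matrix(
        (
            occ["count"].to_numpy(),
            (
                occ["subject_id"].map(sidx).to_numpy(),
                occ["feature_id"].map(fidx).to_numpy(),
            ),
        ),
        shape=(len(subject_ids), len(feature_ids)),
    ).tocsr()
    return FeatureMatrix(
        subject_ids=subject_ids,
        feature_ids=feature_ids,
        kinds=kind_map.loc[feature_ids].to_numpy(),
        counts=counts,
        labels=y,
    )


def build_cohort(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    inclusion: InclusionConfig | None = None,
) -> FeatureMatrix:
    """Full pipeline: inclusion -> censoring -> expansion -> matrix."""
    retained, _ = apply_inclusion_criteria(events, labels, inclusion)
    keep = labels["subject_id"].isin(retained)
    labels = labels[keep].reset_index(drop=True)
    events = events[events["subject_id"].isin(retained)].reset_index(drop=True)
    censored, points, _ = censor_case_history(events, labels)
    expanded = expand_features(censored)
    return build_feature_matrix(expanded, labels, points)


def split_train_test(
    matrix: FeatureMatrix, test_fraction: float = 0.30, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Subject-level stratified split; both sides contain cases."""
    if int(matrix.labels.sum()) < 2:
        raise ValueError("need at least 2 cases to stratify the split")
    idx = np.arange(matrix.n_subjects)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=matrix.labels,
    )
    return matrix.subset_subjects(np.sort(train_idx)), matrix.subset_subjects(
        np.sort(test_idx)
    )


def subsample_training(
    train: FeatureMatrix,
    total_n: int,
    target_case_fraction: float = 0.12,
    seed: int = 0,
) -> FeatureMatrix:
    """Lift the training case prevalence by undersampling non-cases.

    Keeps ``round(total_n * target_case_fraction)`` cases and fills the rest
    with non-cases, both sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(train.labels == 1)
    noncase_idx = np.flatnonzero(train.labels == 0)
    n_case = int(round(total_n * target_case_fraction))
    n_noncase = total_n - n_case
    if n_case > len(case_idx):
        attainable = len(case_idx) / total_n
        raise ValueError(
            f"cannot reach case fraction {target_case_fraction} at n={total_n}; "
            f"maximum attainable is {attainable:.4f}"
        )
    if n_noncase > len(noncase_idx):
        raise ValueError("not enough non-cases for the requested total_n")
    chosen = np.concatenate(
        [
            rng.choice(case_idx, size=n_case, replace=False),
            rng.choice(noncase_idx, size=n_noncase, replace=False),
        ]
    )
    return train.subset_subjects(np.sort(chosen))
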