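"""Reading and writing of event streams, label tables and feature matrices.

All on-disk formats are UTF-8 tab-delimited text with a header row, so that
fixtures and outputs stay inspectable.  Dates are ISO-8601.  Inapplicable
fields (value flags outside the lab domain, mention types outside the NLP
domain) are empty strings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import (
    DOMAINS,
    EVENT_COLUMNS,
    LABEL_COLUMNS,
    MENTION_TYPES,
    VALUE_FLAGS,
)


class EventFormatError(ValueError):
    """Raised when an event file or frame violates the schema."""


def validate_events(events: pd.DataFrame) -> None:
    """Check schema, domains and conditional flag/mention fields.

    Raises :class:`EventFormatError` naming the offending row (0-based,
    excluding the header) and field.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventFormatError(f"missing columns: {missing}")
    bad = ~events["domain"].isin(DOMAINS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventFormatError(
            f"row {row}: unknown domain {events['domain'].iloc[row]!r}"
        )
    is_lab = events["domain"] == "lab"
    flag = events["value_flag"].fillna("")
    bad = is_lab & ~flag.isin(VALUE_FLAGS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventFormatError(
            f"row {row}: lab event requires value_flag in {VALUE_FLAGS}, "
            f"got {flag.iloc[row]!r}"
        )
    bad = ~is_lab & (flag != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventFormatError(
            f"row {row}: value_flag set on non-lab domain "
            f"{events['domain'].iloc[row]!r}"
        )
    is_nlp = events["domain"] == "nlp"
    mention = events["mention_type"].fillna("")
    bad = is_nlp & ~mention.isin(MENTION_TYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventFormatError(
            f"row {row}: nlp event requires mention_type in {MENTION_TYPES}, "
            f"got {mention.iloc[row]!r}"
        )
    bad = ~is_nlp & (mention != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventFormatError(
            f"row {row}: mention_type set on non-nlp domain "
            f"{events['domain'].iloc[row]!r}"
        )
    if events["date"].isna().any():
        row = int(np.flatnonzero(events["date"].isna().to_numpy())[0])
        raise EventFormatError(f"row {row}: unparseable or missing date")


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in EVENT_COLUMNS if c != "date"},
        keep_default_na=False,
    )
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventFormatError(f"missing columns: {missing}")
    events["date"] = pd.to_datetime(events["date"], errors="coerce")
    validate_events(events)
    return events


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.loc[:, list(LABEL_COLUMNS)].copy()
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out["index_date"] = out["index_date"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject_id": str, "index_date": str},
        keep_default_na=False,
    )
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise EventFormatError(f"missing columns: {missing}")
    labels["is_case"] = labels["is_case"].astype(int)
    if not labels["is_case"].isin((0, 1)).all():
        raise EventFormatError("is_case must be 0/1")
    labels["index_date"] = pd.to_datetime(
        labels["index_date"].replace("", pd.NaT), errors="raise"
    )
    return labels


def write_matrix(matrix, prefix: str | Path) -> None:
    """Write a FeatureMatrix as sparse triplets plus a feature dictionary.

    ``<prefix>.triplets.tsv`` holds (subject_id, feature_id, count) rows of
    the occurrence view; ``<prefix>.features.tsv`` holds the ordered feature
    dictionary with its STRUCTURED/UNSTRUCTURED kind; ``<prefix>.subjects.tsv``
    holds the ordered subjects with labels.
    """
    prefix = Path(prefix)
    coo = matrix.counts.tocoo()
    pd.DataFrame(
        {
            "subject_id": np.asarray(matrix.subject_ids)[coo.row],
            "feature_id": np.asarray(matrix.feature_ids, dtype=object)[coo.col],
            "count": coo.data.astype(int),
        }
    ).to_csv(prefix.with_suffix(".triplets.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"feature_id": matrix.feature_ids, "kind": matrix.kinds}
    ).to_csv(prefix.with_suffix(".features.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"subject_id": matrix.subject_ids, "is_case": matrix.labels}
    ).to_csv(prefix.with_suffix(".subjects.tsv"), sep="\t", index=False)


def read_matrix(prefix: str | Path):
    from .cohort import FeatureMatrix

    prefix = Path(prefix)
    trip = pd.read_csv(prefix.with_suffix(".triplets.tsv"), sep="\t", dtype={"subject_id": str, "feature_id": str})
    feats = pd.read_csv(prefix.with_suffix(".features.tsv"), sep="\t", dtype=str)
    subs = pd.read_csv(prefix.with_suffix(".subjects.tsv"), sep="\t", dtype={"subject_id": str})
    feature_ids = feats["feature_id"].tolist()
    subject_ids = subs["subject_id"].to_numpy()
    fidx = {f: j for j, f in enumerate(feature_ids)}
    sidx = {s: i for i, s in enumerate(subject_ids)}
    counts = sp.coo_matrix(
        (
            trip["count"].to_numpy(),
            (
                trip["subject_id"].map(sidx).to_numpy(),
                trip["feature_id"].map(fidx).to_numpy(),
            ),
        ),
        shape=(len(subject_ids), len(feature_ids)),
    ).tocsr()
    return FeatureMatrix(
        subject_ids=subject_ids,
        feature_ids=feature_ids,
        kinds=feats["kind"].to_numpy(),
        counts=counts,
        labels=subs["is_case"].to_numpy().astype(int),
    )
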