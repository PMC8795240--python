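"""Synthetic longitudinal EHR cohort generator with planted ground truth.

Generates event streams shaped like a de-identified EHR extract (one row =
one concept recorded at one encounter) for two labelled cohorts: ``cases``,
who carry an index event (the first occurrence of the outcome, after which
their record is censored downstream), and ``non-cases``.  Feature presence is
sampled at the subject level as first-occurrence indicators; designated
structured-unstructured feature pairs are planted with a chosen per-cohort
odds ratio so the interaction-heterogeneity ground truth is known exactly.

The default configuration emulates a rare-outcome clinical population:
~1% case prevalence, over-dispersed visit counts, and feature marginal
prevalences in the 1-20% range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

DOMAINS = ("diagnosis", "procedure", "medication", "lab", "demographic", "nlp")
VALUE_FLAGS = ("L", "N", "H", "A", "U")
MENTION_TYPES = ("positive", "NEG", "FH", "NFH")

# per-occurrence sampling weights for lab value flags and NLP mention types
_FLAG_WEIGHTS = (0.15, 0.50, 0.20, 0.10, 0.05)
_MENTION_WEIGHTS = (0.70, 0.15, 0.10, 0.05)

EVENT_COLUMNS = (
    "subject_id",
    "encounter_id",
    "concept_code",
    "domain",
    "date",
    "value_flag",
    "mention_type",
)
LABEL_COLUMNS = ("subject_id", "is_case", "index_date")


class InfeasibleTableError(ValueError):
    """Raised when (marginals, odds ratio) admit no valid 2x2 probability table."""


def solve_cell_probs(p_a: float, p_b: float, or_target: float) -> np.ndarray:
    """Solve the 2x2 cell probabilities with given marginals and odds ratio.

    Returns ``[[p11, p10], [p01, p00]]`` (rows index A, columns index B)
    such that row/column sums match ``p_a``/``p_b`` and
    ``p11*p00 / (p10*p01) == or_target``.  For ``or_target != 1`` the joint
    cell is the admissible root of the quadratic

        (theta-1) p11^2 - S p11 + theta p_a p_b = 0,
        S = 1 + (p_a + p_b)(theta - 1),

    i.e. the Plackett-copula construction for a 2x2 table.

    Raises
    ------
    InfeasibleTableError
        If the marginals are outside (0, 1), the odds ratio is not positive,
        or the implied cells leave [0, 1].
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise InfeasibleTableError(
            f"marginals must lie in (0,1); got p_a={p_a}, p_b={p_b}"
        )
    if not or_target > 0.0:
        raise InfeasibleTableError(f"odds ratio must be positive; got {or_target}")

    if math.isclose(or_target, 1.0, rel_tol=0.0, abs_tol=1e-15):
        p11 = p_a * p_b
    else:
        theta = or_target
        s = 1.0 + (p_a + p_b) * (theta - 1.0)
        disc = s * s - 4.0 * theta * (theta - 1.0) * p_a * p_b
        if disc < 0.0:
            raise InfeasibleTableError(
                f"no real joint probability for p_a={p_a}, p_b={p_b}, or={or_target}"
            )
        p11 = (s - math.sqrt(disc)) / (2.0 * (theta - 1.0))

    cells = np.array(
        [[p11, p_a - p11], [p_b - p11, 1.0 - p_a - p_b + p11]], dtype=float
    )
    if (cells < -1e-12).any():
        raise InfeasibleTableError(
            f"cell probabilities leave [0,1] for p_a={p_a}, p_b={p_b}, "
            f"or={or_target}: {cells.ravel().tolist()}"
        )
    return np.clip(cells, 0.0, 1.0)


@dataclass(frozen=True)
class PlantedPair:
    """A structured-unstructured feature pair with known per-cohort odds ratios.

    The four marginal prevalences and two odds ratios fully determine the
    joint first-occurrence distribution of the pair in each cohort, hence the
    true interaction heterogeneity between cohorts.
    """

    structured_feature_id: str
    nlp_feature_id: str
    or_case: float
    or_noncase: float
    p_a_case: float
    p_a_noncase: float
    p_b_case: float
    p_b_noncase: float

    def __post_init__(self) -> None:
        # validates feasibility eagerly; raises InfeasibleTableError otherwise
        self.cells("case")
        self.cells("noncase")

    def cells(self, stratum: str) -> np.ndarray:
        if stratum == "case":
            return solve_cell_probs(self.p_a_case, self.p_b_case, self.or_case)
        if stratum == "noncase":
            return solve_cell_probs(
                self.p_a_noncase, self.p_b_noncase, self.or_noncase
            )
        raise ValueError(f"unknown stratum {stratum!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``visits_mean``/``visits_dispersion`` parameterise an over-dispersed
    (negative-binomial, shifted to a minimum of one) visit-count
    distribution, so subjects below any visit-based inclusion threshold
    exist by construction.
    """

    n_subjects: int = 10_000
    case_fraction: float = 0.01
    date_range: tuple[date, date] = (date(2000, 1, 1), date(2018, 12, 31))
    visits_mean: float = 8.0
    visits_dispersion: float = 1.5
    n_structured_features: int = 30
    n_nlp_features: int = 10
    marginal_prevalence_range: tuple[float, float] = (0.01, 0.20)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    # optional per-feature (p_case, p_noncase) prevalence overrides
    prevalence_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    repeat_mean: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0,1)")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_structured_features <= 0 or self.n_nlp_features < 0:
            raise ValueError("feature counts must be positive")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("date_range start must precede end")
        lo, hi = self.marginal_prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("marginal_prevalence_range must be within (0,1)")
        if self.visits_mean < 1.0 or self.visits_dispersion <= 0:
            raise ValueError("visits_mean >= 1 and visits_dispersion > 0 required")

    def structured_ids(self) -> list[str]:
        return [f"str_{i:04d}" for i in range(self.n_structured_features)]

    def nlp_ids(self) -> list[str]:
        return [f"nlp_{i:04d}" for i in range(self.n_nlp_features)]


def _structured_domain(index: int) -> str:
    # deterministic mix of structured domains; planted pairs should use
    # diagnosis-domain features (no value-flag expansion changes their id)
    if index % 5 == 3:
        return "medication"
    if index % 5 == 4:
        return "lab"
    return "diagnosis"


def sample_pair_tables(
    pair: PlantedPair,
    n_case: int,
    n_noncase: int,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample replicate 2x2 first-occurrence count tables for a planted pair.

    Draws subject-level joint indicators directly from the pair's cell
    probabilities — the same generative model :func:`simulate_cohort` uses —
    without materialising dated events, which makes replicate studies of the
    downstream statistics cheap.  Returns two ``(n_reps, 4)`` arrays of
    ``(a, b, c, d)`` counts, for the case and non-case cohorts.
    """
    out = []
    for stratum, n in (("case", n_case), ("noncase", n_noncase)):
        probs = pair.cells(stratum).ravel()
        out.append(rng.multinomial(n, probs, size=n_reps))
    return out[0], out[1]


def make_interaction_benchmark(
    n_train: int = 8_000,
    n_test: int = 20_000,
    train_case_fraction: float = 0.12,
    test_case_fraction: float = 0.01,
    n_informative_structured: int = 8,
    n_noise_structured: int = 12,
    n_noise_nlp: int = 8,
    base_prevalence: float = 0.10,
    effect: float = 0.12,
    interaction_agreement: float = 0.9,
    seed: int = 0,
):
    """Feature matrices with structured-dominant signal plus one
    structured-unstructured interaction.

    The informative structured features are case-enriched by ``effect`` in
    absolute prevalence.  One structured/unstructured pair carries an
    XOR-style interaction: both members have prevalence 0.5 in *both*
    classes (marginally uninformative), but they agree with probability
    ``interaction_agreement`` in cases and disagree with that probability in
    non-cases.  An additive per-feature risk score therefore gains nothing
    from the pair, while a model that conditions on feature combinations
    can.  Training prevalence defaults to the lifted 12%, testing to the
    natural 1%.

    Returns ``(train, test)`` FeatureMatrix objects (counts are binary).
    """
    import scipy.sparse as sp

    from .cohort import STRUCTURED, UNSTRUCTURED, FeatureMatrix

    rng = np.random.default_rng(seed)
    feature_ids = (
        [f"sig_{i:02d}" for i in range(n_informative_structured)]
        + [f"strnoise_{i:02d}" for i in range(n_noise_structured)]
        + ["int_struct"]
        + ["int_nlp|positive"]
        + [f"nlpnoise_{i:02d}|positive" for i in range(n_noise_nlp)]
    )
    n_struct = n_informative_structured + n_noise_structured + 1
    kinds = np.array(
        [STRUCTURED] * n_struct + [UNSTRUCTURED] * (1 + n_noise_nlp), dtype=object
    )

    def build(n: int, case_fraction: float, tag: str) -> FeatureMatrix:
        n_case = int(round(n * case_fraction))
        y = np.zeros(n, dtype=int)
        y[:n_case] = 1
        p = len(feature_ids)
        X = np.zeros((n, p), dtype=np.int8)
        prev = np.full(p, base_prevalence)
        Xr = rng.random((n, p))
        X[:] = Xr < prev  # baseline draw for every feature
        for j in range(n_informative_structured):
            X[:, j] = Xr[:, j] < np.where(y == 1, base_prevalence + effect, base_prevalence)
        # interaction pair: balanced marginals, class-dependent agreement
        js, jn = n_struct - 1, n_struct
        s = rng.random(n) < 0.5
        agree = rng.random(n) < np.where(y == 1, interaction_agreement, 1 - interaction_agreement)
        X[:, js] = s
        X[:, jn] = np.where(agree, s, ~s)
        return FeatureMatrix(
            subject_ids=np.array([f"{tag}{i:06d}" for i in range(n)]),
            feature_ids=list(feature_ids),
            kinds=kinds,
            counts=sp.csr_matrix(X),
            labels=y,
        )

    return (
        build(n_train, train_case_fraction, "tr"),
        build(n_test, test_case_fraction, "te"),
    )


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an event stream and label table under ``config``.

    Every subject has at least one encounter (a ``demographic`` marker event
    is recorded at each visit, as real encounters always record something).
    Cases take their final visit as the index event; all their feature
    events are placed strictly before it so that censoring at the index
    preserves the planted joint distribution exactly.

    Returns ``(events, labels)`` data frames with the canonical columns.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subject_ids = np.array([f"s{i:07d}" for i in range(n)])
    is_case = rng.random(n) < config.case_fraction

    # visit counts: shifted negative binomial, minimum 1
    mu = config.visits_mean - 1.0
    r = config.visits_dispersion
    n_visits = 1 + rng.negative_binomial(r, r / (r + mu), size=n)
    # cases need at least 2 visits *usually* (index + history) but single-visit
    # cases must remain possible for censoring edge-case coverage, so no floor.

    start, end = config.date_range
    span_days = (end - start).days

    structured = config.structured_ids()
    nlp = config.nlp_ids()
    all_features = structured + nlp
    planted_feature_ids = set()
    for p in config.planted_pairs:
        if p.structured_feature_id not in structured:
            raise ValueError(f"unknown structured feature {p.structured_feature_id}")
        if p.nlp_feature_id not in nlp:
            raise ValueError(f"unknown nlp feature {p.nlp_feature_id}")
        planted_feature_ids.update((p.structured_feature_id, p.nlp_feature_id))

    # per-feature prevalence, shared across cohorts unless overridden
    base_prev = rng.uniform(*config.marginal_prevalence_range, size=len(all_features))
    prev = np.column_stack([base_prev, base_prev])  # columns: case, noncase
    col_of = {fid: j for j, fid in enumerate(all_features)}
    for fid, (pc, pnc) in config.prevalence_overrides.items():
        prev[col_of[fid]] = (pc, pnc)

    # subject-level first-occurrence indicators
    present = np.zeros((n, len(all_features)), dtype=bool)
    u = rng.random((n, len(all_features)))
    present[is_case] = u[is_case] < prev[:, 0]
    present[~is_case] = u[~is_case] < prev[:, 1]

    # planted pairs override their two columns with the joint draw
    for p in config.planted_pairs:
        ja, jb = col_of[p.structured_feature_id], col_of[p.nlp_feature_id]
        for stratum, mask in (("case", is_case), ("noncase", ~is_case)):
            m = int(mask.sum())
            if m == 0:
                continue
            cell = rng.choice(4, size=m, p=p.cells(stratum).ravel())
            present[mask, ja] = cell < 2  # cells 0,1 have A=1
            present[mask, jb] = (cell == 0) | (cell == 2)  # cells 0,2 have B=1

    domains = {fid: _structured_domain(i) for i, fid in enumerate(structured)}
    domains.update({fid: "nlp" for fid in nlp})

    rows: list[tuple] = []
    day = timedelta(days=1)
    for i in range(n):
        sid = subject_ids[i]
        k = int(n_visits[i])
        offsets = np.sort(rng.choice(span_days + 1, size=k, replace=False)) if (
            k <= span_days
        ) else np.sort(rng.integers(0, span_days + 1, size=k))
        dates = [start + int(o) * day for o in offsets]
        enc_ids = [f"{sid}_e{j:03d}" for j in range(k)]
        for eid, d in zip(enc_ids, dates):
            rows.append((sid, eid, "encounter", "demographic", d, "", ""))
        # cases: feature history strictly before the index (= last) visit
        if is_case[i]:
            eligible = list(range(k - 1))
        else:
            eligible = list(range(k))
        if not eligible:
            continue
        feat_cols = np.flatnonzero(present[i])
        for j in feat_cols:
            fid = all_features[j]
            dom = domains[fid]
            n_occ = 1 + (
                rng.poisson(config.repeat_mean) if fid not in planted_feature_ids else 0
            )
            n_occ = min(n_occ, len(eligible))
            visit_idx = rng.choice(eligible, size=n_occ, replace=False)
            for v in visit_idx:
                flag = ""
                mention = ""
                if dom == "lab":
                    flag = VALUE_FLAGS[rng.choice(5, p=_FLAG_WEIGHTS)]
                elif dom == "nlp":
                    if fid in planted_feature_ids:
                        mention = "positive"
                    else:
                        mention = MENTION_TYPES[rng.choice(4, p=_MENTION_WEIGHTS)]
                rows.append((sid, enc_ids[v], fid, dom, dates[v], flag, mention))

    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    events["date"] = pd.to_datetime(events["date"])
    events = events.sort_values(
        ["subject_id", "date", "encounter_id", "concept_code"], kind="stable"
    ).reset_index(drop=True)

    last_dates = events.groupby("subject_id")["date"].max()
    labels = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "is_case": is_case.astype(int),
            "index_date": pd.to_datetime(
                [last_dates[sid] if is_case[i] else pd.NaT for i, sid in enumerate(subject_ids)]
            ),
        }
    )
    return events, labels
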