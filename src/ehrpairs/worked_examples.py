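"""Reference worked examples from a published EHR suicide-risk case-control
analysis.

The published study drew two equal cohorts of 23,566 subjects (cases and
non-cases) from a large hospital-system EHR and reported, for its
highest-interaction-heterogeneity structured-unstructured feature pairs, the
per-cohort margins |A|, |B| and the joint first-occurrence count a.  Those
printed margins fully determine each stratum's 2x2 table
(b = |A| - a, c = |B| - a, d = n - |A| - |B| + a), so the pair statistics can
be recomputed from scratch here and compared against the printed values.

Also included: the study's concept-overlap counts (patients holding a
structured code for a concept out of all patients holding the concept in
either coded or note-derived form).

These constants are *inputs* (printed margins and counts), never outputs.
"""

from __future__ import annotations

from .interactions import StratifiedPair

COHORT_SIZE = 23_566

# per-stratum margins as (|A|, |B|, a)
PAIR_MARGIN_EXAMPLES: dict[str, dict] = {
    "drug_abuse_x_suicide_attempts": dict(
        structured="Other, mixed, or unsp. drug abuse, unsp. use",
        unstructured="Suicide attempts|positive",
        case=(2356, 3741, 1003),
        noncase=(148, 563, 53),
    ),
    "suicidal_ideation_x_section_xii": dict(
        structured="Suicidal ideation",
        unstructured="Section XII|positive",
        case=(1820, 3045, 1299),
        noncase=(127, 403, 81),
    ),
    "suicidal_ideation_x_schizoaffective": dict(
        structured="Suicidal ideation",
        unstructured="Schizoaffective schizophrenia|positive",
        case=(1820, 676, 223),
        noncase=(127, 118, 21),
    ),
}

# concept -> (patients with a structured code, patients with the concept at all)
CONCEPT_OVERLAP_EXAMPLES: dict[str, tuple[int, int]] = {
    "schizoaffective_disorder": (250, 595),
    "opioid_dependence_or_abuse": (1183, 4315),
}


def example_pair(name: str, n: int = COHORT_SIZE) -> StratifiedPair:
    """Reconstruct one reference pair's stratified tables from its margins."""
    spec = PAIR_MARGIN_EXAMPLES[name]
    return StratifiedPair.from_margins(
        spec["structured"],
        spec["unstructured"],
        case=spec["case"],
        noncase=spec["noncase"],
        n=n,
    )


def structured_coverage_percent(n_structured: int, n_total: int) -> float:
    """Percentage of concept holders carrying the structured code."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_structured / n_total
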