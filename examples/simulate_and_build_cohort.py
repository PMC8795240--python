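"""Simulate a longitudinal EHR cohort and build its feature matrix.

Generates dated event streams for 5,000 subjects (~1% cases) with one
planted structured-unstructured pair, applies the inclusion criteria
(>=3 visits spanning >=30 days), censors cases at their index event, and
assembles the first-occurrence feature matrix.
"""

from ehrpairs import (
    InclusionConfig,
    PlantedPair,
    SimConfig,
    apply_inclusion_criteria,
    build_cohort,
    simulate_cohort,
)

config = SimConfig(
    n_subjects=5_000,
    case_fraction=0.01,
    seed=42,
    planted_pairs=[
        PlantedPair("str_0000", "nlp_0000", 6.0, 2.0, 0.20, 0.15, 0.20, 0.15)
    ],
)
events, labels = simulate_cohort(config)
print(f"events: {len(events):,} rows, {labels['is_case'].sum()} cases "
      f"of {len(labels):,} subjects")

retained, exclusion_log = apply_inclusion_criteria(events, labels, InclusionConfig())
print(f"inclusion: {len(retained):,} retained; exclusions by rule:")
print(exclusion_log["rule"].value_counts().to_string())

matrix = build_cohort(events, labels)
print(f"\nfeature matrix: {matrix.n_subjects:,} subjects x "
      f"{len(matrix.feature_ids)} expanded features "
      f"({(matrix.kinds == 'UNSTRUCTURED').sum()} unstructured), "
      f"{int(matrix.labels.sum())} cases")
print("a lab feature expands per value flag, e.g.:",
      [f for f in matrix.feature_ids if f.startswith("str_0004|")])
print("an NLP feature expands per mention type, e.g.:",
      [f for f in matrix.feature_ids if f.startswith("nlp_0001|")])
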