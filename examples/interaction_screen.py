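"""Screen structured x unstructured feature pairs for interaction
heterogeneity.

Simulates a cohort in which one pair's odds ratio differs between cases
(OR = 12) and non-cases (OR = 3), samples equal case / non-case cohorts,
and runs the selection pipeline: affirmative-mention filter, top-200 NBC
ranking, chi-squared screen in both strata, IH test, and the minimum
joint-occurrence rule.
"""

from ehrpairs import (
    PlantedPair,
    SimConfig,
    build_cohort,
    fit_nbc,
    rank_report,
    sample_equal_cohorts,
    select_pairs,
    simulate_cohort,
)

planted = PlantedPair("str_0000", "nlp_0000", 12.0, 3.0, 0.25, 0.20, 0.25, 0.20)
config = SimConfig(
    n_subjects=8_000, case_fraction=0.05, seed=3, planted_pairs=[planted]
)
events, labels = simulate_cohort(config)
matrix = build_cohort(events, labels)
model = fit_nbc(matrix)
cases, noncases = sample_equal_cohorts(matrix, seed=3)
print(f"equal cohorts of {cases.n_subjects} subjects each")

selected, survival = select_pairs(cases, noncases, model, top_k=200, min_joint=10)
print("pairs surviving each filter:", survival)
print("\nselected pairs (sorted by IH):")
cols = ["A", "B", "a_case", "a_noncase", "ih", "ih_p", "joint_risk", "posterior"]
print(selected[cols].to_string(index=False))

detail, summary = rank_report(selected, "risk")
print("\nrisk-factor report (margins, expected vs actual joint counts, IH):")
print(detail.round(2).to_string(index=False))
print(
    "\nThe planted pair is flagged because its association strength differs"
    "\nbetween cohorts (heterogeneous OR), not merely because both features"
    "\nare common in cases."
)
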