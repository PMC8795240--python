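# ehrpairs

Screening of structured–unstructured feature-pair interactions in
electronic-health-record (EHR) risk models, with a synthetic longitudinal
cohort generator, first-occurrence cohort building, additive naive-Bayes
risk scores and a balanced random forest benchmark.

## The problem

EHR prediction models draw on two kinds of features: *structured* coded
data (diagnoses, procedures, medications, lab results with value flags)
and *unstructured* concepts extracted from clinician notes by NLP, tagged
by mention type (positive, negated, family history, negated family
history). For rare outcomes such as suicide attempts, an additive
per-feature risk model gains little from adding note-derived features,
while interaction-capturing ensembles gain a lot — suggesting that the
useful extra signal lives in *interactions* between coded and note-derived
features. This package implements a contingency-table framework that finds
the specific pairs responsible.

## The statistics

For a structured feature *A* and unstructured feature *B*, build a 2×2
first-occurrence table (cells *a, b, c, d*) in each of two equal-size
cohorts — cases (stratum 1) and non-cases (stratum 0):

* **Chi-squared screen.** Within each stratum, Pearson's independence
  statistic T = Σ (O − E)²/E with E[a] = (a+c)(a+b)/n, 1 df, flags pairs
  whose joint occurrence departs from independence.
* **Interaction heterogeneity (IH).** Woolf's homogeneity statistic
  across strata:

      log ÔR_i = log(a_i d_i / b_i c_i),
      w_i = (1/a_i + 1/b_i + 1/c_i + 1/d_i)⁻¹,
      IH = Σ_i w_i (log ÔR_i − mean log OR)²  ~  χ²_{k−1},  k = 2.

  Large IH means the A–B association itself differs by outcome status —
  exactly the signal an additive score ignores and a tree ensemble can use.
* **Joint risk.** log₁₀(E_case[a] / E_noncase[a]), a marginal-association
  summary to contrast with IH.
* **Posterior risk.** P(Y=1 | A=1, B=1) by Bayes' rule, after rescaling
  case cells by 1/100 to restore the ~1/99 population case:non-case ratio.

Pairs are screened in order: affirmative-mention filter on *B* (positive
and family-history mentions only), membership of both features in the top
200 by |NBC risk score|, chi-squared significance in both strata, IH
significance, and ≥10 joint occurrences in either cohort.

The supporting models: the **NBC** scores each feature
log[(k₁+α)/(n₁−k₁+α)] − log[(k₀+α)/(n₀−k₀+α)] (α = 0.5) and sums scores
over every (feature, visit) occurrence in a patient's history; the
**balanced random forest** trains each of 30 CART trees on a bootstrap
with an exact 1:4 case:non-case composition (majority undersampling) and
a random 50% feature subset.

## Worked example

Reconstructing a published pair's tables from its printed margins
(|A| = 2356, |B| = 3741, a = 1003 in 23,566 cases; |A| = 148, |B| = 563,
a = 53 in 23,566 non-cases):

```python
from ehrpairs import StratifiedPair, woolf_ih, joint_risk, posterior_risk

pair = StratifiedPair.from_margins(
    "Other, mixed, or unsp. drug abuse, unsp. use", "Suicide attempts|positive",
    case=(2356, 3741, 1003), noncase=(148, 563, 53), n=23_566,
)
woolf_ih(pair)        # (77.3997..., 1.40e-18)
joint_risk(pair)      # 2.0244  -> prints as 2.02
posterior_risk(pair)  # 0.1591  = 10.03 / (10.03 + 53)
```

The IH of 77.4 says the drug-abuse code and the note-derived
suicide-attempt concept are far more strongly associated in cases than in
non-cases; the joint risk of 2.02 says their expected co-occurrence is
~100× higher among cases; the posterior says a patient with both carries
a ~16% outcome probability at the population case rate.

The `examples/` scripts each run one capability end to end and print what
the numbers mean:

* `worked_contingency_examples.py` — the published worked examples above;
* `simulate_and_build_cohort.py` — event-stream simulation, inclusion
  rules, index-event censoring, feature expansion;
* `interaction_screen.py` — full pair-screening pipeline on a cohort with
  a planted heterogeneous pair;
* `model_comparison.py` — NBC vs balanced forest across unstructured /
  structured / combined feature sets;
* `ih_calibration.py` — size and power of the IH test.

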