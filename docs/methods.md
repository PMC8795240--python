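# Methods

## Data model

The atomic datum is an event: one concept recorded at one encounter
(subject id, encounter id, concept code, domain, ISO date, value flag for
labs, mention type for NLP concepts). Cohort labels mark cases and their
index date — the first occurrence of the outcome. Feature matrices carry
two views per (subject, feature): a binary first-occurrence indicator
(presence at or before the subject's prediction point), which is the unit
of every contingency statistic, and a per-visit occurrence count (distinct
encounters recording the feature), which is the unit of cumulative
naive-Bayes scoring.

## Cohort construction

Inclusion requires ≥3 distinct encounters spanning ≥30 days (both
configurable); an optional age window (10–90 years) applies only when
birthdates are supplied, since synthetic streams carry none. Rules fire in
a fixed order and the first violation is logged per excluded subject.

Cases are censored at the index event: every event dated at or after the
index date is dropped, *including the index encounter itself* — the
boundary is ambiguous in common practice, and keeping any index-day data
would risk label leakage. The prediction point is then the latest
remaining encounter (the penultimate visit); non-cases predict at their
last visit. Cases left without pre-index encounters are dropped and
logged.

Lab codes expand into `code|flag` dummies over the five value flags
(L/N/H/A/U) and NLP codes into `code|mention` over the four mention types
(positive/NEG/FH/NFH); expansion is injective, and the expanded universe
partitions into STRUCTURED (everything non-NLP) and UNSTRUCTURED (NLP).

The train/test split is subject-level, 70/30, and *stratified* by label:
at ~1% prevalence an unstratified split at desk scale can leave a test
set with no cases. Forest training data are further rebalanced by
undersampling non-cases to a 12% case fraction, mirroring the lifted
prevalence used for tree ensembles on rare outcomes; the test set keeps
its natural prevalence.

## Pair statistics

All contingency statistics operate on equal-size, label-pure cohorts
sampled without replacement (default size: the minority-class count), so
cohort-size imbalance cannot masquerade as heterogeneity.

* Chi-squared screen: standard Pearson T = Σ(O−E)²/E with margin-based
  expecteds and 1 df, per stratum. The screen requires significance in
  *both* strata, so selected pairs are genuinely associated in each
  cohort, not just one.
* Interaction heterogeneity: Woolf's homogeneity statistic over the k = 2
  strata, 1 df. Log odds ratios use natural log — the inverse-variance
  weight w = (1/a + 1/b + 1/c + 1/d)⁻¹ is the natural-log variance — and
  any stratum containing a zero cell gets 0.5 added to all four of its
  cells (Haldane–Anscombe; configurable) before the computation.
* Joint risk: log₁₀ of the ratio of expected joint counts. Base 10 keeps
  the published decade-scale readings ("2.02" ≈ two orders of magnitude).
* Posterior risk: case cells are multiplied by 1/100 to restore the
  ~1/99 population ratio *only* here — T and IH are computed on raw
  counts, which is the only reading under which the published worked
  examples reproduce. The implementation evaluates the full three-factor
  Bayes chain and its algebraic simplification a₁/(a₁+a₀) and requires
  agreement to 1e-12.

Selection pipeline order: affirmative-mention filter on B (suffixes
`|positive`, `|FH`; negated and negated-family-history mentions are
excluded), then the top-200-by-|NBC-score| membership for both features
(ranked after the mention filter — ranking before it would spend top-200
slots on features that can never be reported), chi-squared in both strata
at α = 0.05, IH at α = 0.05, then ≥10 joint occurrences in either
stratum. Thresholds are uncorrected for multiplicity by default (pass
α = 0.05/m for a Bonferroni reading); every stage logs its survivor
count. Output is sorted by (IH desc, joint risk desc, A, B) for
deterministic reports.

### Worked-example tolerance

The published worked examples are reconstructed from printed margins at
n = 23,566 per cohort. Recomputed IH values land within 0.3% of the
printed ones (77.40 vs 77.55, 54.58 vs 54.69, 52.58 vs 52.75): the
printed expected counts imply an effective n ≈ 23,533 (a ~0.14% smaller
denominator, presumably subjects dropped after cohort sampling), which we
do not attempt to emulate. Joint-risk and expected-count values agree to
the printed two decimals.

## Models

NBC scores are smoothed log odds ratios of first-occurrence prevalence,
α = 0.5 by default — the standard pseudocount guaranteeing finite scores
at k = 0 and k = n, and the value under which the score is exactly
antisymmetric under label swap. Patient scores sum over per-visit
occurrences (a feature recorded at three visits counts three times).
Natural log: only ranking and additive accumulation matter.

The balanced random forest fixes each bootstrap's composition exactly:
cases = round(size/5) for the 1:4 default, drawn with replacement from
all cases; non-cases drawn with replacement from a per-tree majority pool
first undersampled (without replacement) to the ratio against the
available cases. Trees are standard CART (Gini, unlimited depth) from
scikit-learn over a per-tree random ⌈0.5·p⌉ feature subset; ensemble
output is the mean tree case-probability. Per-tree randomness derives
from (seed, tree index), so fits are reproducible and trees independent
of fitting order. A small 5-fold CV grid-search helper selects
configurations by mean AUC.

## Evaluation

AUC via the Mann–Whitney form (half-weight ties). Operating points pick,
for each specificity level (0.99/0.95/0.90/0.80), the smallest score cut
whose specificity ≥ the level — a conservative convention — and report
PPV and sensitivity there, flagging unattainable levels. Confidence
intervals are 95% percentile bootstrap over subjects (1,000 resamples);
model comparisons use a *paired* bootstrap of the AUC difference (both
models evaluated on identical resampled subjects), two-sided
p = 2·min(frac ≤ 0, frac ≥ 0) with zero-differences counted in both
tails. Single-class resamples are redrawn.

## Synthetic data

`simulate_cohort` emulates the shape of a de-identified EHR extract: ~1%
cases, over-dispersed visit counts (shifted negative binomial, minimum
one visit, so inclusion-rule failures exist by construction), dated
encounters over a 19-year window, a demographic marker event per visit
(real encounters always record something), structured features spread
over diagnosis/medication/lab domains and NLP features over mention
types. Feature presence is sampled at the subject level as
first-occurrence indicators — temporal placement within the pre-index
window is uniform, since first-occurrence semantics make finer temporal
structure irrelevant to every downstream statistic. Planted pairs draw
their two indicators jointly from the 2×2 cell probabilities solved from
(marginals, odds ratio) via the Plackett quadratic, per cohort, so IH
ground truth is exact; planted events are placed strictly pre-index so
censoring preserves the planted distribution. Non-planted features are
independent Bernoulli given cohort, isolating the planted signal. A
single generator seeded from the config drives all draws (byte-identical
streams per seed); we chose one vectorised global stream over per-subject
substreams for simplicity — parallel generation is out of scope.

`sample_pair_tables` draws replicate 2×2 count tables directly from the
same subject-level joint distribution without materialising dated events;
replicate studies (null calibration at 1,000 replicates, recovery at 500,
n = 20,000 per stratum) use it because the event layer provably cannot
change first-occurrence counts for planted pairs.

`make_interaction_benchmark` builds the model-ordering testbed: 8
structured features case-enriched by +0.12 prevalence (main signal), 12
structured and 8 unstructured noise features, and one
structured–unstructured pair with balanced 50% marginals in both classes
that *agrees* with probability 0.9 in cases and *disagrees* with
probability 0.9 in non-cases — an XOR-style dependency that is invisible
to any marginal score yet linearly separable for a two-split tree.
Defaults: 8,000 training subjects at 12% prevalence, 20,000 test subjects
at 1%, sizes at which the forest's gain from unstructured data is
decisively significant and the NBC's is decisively not.

### What the generator does not emulate

Real code vocabularies and their ICD-9/ICD-10 duplication, visit-type
taxonomies, age/demographic structure, temporal trends, correlated
feature blocks, and note text itself (concept-level NLP events stand in
for an NLP pipeline). Passing tests therefore demonstrate correctness of
the statistical machinery and its stated operating characteristics under
a known generative model — not performance on real clinical data, where
feature correlation and coding practice can change power and calibration.

## Numerical choices and degenerate inputs

Infeasible (marginal, OR) combinations raise a dedicated error naming the
constraint; cell solutions are validated to sum to one and reproduce the
target OR to 1e-9 relative. Degenerate contingency margins make the
chi-squared expecteds zero: per-pair operations raise, the vectorised
screen marks the pair non-significant. Tie-breaks are explicit
everywhere: |score| ranking breaks ties lexicographically; pair reports
sort by (IH, joint risk, A, B); equal-specificity cuts resolve to the
smallest. Empty selections return empty frames with the survival log, not
errors.

## Problem sizes

Replicate studies run at n = 20,000 per stratum (1,000 null replicates,
500 recovery replicates); the model-ordering benchmark at 8,000/20,000
train/test; end-to-end pipeline demonstrations at 5,000–8,000 subjects.
These desk-scale sizes keep every property measurable with comfortable
statistical margins while remaining cheap to rerun.

## Known limitations

The equal-cohort design conditions on outcome status, so IH identifies
association heterogeneity, not causal interaction. Uncorrected α = 0.05
thresholds match common screening practice but inflate family-wise error
over large pair universes. The posterior's 1/100 rescaling assumes the
1/99 population ratio rather than estimating it. The forest exposes no
per-pair attribution; IH is the interpretable complement, and agreement
between the two (pairs with high IH driving forest gains) is demonstrated
only on synthetic data.
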