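"""Compare additive NBC scores with the balanced random forest across
feature sets.

Builds a benchmark in which structured features carry the main signal and
one structured-unstructured pair interacts (agreeing in cases, disagreeing
in non-cases, marginally uninformative).  The additive NBC cannot exploit
the interaction, so adding unstructured data does not help it; the forest
conditions on feature combinations and gains substantially.
"""

import numpy as np

from ehrpairs import BrfcConfig, compare_auc, run_feature_set_comparison
from ehrpairs.simulate import make_interaction_benchmark

train, test = make_interaction_benchmark(seed=0)
print(f"train: {train.n_subjects:,} subjects ({train.labels.mean():.0%} cases), "
      f"test: {test.n_subjects:,} ({test.labels.mean():.1%} cases)")

res = run_feature_set_comparison(train, test, BrfcConfig(seed=0), n_boot=200, seed=0)
print(f"\n{'model':6s} {'features':14s} {'AUC':>6s}  95% CI")
for model in ("nbc", "brfc"):
    for fs in ("unstructured", "structured", "both"):
        r = res[(model, fs)]
        print(f"{model:6s} {fs:14s} {r.auc:6.3f}  ({r.auc_ci[0]:.3f}, {r.auc_ci[1]:.3f})")

for model in ("nbc", "brfc"):
    delta, p = compare_auc(
        res[("scores", model, "both")],
        res[("scores", model, "structured")],
        test.labels,
        seed=0,
    )
    print(f"\n{model}: AUC(both) - AUC(structured) = {delta:+.3f}, "
          f"paired-bootstrap p = {p:.3f}")

r = res[("brfc", "both")]
print("\nforest operating points (both feature sets):")
print(r.at_specificity.round(3).to_string(index=False))
print(
    "\nOnly the forest benefits from adding unstructured data — the gain"
    "\ncomes entirely from the planted structured-unstructured interaction."
)
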