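"""Check the IH test's size and power on synthetic pairs.

Under equal per-cohort odds ratios (the null) the Woolf IH statistic should
reject at its nominal level; as the odds ratios diverge, power should grow.
Tables are sampled directly from the pair's subject-level joint
distribution at n = 20,000 per stratum.
"""

import numpy as np

from ehrpairs import PlantedPair, StratifiedPair, sample_pair_tables, woolf_ih

rng = np.random.default_rng(0)
n, reps = 20_000, 400

print(f"{'or_case':>8s} {'or_noncase':>10s} {'rejection rate at a=0.05':>26s}")
for or_case in (3.0, 4.0, 6.0, 9.0):
    pair = PlantedPair("a", "b", or_case, 3.0, 0.10, 0.08, 0.15, 0.12)
    tc, tn = sample_pair_tables(pair, n, n, reps, rng)
    rej = 0
    for i in range(reps):
        _, p = woolf_ih(StratifiedPair("a", "b", tuple(tc[i]), tuple(tn[i])))
        rej += p < 0.05
    print(f"{or_case:8.1f} {3.0:10.1f} {rej / reps:26.3f}")

print(
    "\nThe first row is the null (equal odds ratios): the rate sits near the"
    "\nnominal 5%.  Power rises with the log odds-ratio gap between cohorts."
)
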