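"""Score a call set against a comparator assay: 2x2 table and PR curve.

Builds a toy 200-locus universe with 12 comparator positives, a call set
that misses one and adds two false positives, then sweeps the
calculated-VAF cutoff for the precision-recall curve.
"""

import numpy as np

from concatcall import concordance, pr_curve
from concatcall.quant import VafEstimate

rng = np.random.default_rng(0)
universe = {("s1", "AMP00", i) for i in range(200)}
positives = {("s1", "AMP00", i) for i in range(12)}
called = {("s1", "AMP00", i) for i in range(11)} | \
         {("s1", "AMP00", 150), ("s1", "AMP00", 151)}

table = concordance(called, positives, universe)
print(f"TP={table.tp} FP={table.fp} FN={table.fn} TN={table.tn}")
print(f"sensitivity {table.sensitivity * 100:.1f}%  "
      f"specificity {table.specificity * 100:.1f}%")

estimates = [
    VafEstimate(locus=loc, vrf=0.5, fold=1000.0,
                vaf=float(rng.uniform(0.05, 0.3)) if loc in positives
                else float(rng.uniform(0.0, 0.1)),
                saturated=False, classification="")
    for loc in sorted(called | positives)
]
curve = pr_curve(estimates, positives)
print(f"\nPR curve over {len(curve.cutoffs)} cutoffs, "
      f"AUC = {curve.auc * 100:.2f}%")
print("Sensitivity counts comparator positives recovered; the PR curve "
      "trades precision against recall as the estimated-VAF cutoff "
      "drops, and its AUC summarizes ranking quality.")
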