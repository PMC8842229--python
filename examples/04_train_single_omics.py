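"""Build a single-omics Ridge model under repeated stratified resampling.

The protocol: 20 stratified 70/30 splits; per split, supervised +
unsupervised selection on the training rows, then a Ridge classifier with
its penalty tuned by inner 10-fold CV AUC.  Frequency-ranked backward
elimination finds the feature-set size maximising mean hold-out AUC.
Headline numbers are the mean hold-out AUC with SD and a normal-
approximation 95% CI (mean +/- 1.96 SD / sqrt(20)).
"""

import numpy as np

from artomics.datamodel import FeatureColumn, FeatureTable
from artomics.feature_selection import FSCombination
from artomics.modeling import build_model, make_split_plan

rng = np.random.default_rng(1)
n = 135
y = np.zeros(n, dtype=int)
y[:35] = 1
X = rng.normal(size=(n, 80))
X[:, :6] += 1.8 * y[:, None]
cols = [FeatureColumn("R", "voi", f"f{j}") for j in range(80)]
table = FeatureTable(X, cols, [f"P{i}" for i in range(n)])

plan = make_split_plan(y, seed=1)
report = build_model(table, y, plan, FSCombination("fisher", "variance"),
                     name="R", k_sup=30, k_final=12)

s = report.test_summary
print(f"final model: {len(report.feature_keys)} features")
print(f"hold-out AUC {s['mean']:.3f} (SD {s['sd']:.3f}, "
      f"95% CI {s['ci_low']:.3f}-{s['ci_high']:.3f}) over {s['n']} splits")
print("elimination trajectory (size -> mean hold-out AUC):")
for size, a in report.trajectory[:6]:
    print(f"  {size:3d} -> {a:.3f}")
print("The chosen size is where the mean hold-out AUC across the 20"
      "\nresamplings peaked; informative features survive elimination"
      "\nbecause they are selected in (nearly) every iteration.")
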