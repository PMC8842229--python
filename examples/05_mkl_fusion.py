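"""Fuse heterogeneous omics blocks with multi-kernel learning.

Per block, Gaussian kernels over a range of widths and polynomial kernels
of degree 1-3 are built on the standardised features; kernels are combined
with non-negative weights proportional to their centred-kernel alignment
with the label kernel, and a kernel-ridge classifier runs on the combined
Gram matrix.  Blocks carrying no signal receive near-zero weight.
"""

import numpy as np

from artomics.modeling import auc, make_split_plan, train_mkl

rng = np.random.default_rng(2)
n = 135
y = np.zeros(n, dtype=int)
y[:35] = 1
blocks = {
    "R": rng.normal(size=(n, 10)) + 1.6 * y[:, None],  # strong signal
    "C": rng.normal(size=(n, 10)),                      # pure noise
}

plan = make_split_plan(y, seed=2)
it = plan.iterations[0]
tr, te = it.train_idx, it.test_idx
model = train_mkl({k: v[tr] for k, v in blocks.items()}, y[tr], it.fold_of_train_row)

per_block = {}
for w, spec in zip(model.weights, model.specs):
    per_block[spec.block] = per_block.get(spec.block, 0.0) + w
print("kernel weight per block:", {k: round(v, 3) for k, v in per_block.items()})
scores = model.decision({k: v[te] for k, v in blocks.items()})
print(f"hold-out AUC: {auc(scores, y[te]):.3f}")
print("Nearly all weight lands on the signal block: centred-kernel"
      "\nalignment of a noise kernel with the labels concentrates near 0.")
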