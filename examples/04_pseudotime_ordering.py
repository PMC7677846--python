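"""Order differentiating cells in pseudotime from binarized expression.

Simulates a time course in which each gene's ON probability drifts
monotonically (staggered activation waves), binarizes the matrix, and
reconstructs the cell ordering with variation-of-information distances,
connecting-cell anchors and a per-cluster probabilistic suffix tree.
"""

import numpy as np
from scipy.stats import spearmanr

from switchmodal import SimConfig, binarize, infer_pseudotime, simulate_timecourse

rng = np.random.default_rng(1)
n_genes = 1371  # ordering needs many genes; VI over few genes is noisy
cfg = SimConfig(
    n_genes=n_genes, n_cells=300, seed=1, drift=True,
    switch_up=rng.random(n_genes) < 0.5, n_timepoints=6,
)
matrix, annotation, truth = simulate_timecourse(cfg)
binary = binarize(matrix["logtpm"], truth.threshold)

order = infer_pseudotime(binary, annotation, k=100)
rank = order.rank()

print(f"cells ordered          : {len(order.order)}")
print(f"cluster blocks         : {order.cluster_labels}")
print(f"block boundaries       : {order.boundaries}")
rhos = []
for g in annotation.group_order:
    cells = list(annotation.cells_in(g))
    rho = spearmanr(rank[cells], truth.cell_time[cells]).statistic
    rhos.append(rho)
    print(f"  {g}: within-cluster Spearman(inferred, true time) = {rho:+.2f}")
print(f"mean within-cluster correlation: {np.mean(rhos):.2f}")
print("values near 1 mean the binarized VI/PST ordering recovers each")
print("timepoint's internal progression; cluster order is fixed by design.")
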