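"""Fit the reshuffling parameter Q of the semi-hierarchical folding model.

Agglomerates 120 domains into a folding tree by greedy strongest-interaction
merging, generates 'empirical' nestedness data by reshuffling the tree at a
known Q*, and recovers Q* by minimizing the Kolmogorov-Smirnov distance
between model and data nestedness distributions.
"""

import numpy as np

import chromnest as cn

rng = np.random.default_rng(0)
nd = 120
strengths = rng.random((nd, nd))
strengths = 0.5 * (strengths + strengths.T)
np.fill_diagonal(strengths, 0.0)

tree = cn.agglomerate(strengths)
rings = cn.slice_rings(tree, n_rings=8)
print(f"folding tree over {nd} domains; ring sizes (structures per level):")
print("  ", [int(np.unique(r[r >= 0]).size) for r in rings])

q_star = 0.3
empirical = cn.model_nestedness(cn.reshuffle(rings, q_star, seed=11))
fit = cn.fit_q(empirical, strengths, replicates=10, seed=21, n_rings=8)
print(f"\nplanted Q* = {q_star}, fitted Q_opt = {fit.q_opt:.2f}")
print("mean KS distance along the grid (minimum marks the fit):")
for q, d in zip(fit.q_grid[::4], fit.distances[::4]):
    print(f"  Q={q:.2f}  D={d:.3f}")
# The KS distance is minimized near the planted Q*: about 30% membership
# reshuffling per level reproduces the observed nestedness distribution.
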