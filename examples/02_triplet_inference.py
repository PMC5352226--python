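"""Bayesian topology inference for one triplet of cell types.

Generates a triplet with planted transition genes (clear minima in the
leaves), computes the posterior over the four topologies (root A, root B,
root C, or null) and prints the per-gene transition odds and role posteriors.
Every gene votes against the cell type where its mean is lowest being the
root, weighted by its odds of being a transition gene.
"""

import trilineage as tl

prior = tl.PriorConfig()  # mu in [2,14], sigma in (0,0.75], prior odds 0.05

matrix, clusters, truth = tl.generate_tree_dataset(
    [("B", "A"), ("A", "C")], n_transition=10, n_marker=5, n_irrelevant=30,
    s=2.0, sigma=0.5, m=8, seed=3,
)
data = tl.TripletData.from_matrix(matrix, clusters, ("A", "B", "C"))
result = tl.sweep_prior_odds(data, prior)

print("posterior over topologies at prior odds 0.05:")
for name, p in result.posterior_dict().items():
    print(f"  root {name}: {p:.4f}" if name != "null" else f"  null:   {p:.4f}")
print("dominant topology:", result.dominant_topology, "| confident:", result.confident)

roles = result.roles.to_frame()
print("\ntop 5 genes by transition odds (the strongest votes):")
print(roles.head(5).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    "\ntransition_class names the leaf where each gene's minimum lies;"
    "\ngenes planted as 'tr_AtoB_*' are low on the B side, 'tr_AtoC_*' on the C side."
)
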