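"""Stability of the inferred lineage tree under the model's tunable knobs.

Re-derives the tree across ranges of p(alpha=1 | beta=0), the null-topology
prior p(null), and the confidence threshold, reusing the expensive integrals.
A trustworthy tree is invariant over sensible ranges of all three; the sweep
reports where (if anywhere) the edge set first changes.  Runtime ~30 s.
"""

import trilineage as tl

matrix, clusters, truth = tl.generate_tree_dataset(
    [("A", "B"), ("B", "C"), ("B", "D"), ("D", "E"), ("D", "F")],
    n_transition=8, n_marker=4, n_irrelevant=20,
    s=2.0, sigma=0.5, m=8, seed=7,
)
config = tl.RunConfig(
    prior=tl.PriorConfig(),
    p_alpha_range=(0.25, 0.4, 0.5, 0.65),
    p_null_range=(0.1, 0.25, 0.35),
    threshold_range=(0.5, 0.55, 0.6, 0.65),
)
report = tl.stability_sweep(matrix, clusters, config)
print(report.summary())
print("\nplanted tree:", sorted(tuple(sorted(e)) for e in truth.tree.edges))
print("reference    :", sorted(tuple(sorted(e)) for e in report.reference_edges))
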