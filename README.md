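# trilineage

Inference of cell-state lineage topologies from gene expression, three cell
types at a time.

## The problem

Reconstructing a developmental lineage — which progenitor gives rise to which
cell states — from expression snapshots is hard because most genes carry no
information about lineage, and global projections (PCA, t-SNE) mix the few
informative genes with the many uninformative ones.  `trilineage` exploits a
sparse, biologically grounded pattern: within a triplet of related cell types,
*transition genes* reach a clear expression minimum in exactly one of the two
non-intermediate ("leaf") types, essentially never in the intermediate
("root").  Counting and weighing these clear-minimum genes identifies the root
of each triplet; triplet roots then act as constraints that assemble into the
full lineage graph.  The package targets bulk replicate data (e.g. sorted
microarray populations) and single-cell RNA-seq, where it couples topology
inference with iterative sparse clustering.

## The model

For a triplet of clusters (A, B, C) with log2 expression replicates
$g_i^{A,B,C}$ for gene $i$, each cluster's values for a gene are modelled as
normal in log space with mean $\mu$ and SD $\sigma$, integrated over a uniform
prior on a rectangle ($2<\mu<14$, $0<\sigma\le 0.75$ by default, trapezoidal
quadrature with steps $\delta_\mu=0.05$, $\delta_\sigma=0.01$).  A gene is a
*transition gene* ($\beta_i=1$) if one cluster's mean lies below the other
two, a *marker gene* ($\alpha_i=1$) if one cluster is high and the other two
share a low distribution, and *irrelevant* otherwise (one shared
distribution).  The topology $T \in \{A, B, C, \varnothing\}$ names the root;
its posterior is

$$p(T \mid \{g_i\}) \propto p(T)\prod_i\Bigl(1 + \tfrac{3}{2}\,
\mathcal{O}_i\,[1 - p(\mu^i_T \text{ is min} \mid g_i)]\Bigr),$$

where $\mathcal{O}_i$ is the posterior odds that gene $i$ is a transition
gene.  Every gene votes against its minimum cluster being the root, weighted
by those odds.  The only free parameter is the prior odds
$p(\beta_i{=}1)/p(\beta_i{=}0)$ (default 0.05), a sparsity knob that is swept
over $10^{-6}..10^2$; a triplet is kept for tree building only if exactly one
non-null topology exceeds probability 0.6 somewhere on the sweep.  Confident
triplets contribute root–leaf edges; an edge (X, Y) is pruned whenever some
confident triplet places an intermediate between X and Y.  Loops are allowed.
For single-cell data, clustering and inference are alternated: spectral
K-medoids over-clusters the cells, triplet inference selects high-probability
transition/marker genes, and re-clustering in that subspace repeats until the
subspace changes by less than 10% of the gene whitelist; the final K comes
from the gap statistic.

## Worked example

```python
import trilineage as tl

prior = tl.PriorConfig()
matrix, clusters, truth = tl.generate_tree_dataset(
    [("B", "A"), ("A", "C")], n_transition=10, n_marker=5, n_irrelevant=30,
    s=2.0, sigma=0.5, m=8, seed=3,
)
data = tl.TripletData.from_matrix(matrix, clusters, ("A", "B", "C"))
result = tl.sweep_prior_odds(data, prior)
print(result.posterior_dict())
print(result.dominant_topology, result.confident)
```

prints

```
{'A': 0.9997, 'B': 4.2e-55, 'C': 2.5e-53, 'null': 0.0003}
A True
```

The planted root A is recovered with posterior 0.9997; the per-gene table
(`result.roles.to_frame()`) lists each gene's transition odds and which leaf
its minimum lies in — the strongest planted genes reach odds of $10^6..10^8$,
orders of magnitude above the uninformative background.  The scripts under
`examples/` walk through each capability (pattern census, single-triplet
inference, the prior-odds sweep, tree assembly with the loop-preserving
pruning rule, the single-cell loop, and the stability sweep) and print the
numbers they compute.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a planted six-type lineage from the seed, runs the complete
method — triplet marginals, prior-odds sweeps, confident-triplet selection,
assembly and pruning — and reports progress on stderr before writing its JSON
output.  The configuration has no externally reported numeric targets, so the
JSON object is empty by design.
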