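"""Iterative clustering-inference loop for single-cell expression data.

Clustering needs the right gene subspace, and finding that subspace (the
transition and marker genes of high-probability triplets) needs a clustering.
The loop alternates the two: seed with a deliberate over-clustering (spectral
K-medoids at ``seed_k``, larger than the expected number of cell types), run
triplet inference over all clusters with enough cells, collect the genes that
are transition or marker genes with high posterior in confident triplets,
re-cluster in that subspace, and repeat until the subspace changes by less
than 10% of the whitelist.  The final number of clusters is chosen by the gap
statistic in the converged subspace, and the lineage graph is assembled from
the final confident triplets.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayes import ClusterMarginalEngine, TripletResult
from .cluster import gap_statistic_k, kmedoids_cluster
from .matrix import ClusterAssignment, ExpressionMatrix
from .priors import PriorConfig
from .tree import LineageGraph, assemble_and_prune, select_confident

logger = logging.getLogger(__name__)

__all__ = ["IterationState", "PipelineResult", "iterate_cluster_infer", "assignment_shift"]


@dataclass
class IterationState:
    """Snapshot of one iteration of the clustering-inference loop."""

    iteration: int
    clustering: ClusterAssignment
    subspace: frozenset[str]
    subspace_delta: float  # |symmetric difference with previous| / |whitelist|
    n_confident: int
    n_triplets: int


@dataclass
class PipelineResult:
    assignment: ClusterAssignment
    subspace: frozenset[str]
    triplet_results: list[TripletResult]
    graph: LineageGraph
    history: list[IterationState] = field(default_factory=list)
    converged: bool = False
    final_k: int = 0


def _eligible(assignment: ClusterAssignment, min_cluster: int) -> list[str]:
    return sorted(lab for lab, n in assignment.clusters.items() if n >= min_cluster)


def _restricted(assignment: ClusterAssignment, labels: list[str]) -> ClusterAssignment:
    keep = set(labels)
    return ClusterAssignment({s: l for s, l in assignment.labels.items() if l in keep})


def _infer_all_triplets(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    prior: PriorConfig,
    min_cluster: int,
    threshold: float,
    odds_grid,
) -> list[TripletResult]:
    labels = _eligible(assignment, min_cluster)
    if len(labels) < 3:
        raise RuntimeError(
            f"only {len(labels)} clusters have >= {min_cluster} cells; "
            "triplet inference needs at least 3 (lower min_cluster or seed_k)"
        )
    engine = ClusterMarginalEngine(matrix, _restricted(assignment, labels), prior)
    return [
        engine.sweep(trip, threshold=threshold, odds_grid=odds_grid)
        for trip in itertools.combinations(labels, 3)
    ]


def _collect_subspace(results: list[TripletResult], role_threshold: float) -> frozenset[str]:
    genes: set[str] = set()
    for r in results:
        if r.roles is None:
            continue
        keep = (r.roles.p_transition > role_threshold) | (r.roles.p_marker > role_threshold)
        genes.update(np.asarray(r.roles.gene_ids)[keep])
    return frozenset(genes)


def iterate_cluster_infer(
    matrix: ExpressionMatrix,
    seed_k: int = 40,
    final_k: int | str = "auto",
    prior: PriorConfig | None = None,
    threshold: float = 0.6,
    convergence: float = 0.10,
    min_cluster: int = 10,
    max_iter: int = 20,
    role_threshold: float = 0.8,
    metric: str = "correlation",
    seed: int = 0,
    odds_grid=None,
    gap_k_max: int | None = None,
) -> PipelineResult:
    """Run the full iterative clustering-inference loop on a single-cell matrix.

    The matrix should already be preprocessed (log2 with pseudocount, then
    90th-percentile normalization) and restricted to the gene whitelist; the
    whitelist against which subspace changes are measured is the matrix's gene
    set.  Cells in clusters smaller than ``min_cluster`` are excluded from
    triplet inference but always retained when re-clustering.

    Returns full provenance of every iteration alongside the final
    clustering, gene subspace, triplet results and pruned lineage graph.
    """
    if prior is None:
        prior = PriorConfig.for_data(matrix.values)
    whitelist = set(matrix.gene_ids)
    assignment = kmedoids_cluster(
        matrix, seed_k, metric=metric, embedding="spectral", seed=seed
    )
    history: list[IterationState] = []
    subspace: frozenset[str] = frozenset()
    converged = False
    for iteration in range(max_iter):
        results = _infer_all_triplets(
            matrix, assignment, prior, min_cluster, threshold, odds_grid
        )
        confident = select_confident(results, threshold)
        if not confident:
            raise RuntimeError(
                "no confident triplets at iteration "
                f"{iteration}: no non-null topology exceeded {threshold} for any "
                "triplet. Consider fewer seed clusters, a lower threshold, or "
                "checking that the data contain distinct cell states."
            )
        new_subspace = _collect_subspace(confident, role_threshold)
        if not new_subspace:
            raise RuntimeError(
                f"confident triplets found at iteration {iteration}, but no gene "
                f"reached role posterior {role_threshold}; lower role_threshold"
            )
        delta = len(subspace ^ new_subspace) / len(whitelist)
        history.append(
            IterationState(
                iteration=iteration,
                clustering=assignment,
                subspace=new_subspace,
                subspace_delta=delta,
                n_confident=len(confident),
                n_triplets=len(results),
            )
        )
        logger.info(
            "iteration %d: %d/%d confident triplets, subspace %d genes, delta %.3f",
            iteration, len(confident), len(results), len(new_subspace), delta,
        )
        previous = subspace
        subspace = new_subspace
        if previous and delta < convergence:
            converged = True
            break
        assignment = kmedoids_cluster(
            matrix, seed_k, metric=metric, genes=sorted(subspace), seed=seed
        )
    if not converged:
        warnings.warn(
            f"subspace did not converge below {convergence:.0%} within {max_iter} "
            "iterations; returning the last state",
            RuntimeWarning,
            stacklevel=2,
        )

    if final_k == "auto":
        from .matrix import restrict_to_genes

        sub_matrix = restrict_to_genes(matrix, sorted(subspace))
        k = gap_statistic_k(
            sub_matrix,
            k_max=gap_k_max or seed_k,
            seed=seed,
            metric=metric,
        )
        k = max(k, 3)  # triplet inference needs at least three clusters
    else:
        k = int(final_k)
    final_assignment = kmedoids_cluster(
        matrix, k, metric=metric, genes=sorted(subspace), seed=seed
    )
    final_results = _infer_all_triplets(
        matrix, final_assignment, prior, min_cluster, threshold, odds_grid
    )
    final_confident = select_confident(final_results, threshold)
    graph = assemble_and_prune(
        final_confident, extra_nodes=_eligible(final_assignment, min_cluster)
    )
    return PipelineResult(
        assignment=final_assignment,
        subspace=subspace,
        triplet_results=final_results,
        graph=graph,
        history=history,
        converged=converged,
        final_k=k,
    )


def assignment_shift(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Fraction of samples whose cluster changed between two assignments.

    Cluster labels are arbitrary, so clusters are first matched one-to-one by
    maximum overlap (Hungarian algorithm on the contingency table); the shift
    is the fraction of shared samples falling outside the matched blocks.
    """
    from scipy.optimize import linear_sum_assignment

    samples = sorted(set(a.labels) & set(b.labels))
    if not samples:
        raise ValueError("assignments share no samples")
    labs_a = sorted(a.clusters)
    labs_b = sorted(b.clusters)
    index_a = {l: i for i, l in enumerate(labs_a)}
    index_b = {l: i for i, l in enumerate(labs_b)}
    table = np.zeros((len(labs_a), len(labs_b)))
    for s in samples:
        table[index_a[a.labels[s]], index_b[b.labels[s]]] += 1
    rows, cols = linear_sum_assignment(-table)
    matched = table[rows, cols].sum()
    return 1.0 - matched / len(samples)
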