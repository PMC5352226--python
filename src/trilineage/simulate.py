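"""Synthetic expression data with planted lineage trees and gene roles.

The generator draws log2-scale expression values from normal distributions —
the same generative family the inference model assumes — around planted means:

* a *transition* gene is tagged to one direction of one tree edge and is
  expressed at the baseline everywhere except in the cell types on the far
  side of that edge, where its mean drops by the separation ``s``.  Within
  any triplet forming a path in the tree, such genes therefore show a clear
  minimum in exactly one leaf-side type;
* a *marker* gene is high (baseline + s) in exactly one cell type;
* an *irrelevant* gene shares a single mean across all types.

Defaults (s=2 log2 units, sigma=0.5, m=8 replicates) make recovery hard but
achievable at microarray-like effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ClusterAssignment, ExpressionMatrix

__all__ = ["SyntheticTruth", "generate_tree_dataset", "generate_unrelated_triplet"]

DEFAULT_BASE_MEAN = 8.0


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset."""

    tree: nx.Graph | None  # planted undirected tree (None for unrelated fixtures)
    roles: dict[str, tuple[str, str | None]]  # gene -> (role, tagged node/edge description)
    means: pd.DataFrame  # genes x cell types, planted log2 means
    sigma: float
    replicates: dict[str, int]
    seed: int

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, (r, _tag) in self.roles.items() if r == role]


def _as_tree(tree_spec) -> nx.Graph:
    if isinstance(tree_spec, nx.Graph):
        graph = nx.Graph(tree_spec)
    else:
        graph = nx.Graph()
        graph.add_edges_from((str(u), str(v)) for u, v in tree_spec)
    if graph.number_of_nodes() == 0:
        raise ValueError("tree has no nodes")
    if not nx.is_connected(graph) or graph.number_of_edges() != graph.number_of_nodes() - 1:
        raise ValueError("planted tree must be a connected acyclic graph")
    return graph


def _sample(
    means: pd.DataFrame,
    sigma: float,
    replicates: dict[str, int],
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, ClusterAssignment]:
    sample_ids, cluster_of, columns = [], {}, []
    for node in means.columns:
        m = replicates[node]
        draws = rng.normal(means[node].to_numpy()[:, None], sigma, size=(len(means), m))
        columns.append(draws)
        for j in range(m):
            sid = f"{node}_{j}"
            sample_ids.append(sid)
            cluster_of[sid] = node
    matrix = ExpressionMatrix(
        gene_ids=list(means.index),
        sample_ids=sample_ids,
        values=np.concatenate(columns, axis=1),
        cluster_of=cluster_of,
    )
    return matrix, ClusterAssignment(cluster_of)


def generate_tree_dataset(
    tree_spec,
    n_transition: int = 20,
    n_marker: int = 10,
    n_irrelevant: int = 100,
    s: float = 2.0,
    sigma: float = 0.5,
    m: int | dict[str, int] = 8,
    seed: int = 0,
    base_mean: float = DEFAULT_BASE_MEAN,
    dropout: float = 0.0,
) -> tuple[ExpressionMatrix, ClusterAssignment, SyntheticTruth]:
    """Generate a dataset whose cell types follow a planted lineage tree.

    Parameters
    ----------
    tree_spec
        Edge list or ``networkx.Graph`` over cell-type labels; must be a tree.
    n_transition
        Transition genes per edge *per direction* (each edge gets
        ``2 * n_transition`` genes, half low on each side).
    n_marker
        Marker genes per cell type (high in that type only).
    n_irrelevant
        Genes with one shared mean across all types, drawn per gene uniformly
        within +-1 log2 unit of ``base_mean``.
    s
        Separation in log2 units between baseline and the shifted mean; must
        be positive, otherwise planted patterns are degenerate.
    sigma, m
        Replicate noise SD (log2 units) and replicates per type (int or map).
    dropout
        Optional Bernoulli zeroing probability for stress tests (default off).
    """
    if s <= 0:
        raise ValueError("separation s must be positive (s=0 plants no pattern)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    tree = _as_tree(tree_spec)
    nodes = sorted(tree.nodes)
    replicates = {n: (m[n] if isinstance(m, dict) else int(m)) for n in nodes}
    if any(v < 1 for v in replicates.values()):
        raise ValueError("each cell type needs at least one replicate")
    rng = np.random.default_rng(seed)

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    roles: dict[str, tuple[str, str | None]] = {}

    def far_side(u: str, v: str) -> set[str]:
        # nodes in the component of v once edge (u, v) is removed
        cut = nx.Graph(tree)
        cut.remove_edge(u, v)
        return nx.node_connected_component(cut, v)

    for u, v in sorted(tuple(sorted(e)) for e in tree.edges):
        for near, far in ((u, v), (v, u)):
            low = far_side(near, far)
            for j in range(n_transition):
                gene = f"tr_{near}to{far}_{j}"
                gene_ids.append(gene)
                roles[gene] = ("transition", f"{near}->{far}")
                rows.append(
                    np.array([base_mean - s if n in low else base_mean for n in nodes])
                )
    for node in nodes:
        for j in range(n_marker):
            gene = f"mk_{node}_{j}"
            gene_ids.append(gene)
            roles[gene] = ("marker", node)
            rows.append(np.array([base_mean + s if n == node else base_mean for n in nodes]))
    for j in range(n_irrelevant):
        gene = f"ir_{j}"
        gene_ids.append(gene)
        roles[gene] = ("irrelevant", None)
        rows.append(np.full(len(nodes), base_mean + rng.uniform(-1.0, 1.0)))

    means = pd.DataFrame(np.array(rows), index=gene_ids, columns=nodes)
    matrix, assignment = _sample(means, sigma, replicates, rng)
    if dropout > 0:
        mask = rng.random(matrix.values.shape) < dropout
        matrix.values[mask] = 0.0
    truth = SyntheticTruth(
        tree=tree, roles=roles, means=means, sigma=sigma, replicates=replicates, seed=seed
    )
    return matrix, assignment, truth


def generate_unrelated_triplet(
    n_genes: int = 60,
    s: float = 2.0,
    sigma: float = 0.5,
    m: int = 8,
    seed: int = 0,
    labels: tuple[str, str, str] = ("X1", "X2", "X3"),
    base_mean: float = DEFAULT_BASE_MEAN,
) -> tuple[ExpressionMatrix, ClusterAssignment, SyntheticTruth]:
    """Three cell types with clear minima spread evenly across them.

    Every gene is low (baseline - s) in exactly one type, assigned
    round-robin, so no topology is favored: the expected outcome of triplet
    inference is the null topology, and the minima-fraction entropy is close
    to ln 3.
    """
    if s <= 0:
        raise ValueError("separation s must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(set(labels)) != 3:
        raise ValueError("labels must be three distinct cell types")
    rng = np.random.default_rng(seed)
    rows, gene_ids, roles = [], [], {}
    for j in range(n_genes):
        low = j % 3
        gene = f"un_{labels[low]}_{j}"
        gene_ids.append(gene)
        roles[gene] = ("transition", f"min-in-{labels[low]}")
        rows.append(np.array([base_mean - s if i == low else base_mean for i in range(3)]))
    means = pd.DataFrame(np.array(rows), index=gene_ids, columns=list(labels))
    replicates = {lab: int(m) for lab in labels}
    matrix, assignment = _sample(means, sigma, replicates, rng)
    truth = SyntheticTruth(
        tree=None, roles=roles, means=means, sigma=sigma, replicates=replicates, seed=seed
    )
    return matrix, assignment, truth
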