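"""Assemble confident triplet topologies into an undirected lineage graph.

Each confident triplet with root R and leaves X, Y contributes the candidate
edges R-X and R-Y.  The pruning rule then removes any candidate edge (X, Y)
for which some confident triplet places an intermediate between X and Y
(i.e. has X and Y as its two leaves): such a pair cannot be nearest
neighbors.  Pruning is applied to all triplets simultaneously, so the result
is independent of input order, and loops are deliberately not broken — the
rule never assumes the lineage is acyclic.

No direction is assigned to edges: only triplet topologies are inferred, not
temporal orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["LineageGraph", "select_confident", "assemble_and_prune", "export_graph", "load_edgelist"]


@dataclass
class LineageGraph:
    """Undirected graph over cluster labels with full assembly provenance."""

    graph: nx.Graph
    provenance: dict[frozenset, list[tuple[str, str, str]]] = field(default_factory=dict)
    pruned: list[tuple[frozenset, tuple[str, str, str]]] = field(default_factory=list)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def supporting_triplets(self, u: str, v: str) -> list[tuple[str, str, str]]:
        return list(self.provenance.get(frozenset((u, v)), []))


def _as_rooted(triplet) -> tuple[str, str, str]:
    """Normalize input to (root, leaf1, leaf2)."""
    if hasattr(triplet, "dominant_topology"):  # TripletResult
        root = triplet.dominant_topology
        if root not in triplet.labels:
            raise ValueError(
                f"triplet {triplet.labels} has no confident non-null topology ({root})"
            )
        leaves = tuple(l for l in triplet.labels if l != root)
        return (root, *leaves)
    if hasattr(triplet, "root"):  # LabeledTriplet
        return (triplet.root, *triplet.leaves)
    root, a, b = triplet
    return (str(root), str(a), str(b))


def select_confident(results, threshold: float = 0.6):
    """Keep triplets whose sweep shows exactly one non-null topology above threshold."""
    kept = []
    for r in results:
        dominant, confident = r.dominant_at(threshold)
        if confident:
            kept.append(r)
    return kept


def assemble_and_prune(triplets, extra_nodes=None) -> LineageGraph:
    """Build the lineage graph from rooted triplets and apply the pruning rule.

    ``triplets`` may be confident :class:`~trilineage.bayes.TripletResult`
    objects, :class:`~trilineage.census.LabeledTriplet` objects, or plain
    ``(root, leaf1, leaf2)`` tuples.  ``extra_nodes`` adds isolated nodes for
    clusters that appear only in null or ambiguous triplets.
    """
    rooted = [_as_rooted(t) for t in triplets]
    provenance: dict[frozenset, list[tuple[str, str, str]]] = {}
    for root, a, b in rooted:
        for leaf in (a, b):
            provenance.setdefault(frozenset((root, leaf)), []).append((root, a, b))

    # an edge (X, Y) is vetoed when some triplet has X and Y as its two leaves
    vetoes: dict[frozenset, tuple[str, str, str]] = {}
    for root, a, b in rooted:
        vetoes.setdefault(frozenset((a, b)), (root, a, b))

    graph = nx.Graph()
    pruned: list[tuple[frozenset, tuple[str, str, str]]] = []
    for root, a, b in rooted:
        graph.add_node(root)
        graph.add_node(a)
        graph.add_node(b)
    for edge, support in provenance.items():
        if edge in vetoes:
            pruned.append((edge, vetoes[edge]))
        else:
            graph.add_edge(*sorted(edge))
    for edge, witness in pruned:
        u, v = sorted(edge)
        logger.warning(
            "pruned edge %s-%s (supported by %d triplet(s)): triplet %s places an "
            "intermediate between them",
            u, v, len(provenance[edge]), witness,
        )
    if extra_nodes:
        isolated = [n for n in extra_nodes if n not in graph]
        if isolated:
            logger.warning(
                "clusters only seen in null/ambiguous triplets added as isolated nodes: %s",
                sorted(isolated),
            )
            graph.add_nodes_from(isolated)
    return LineageGraph(graph=graph, provenance=provenance, pruned=pruned)


def export_graph(g: LineageGraph, path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or a 2-column tab-separated edge list."""
    if fmt == "graphml":
        nx.write_graphml(g.graph, path)
    elif fmt == "edgelist":
        with open(path, "w") as handle:
            for u, v in sorted(tuple(sorted(e)) for e in g.graph.edges):
                handle.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'edgelist'")


def load_edgelist(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as handle:
        for line in handle:
            parts = line.strip().split("\t")
            if len(parts) >= 2:
                graph.add_edge(parts[0], parts[1])
    return graph
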