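"""Assemble confident triplet topologies into a lineage graph with pruning.

Two classic worked cases: four triplets over {LT, ST, MPP, CMP} collapse to
the path/fork LT - ST - {CMP, MPP} (the LT-CMP and LT-MPP candidate edges are
pruned because ST is an inferred intermediate), and a seven-triplet set whose
assembly contains a five-node loop the pruning rule deliberately leaves
intact — no triplet testifies against any loop edge, and the rule never
assumes the lineage is a tree.
"""

import trilineage as tl

four = [
    ("LT", "CMP", "MPP"),  # root LT
    ("ST", "LT", "CMP"),   # root ST
    ("ST", "LT", "MPP"),   # root ST
    ("ST", "CMP", "MPP"),  # root ST
]
graph = tl.assemble_and_prune(four)
print("four-triplet example")
print("  edges:", sorted(tuple(sorted(e)) for e in graph.edges))
print("  pruned:", sorted(tuple(sorted(e)) for e, _w in graph.pruned))

loop = [
    ("ST", "CMP", "MPP"),
    ("CMP", "ST", "GMP"),
    ("MPP", "ST", "MLP"),
    ("MLP", "MPP", "GMP"),
    ("ST", "LT", "CMP"),
    ("ST", "LT", "MPP"),
    ("ST", "LT", "GMP"),
]
graph = tl.assemble_and_prune(loop)
print("\nseven-triplet loop example")
print("  edges:", sorted(tuple(sorted(e)) for e in graph.edges))
import networkx as nx

print("  cycles retained:", nx.cycle_basis(graph.graph))
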