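"""Stability of the inferred lineage graph under the model's tunable knobs.

The tree-building step has a handful of parameters beyond the prior odds:
p(alpha=1 | beta=0), the null-topology prior p(null), and the confidence
threshold for selecting triplets.  A stability sweep re-derives the lineage
graph across ranges of each and reports whether the edge set is invariant and
where it first changes.  The expensive per-triplet marginals are computed
once and shared across every grid point, since none of these knobs enters the
integrals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .bayes import ClusterMarginalEngine, sweep_prior_odds
from .matrix import ClusterAssignment, ExpressionMatrix
from .priors import PriorConfig, topology_prior_with_null
from .tree import assemble_and_prune, select_confident

__all__ = ["RunConfig", "StabilityReport", "stability_sweep"]


@dataclass
class RunConfig:
    """Bundle of priors, thresholds and sweep ranges for a full analysis."""

    prior: PriorConfig = field(default_factory=PriorConfig)
    triplet_threshold: float = 0.6
    role_threshold: float = 0.8
    p_alpha_range: tuple[float, ...] = ()
    p_null_range: tuple[float, ...] = ()
    threshold_range: tuple[float, ...] = ()
    seed_k_range: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("p_alpha_range", "p_null_range"):
            if any(not 0.0 <= v <= 1.0 for v in getattr(self, name)):
                raise ValueError(f"{name} values must be probabilities in [0, 1]")
        if any(not 0.0 < v < 1.0 for v in self.threshold_range):
            raise ValueError("threshold_range values must be in (0, 1)")


@dataclass
class StabilityReport:
    reference_edges: frozenset
    edges_by_setting: dict[str, dict[float, frozenset]]
    invariant: dict[str, bool]
    breakpoints: dict[str, list[float]]

    def summary(self) -> str:
        lines = [f"reference tree: {len(self.reference_edges)} edges"]
        for param, by_value in self.edges_by_setting.items():
            status = "invariant" if self.invariant[param] else (
                f"changes at {self.breakpoints[param]}"
            )
            values = sorted(by_value)
            lines.append(f"  {param} over {values}: {status}")
        return "\n".join(lines)


def _edges(confident, all_nodes) -> frozenset:
    graph = assemble_and_prune(confident, extra_nodes=all_nodes)
    return frozenset(graph.edges)


def stability_sweep(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    config: RunConfig,
    min_cluster: int = 2,
    odds_grid=None,
) -> StabilityReport:
    """Re-derive the lineage graph across each configured parameter range.

    The dataset must have at least 4 clusters (otherwise there is a single
    triplet and no tree to stabilize).  Per-triplet marginals are computed
    once; each grid point only redoes the cheap posterior algebra and the
    assembly/pruning step.
    """
    labels = sorted(lab for lab, n in assignment.clusters.items() if n >= min_cluster)
    if len(labels) < 4:
        raise ValueError(f"stability analysis needs >= 4 clusters, got {len(labels)}")
    engine = ClusterMarginalEngine(matrix, assignment, config.prior)
    marginals = {trip: engine.marginals(trip) for trip in itertools.combinations(labels, 3)}

    def tree_for(prior: PriorConfig, threshold: float) -> frozenset:
        results = [
            sweep_prior_odds(marg, prior, threshold=threshold,
                             compute_roles=False, odds_grid=odds_grid)
            for marg in marginals.values()
        ]
        return _edges(select_confident(results, threshold), labels)

    reference = tree_for(config.prior, config.triplet_threshold)
    edges_by_setting: dict[str, dict[float, frozenset]] = {}
    invariant: dict[str, bool] = {}
    breakpoints: dict[str, list[float]] = {}

    sweeps = {
        "p_alpha_given_not_beta": (
            config.p_alpha_range,
            lambda v: (config.prior.replace(p_alpha_given_not_beta=v), config.triplet_threshold),
        ),
        "p_null": (
            config.p_null_range,
            lambda v: (
                config.prior.replace(topology_prior=topology_prior_with_null(v)),
                config.triplet_threshold,
            ),
        ),
        "threshold": (
            config.threshold_range,
            lambda v: (config.prior, v),
        ),
    }
    for param, (values, make) in sweeps.items():
        if not values:
            continue
        by_value: dict[float, frozenset] = {}
        for v in values:
            prior_v, threshold_v = make(v)
            by_value[v] = tree_for(prior_v, threshold_v)
        edges_by_setting[param] = by_value
        diffs = [v for v, e in by_value.items() if e != reference]
        invariant[param] = not diffs
        breakpoints[param] = sorted(diffs)
    return StabilityReport(
        reference_edges=reference,
        edges_by_setting=edges_by_setting,
        invariant=invariant,
        breakpoints=breakpoints,
    )
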