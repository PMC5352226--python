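"""Topology posteriors, transition-gene odds and gene-role posteriors.

Given a triplet of cell clusters (A, B, C), the topology T names the cluster
in the middle of the lineage relationship (progenitor or intermediate), or is
null when the expression data carry no topology-consistent structure.  Each
gene contributes one factor to the posterior

    p(T | data)  propto  p(T) * prod_i (1 + O_i * p(g_i | T, beta=1) / p(g_i | beta=1)),

where ``O_i`` is the odds that gene i is a transition gene (one with a clear
expression minimum in a single cluster).  For a non-null T the gene factor
reduces to ``1 + (3/2) O_i [1 - p(mu_T is min | g_i)]``: every gene casts a
vote against its minimum cluster being the root, weighted by its odds of
being a transition gene.  The only free parameter is the prior odds
p(beta=1)/p(beta=0), a sparsity knob; sweeping it and demanding a unique
non-null topology above a probability threshold yields the confident triplets
used for tree assembly.

All expensive integrals live in :class:`~trilineage.integrate.GeneMarginals`
and are independent of the prior odds and of the topology prior, so sweeps
and stability analyses reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .integrate import (
    GeneMarginals,
    GridTables,
    _log_f_from_stats,
    _log_tail,
    _suff_stats,
    compute_triplet_marginals,
    pooled_log_marginal,
)
from .matrix import ClusterAssignment, ExpressionMatrix
from .priors import PriorConfig

__all__ = [
    "NULL",
    "TripletData",
    "TripletResult",
    "GeneRolePosterior",
    "ClusterMarginalEngine",
    "marginal_irrelevant",
    "marginal_min_constrained",
    "marginal_transition",
    "marginal_marker",
    "transition_odds",
    "prob_min",
    "topology_posterior",
    "gene_role_posterior",
    "sweep_prior_odds",
    "restrict_top_n",
    "default_odds_grid",
]

NULL = "null"


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TripletData:
    """Replicate expression values of one gene set across three clusters."""

    labels: tuple[str, str, str]
    gene_ids: list[str]
    blocks: tuple[np.ndarray, np.ndarray, np.ndarray]  # each (n_genes, m_c)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 3:
            raise ValueError("triplet labels must be three distinct cluster labels")
        blocks = tuple(np.atleast_2d(np.asarray(b, dtype=float)) for b in self.blocks)
        n = len(self.gene_ids)
        if any(b.shape[0] != n for b in blocks):
            raise ValueError("block row counts must equal the number of gene ids")
        object.__setattr__(self, "blocks", blocks)

    @property
    def replicate_counts(self) -> tuple[int, int, int]:
        return tuple(b.shape[1] for b in self.blocks)

    @classmethod
    def from_matrix(
        cls,
        matrix: ExpressionMatrix,
        assignment: ClusterAssignment,
        labels: tuple[str, str, str],
    ) -> "TripletData":
        blocks = tuple(matrix.columns_for(assignment.members(lab)) for lab in labels)
        return cls(labels=tuple(labels), gene_ids=list(matrix.gene_ids), blocks=blocks)

    def marginals(self, prior: PriorConfig, tables: GridTables | None = None) -> GeneMarginals:
        return compute_triplet_marginals(
            self.blocks, prior, labels=self.labels, gene_ids=self.gene_ids, tables=tables
        )


@dataclass
class GeneRolePosterior:
    """Per-gene posterior over (transition, marker, irrelevant), given a topology."""

    topology: str  # root cluster label the roles are conditioned on
    labels: tuple[str, str, str]
    gene_ids: list[str]
    p_transition: np.ndarray
    p_marker: np.ndarray
    p_irrelevant: np.ndarray
    odds: np.ndarray
    transition_class: list[str]  # leaf cluster in which the gene's mean is minimal
    marker_class: list[str]  # cluster in which the gene is high

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "odds": self.odds,
                "p_transition": self.p_transition,
                "p_marker": self.p_marker,
                "p_irrelevant": self.p_irrelevant,
                "transition_class": self.transition_class,
                "marker_class": self.marker_class,
            }
        ).sort_values("odds", ascending=False, kind="stable", ignore_index=True)


@dataclass
class TripletResult:
    """Posterior over topologies for one triplet, with its prior-odds sweep."""

    labels: tuple[str, str, str]
    posterior: np.ndarray  # (4,) at prior_odds, ordered (labels..., null)
    prior_odds: float
    odds_grid: np.ndarray | None = None
    sweep: np.ndarray | None = None  # (len(odds_grid), 4)
    dominant_topology: str = NULL  # cluster label, "null" or "ambiguous"
    confident: bool = False
    threshold: float = 0.6
    roles: GeneRolePosterior | None = None
    gene_odds: np.ndarray | None = None
    gene_ids: list[str] | None = None
    marginals: GeneMarginals | None = field(default=None, repr=False)

    @property
    def topology_names(self) -> tuple[str, str, str, str]:
        return (*self.labels, NULL)

    def posterior_dict(self) -> dict[str, float]:
        return dict(zip(self.topology_names, map(float, self.posterior)))

    @property
    def max_nonnull(self) -> float:
        """Largest non-null posterior reached anywhere on the sweep."""
        source = self.sweep if self.sweep is not None else self.posterior[None, :]
        return float(np.max(source[:, :3]))

    def dominant_at(self, threshold: float) -> tuple[str, bool]:
        """(dominant topology, confident) re-evaluated at a different threshold."""
        source = self.sweep if self.sweep is not None else self.posterior[None, :]
        reached = [self.labels[t] for t in range(3) if np.max(source[:, t]) > threshold]
        if len(reached) == 1:
            return reached[0], True
        if len(reached) > 1:
            return "ambiguous", False
        return NULL, False


# ---------------------------------------------------------------------------
# posterior algebra on cached marginals
# ---------------------------------------------------------------------------

def _as_marginals(data, prior: PriorConfig) -> GeneMarginals:
    if isinstance(data, GeneMarginals):
        return data
    if isinstance(data, TripletData):
        return data.marginals(prior)
    raise TypeError(f"expected TripletData or GeneMarginals, got {type(data).__name__}")


def _log_weighted(logs: np.ndarray, weights) -> np.ndarray:
    """logsumexp of columns of ``logs`` (stacked on axis 0) with given weights."""
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    if not keep.any():
        raise ValueError("all mixture weights are zero")
    return logsumexp(logs[keep], axis=0, b=w[keep, None])


def log_p_beta1(marg: GeneMarginals, topology_prior=(0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    """log p(g | beta=1): topology-prior-weighted mixture of the transition marginals.

    With the uniform topology prior this equals the mean of the three
    min-constrained marginals.
    """
    logs = np.stack([marg.log_transition(t) for t in range(4)])
    return _log_weighted(logs, topology_prior)


def log_p_beta0(marg: GeneMarginals, p_alpha_given_not_beta: float = 0.5) -> np.ndarray:
    """log p(g | beta=0): marker/irrelevant mixture."""
    pa = p_alpha_given_not_beta
    logs = np.stack([marg.log_marker, marg.log_irrelevant])
    return _log_weighted(logs, (pa, 1.0 - pa))


def transition_odds(data, prior: PriorConfig, prior_odds: float | None = None) -> np.ndarray:
    """Odds O_i that each gene is a transition gene, given the data."""
    marg = _as_marginals(data, prior)
    po = prior.prior_odds_beta if prior_odds is None else prior_odds
    if po == 0.0:
        return np.zeros(marg.n_genes)
    ratio = log_p_beta1(marg, prior.topology_prior) - log_p_beta0(marg, prior.p_alpha_given_not_beta)
    return po * np.exp(ratio)


def prob_min(data, cell, prior: PriorConfig) -> np.ndarray:
    """p(mu_cell is the minimum mean | g, beta=1), per gene; sums to 1 over cells."""
    marg = _as_marginals(data, prior)
    xi = marg.labels.index(cell) if isinstance(cell, str) else int(cell)
    return np.exp(marg.log_min[:, xi] - logsumexp(marg.log_min, axis=1))


def topology_posterior(data, prior: PriorConfig, prior_odds: float | None = None) -> np.ndarray:
    """Posterior over (A, B, C, null) given all genes, at one value of the prior odds."""
    marg = _as_marginals(data, prior)
    po = prior.prior_odds_beta if prior_odds is None else prior_odds
    return _posterior_from_marginals(marg, prior, po)


def _posterior_from_marginals(marg: GeneMarginals, prior: PriorConfig, po: float) -> np.ndarray:
    tp = np.asarray(prior.topology_prior, dtype=float)
    with np.errstate(divide="ignore"):
        log_post = np.log(tp)
    if po > 0.0:
        lp0 = log_p_beta0(marg, prior.p_alpha_given_not_beta)
        log_po = np.log(po)
        for t in range(4):
            if tp[t] == 0.0:
                continue
            # log(1 + po * p(g|T,beta=1)/p(g|beta=0)), accumulated in log space
            log_post[t] += float(np.sum(np.logaddexp(0.0, log_po + marg.log_transition(t) - lp0)))
    log_post -= logsumexp(log_post)
    return np.exp(log_post)


def _sweep_from_marginals(
    marg: GeneMarginals, prior: PriorConfig, odds_grid: np.ndarray
) -> np.ndarray:
    tp = np.asarray(prior.topology_prior, dtype=float)
    lp0 = log_p_beta0(marg, prior.p_alpha_given_not_beta)
    log_ratio = np.stack([marg.log_transition(t) - lp0 for t in range(4)])  # (4, genes)
    out = np.empty((len(odds_grid), 4))
    with np.errstate(divide="ignore"):
        log_tp = np.log(tp)
    for j, po in enumerate(odds_grid):
        if po == 0.0:
            log_post = log_tp.copy()
        else:
            factors = np.logaddexp(0.0, np.log(po) + log_ratio).sum(axis=1)
            log_post = np.where(tp > 0.0, log_tp + factors, -np.inf)
        log_post = log_post - logsumexp(log_post)
        out[j] = np.exp(log_post)
    return out


def gene_role_posterior(data, topology, prior: PriorConfig) -> GeneRolePosterior:
    """Posterior over (transition, marker, irrelevant) per gene, given root ``topology``."""
    marg = _as_marginals(data, prior)
    t_idx = marg.labels.index(topology) if isinstance(topology, str) else int(topology)
    if t_idx not in (0, 1, 2):
        raise ValueError("gene roles are conditioned on a non-null topology")
    po = prior.prior_odds_beta
    p_beta1 = po / (1.0 + po)
    pa = prior.p_alpha_given_not_beta
    weights = np.array([p_beta1, (1.0 - p_beta1) * pa, (1.0 - p_beta1) * (1.0 - pa)])
    with np.errstate(divide="ignore"):
        logs = np.stack(
            [marg.log_transition(t_idx), marg.log_marker, marg.log_irrelevant]
        ) + np.log(weights)[:, None]
    logs -= logsumexp(logs, axis=0)
    p = np.exp(logs)

    leaves = [i for i in range(3) if i != t_idx]
    leaf_min = np.where(
        marg.log_min[:, leaves[0]] >= marg.log_min[:, leaves[1]], leaves[0], leaves[1]
    )
    transition_class = [marg.labels[i] for i in leaf_min]
    marker_class = [marg.labels[i] for i in np.argmax(marg.log_marker_parts, axis=1)]
    return GeneRolePosterior(
        topology=marg.labels[t_idx],
        labels=marg.labels,
        gene_ids=list(marg.gene_ids),
        p_transition=p[0],
        p_marker=p[1],
        p_irrelevant=p[2],
        odds=transition_odds(marg, prior),
        transition_class=transition_class,
        marker_class=marker_class,
    )


def default_odds_grid(low: float = 1e-6, high: float = 1e2, per_decade: int = 9) -> np.ndarray:
    """Log-spaced prior-odds grid, 9 points per decade from 1e-6 to 1e2 by default."""
    decades = np.log10(high) - np.log10(low)
    n = int(round(decades * per_decade)) + 1
    return np.logspace(np.log10(low), np.log10(high), n)


def sweep_prior_odds(
    data,
    prior: PriorConfig,
    odds_grid: np.ndarray | None = None,
    threshold: float = 0.6,
    compute_roles: bool = True,
) -> TripletResult:
    """Full triplet inference: posterior across the prior-odds sweep plus gene roles.

    The dominant topology is the unique non-null topology whose posterior
    exceeds ``threshold`` somewhere on the grid; if two different non-null
    topologies each reach the threshold at different odds the triplet is
    ambiguous and excluded from tree building.
    """
    marg = _as_marginals(data, prior)
    grid = default_odds_grid() if odds_grid is None else np.asarray(odds_grid, dtype=float)
    sweep = _sweep_from_marginals(marg, prior, grid)
    posterior = _posterior_from_marginals(marg, prior, prior.prior_odds_beta)
    result = TripletResult(
        labels=marg.labels,
        posterior=posterior,
        prior_odds=prior.prior_odds_beta,
        odds_grid=grid,
        sweep=sweep,
        threshold=threshold,
        gene_odds=transition_odds(marg, prior),
        gene_ids=list(marg.gene_ids),
        marginals=marg,
    )
    result.dominant_topology, result.confident = result.dominant_at(threshold)
    if compute_roles and result.confident:
        result.roles = gene_role_posterior(marg, result.dominant_topology, prior)
    return result


def restrict_top_n(data, n: int, prior: PriorConfig, return_genes: bool = False):
    """Topology posterior recomputed from only the n genes with the greatest odds.

    Genes are ranked by their transition-gene odds, which are agnostic of any
    particular topology; ties keep the original gene order.
    """
    marg = _as_marginals(data, prior)
    if not 1 <= n <= marg.n_genes:
        raise ValueError(f"n must be in [1, {marg.n_genes}]")
    odds = transition_odds(marg, prior)
    order = np.argsort(-odds, kind="stable")[:n]
    sub = marg.take(np.sort(order))
    posterior = _posterior_from_marginals(sub, prior, prior.prior_odds_beta)
    if return_genes:
        return posterior, list(sub.gene_ids)
    return posterior


# ---------------------------------------------------------------------------
# spec-level marginal operations (single gene)
# ---------------------------------------------------------------------------

def marginal_irrelevant(g_all, prior: PriorConfig) -> float:
    """Log marginal of pooled replicates under a single shared distribution."""
    return pooled_log_marginal(g_all, prior)


def _single_gene_marginals(g_a, g_b, g_c, prior: PriorConfig) -> GeneMarginals:
    blocks = [np.atleast_1d(np.asarray(g, dtype=float))[None, :] for g in (g_a, g_b, g_c)]
    return compute_triplet_marginals(blocks, prior)


def marginal_min_constrained(g_a, g_b, g_c, min_cell, prior: PriorConfig) -> float:
    """Log marginal with the named cluster's mean constrained below the other two."""
    marg = _single_gene_marginals(g_a, g_b, g_c, prior)
    xi = {"A": 0, "B": 1, "C": 2}.get(min_cell, min_cell)
    return float(marg.log_min[0, int(xi)])


def marginal_transition(g_a, g_b, g_c, topology, prior: PriorConfig) -> float:
    """Log marginal under topology T (root in {A,B,C}) or the null topology."""
    marg = _single_gene_marginals(g_a, g_b, g_c, prior)
    t = {"A": 0, "B": 1, "C": 2, NULL: 3, None: 3}.get(topology, topology)
    return float(marg.log_transition(int(t))[0])


def marginal_marker(g_a, g_b, g_c, prior: PriorConfig) -> float:
    """Log marginal under the marker model (one cluster high, two pooled low)."""
    marg = _single_gene_marginals(g_a, g_b, g_c, prior)
    return float(marg.log_marker[0])


# ---------------------------------------------------------------------------
# engine over a clustered matrix: shared tables across many triplets
# ---------------------------------------------------------------------------

class ClusterMarginalEngine:
    """Computes GeneMarginals for any triplet of clusters of one matrix.

    Per-cluster and per-pair density tables are cached, so inference over all
    triplets of a clustering costs far less than treating each triplet
    independently.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        assignment: ClusterAssignment,
        prior: PriorConfig,
        max_pair_cache: int = 512,
    ):
        self.matrix = matrix
        self.assignment = assignment
        self.prior = prior
        self.tables = GridTables(prior)
        self.gene_ids = list(matrix.gene_ids)
        if not np.isfinite(matrix.values).all():
            bad = np.nonzero(~np.isfinite(matrix.values).all(axis=1))[0][0]
            raise ValueError(f"non-finite expression values for gene {matrix.gene_ids[bad]!r}")
        self._stats: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        for label in assignment.clusters:
            cols = matrix.columns_for(assignment.members(label))
            self._stats[label] = _suff_stats(cols)
        self._single: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._pair: dict[frozenset, np.ndarray] = {}
        self._max_pair_cache = max_pair_cache

    @property
    def cluster_labels(self) -> list[str]:
        return list(self._stats)

    def _single_tables(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        if label not in self._single:
            m, s, ssq = self._stats[label]
            log_f = _log_f_from_stats(m, s, ssq, self.tables)
            self._single[label] = (log_f, _log_tail(log_f, self.prior.d_mu))
        return self._single[label]

    def _pair_table(self, a: str, b: str) -> np.ndarray:
        key = frozenset((a, b))
        if key not in self._pair:
            if len(self._pair) >= self._max_pair_cache:
                self._pair.pop(next(iter(self._pair)))
            ma, sa, qa = self._stats[a]
            mb, sb, qb = self._stats[b]
            self._pair[key] = _log_f_from_stats(ma + mb, sa + sb, qa + qb, self.tables)
        return self._pair[key]

    def marginals(self, labels: tuple[str, str, str]) -> GeneMarginals:
        if len(set(labels)) != 3:
            raise ValueError("need three distinct cluster labels")
        t = self.tables
        n_genes = len(self.gene_ids)
        singles = [self._single_tables(lab) for lab in labels]

        log_min = np.empty((n_genes, 3))
        for xi in range(3):
            others = [i for i in range(3) if i != xi]
            integrand = t.lw_mu + singles[xi][0] + singles[others[0]][1] + singles[others[1]][1]
            log_min[:, xi] = logsumexp(integrand, axis=1) - t.log_z_min

        log_marker_parts = np.empty((n_genes, 3))
        for hi in range(3):
            lo = [labels[i] for i in range(3) if i != hi]
            integrand = t.lw_mu + self._pair_table(*lo) + singles[hi][1]
            log_marker_parts[:, hi] = logsumexp(integrand, axis=1) - t.log_z_pair
        log_marker = logsumexp(log_marker_parts, axis=1) - np.log(3.0)

        stats = [self._stats[lab] for lab in labels]
        m_all = sum(st[0] for st in stats)
        s_all = stats[0][1] + stats[1][1] + stats[2][1]
        q_all = stats[0][2] + stats[1][2] + stats[2][2]
        log_f_all = _log_f_from_stats(m_all, s_all, q_all, t)
        log_irr = logsumexp(t.lw_mu + log_f_all, axis=1) - t.log_z_full

        return GeneMarginals(
            labels=tuple(labels),
            gene_ids=list(self.gene_ids),
            log_min=log_min,
            log_marker_parts=log_marker_parts,
            log_marker=log_marker,
            log_irrelevant=log_irr,
        )

    def sweep(self, labels: tuple[str, str, str], **kwargs) -> TripletResult:
        return sweep_prior_odds(self.marginals(labels), self.prior, **kwargs)
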