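"""Pattern census over labeled triplets: clear minima, clear maxima, entropy.

A gene shows the *clear minimum* pattern within a triplet of cell types when
its expression distribution in one cell type sits significantly below both
others (two two-sample t-tests, each p < alpha, default 0.005), and the
*clear maximum* pattern symmetrically for the highest cell type.  Counting
these patterns across triplets with known lineage roots is the discovery
statistic behind the whole framework: in related triplets the clear minima
concentrate in the leaf cell types, never the root, while in unrelated
triplets the minima spread evenly over the three cell types — which the
entropy of the per-cell-type minima fractions quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .matrix import ClusterAssignment, ExpressionMatrix

__all__ = [
    "LabeledTriplet",
    "PatternFlags",
    "PatternCensus",
    "classify_gene",
    "census_triplet",
    "entropy_of_minima",
    "relatedness_score",
]


@dataclass(frozen=True)
class LabeledTriplet:
    """A triplet with a known root (intermediate/progenitor) and two leaves.

    Even for a linear progression B -> A -> C the middle type A is the root.
    """

    root: str
    leaves: tuple[str, str]
    length: int | None = None  # steps separating the members on a reference tree
    is_terminal: bool | None = None  # contains a terminal cell type
    is_decision: bool | None = None  # cell-fate decision vs lineage progression

    def __post_init__(self) -> None:
        if len({self.root, *self.leaves}) != 3:
            raise ValueError("triplet members must be three distinct labels")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.root, *self.leaves)


@dataclass(frozen=True)
class PatternFlags:
    """Which cell type, if any, carries the clear minimum / clear maximum."""

    clear_min_in: str | None
    clear_max_in: str | None


@dataclass
class PatternCensus:
    """Counts of clear-pattern genes per cell type for one triplet."""

    labels: tuple[str, str, str]
    n_clear_min: dict[str, int]
    n_clear_max: dict[str, int]
    fractions: dict[str, float] | None  # min-pattern fractions; None if no min genes
    entropy: float | None  # -sum f ln f over the min fractions
    majority_min_cell: str | None  # argmax of n_clear_min; None on ties

    @property
    def total_min(self) -> int:
        return sum(self.n_clear_min.values())

    @property
    def total_max(self) -> int:
        return sum(self.n_clear_max.values())


def _extreme_pvalues(groups: list[np.ndarray], equal_var: bool) -> tuple[int, np.ndarray, int, np.ndarray]:
    """(argmin, its two p-values, argmax, its two p-values) for one gene.

    Returns -1 for an extreme that is tied (a tie is not a clear pattern).
    """
    means = [float(np.mean(g)) for g in groups]
    order = np.argsort(means)
    lo = int(order[0]) if means[order[0]] < means[order[1]] else -1
    hi = int(order[2]) if means[order[2]] > means[order[1]] else -1

    def pvals(idx: int) -> np.ndarray:
        out = []
        for j in range(3):
            if j == idx:
                continue
            p = sps.ttest_ind(groups[idx], groups[j], equal_var=equal_var).pvalue
            out.append(1.0 if np.isnan(p) else float(p))
        return np.array(out)

    p_lo = pvals(lo) if lo >= 0 else np.array([1.0, 1.0])
    p_hi = pvals(hi) if hi >= 0 else np.array([1.0, 1.0])
    return lo, p_lo, hi, p_hi


def classify_gene(
    groups,
    alpha: float = 0.005,
    labels: tuple[str, str, str] = ("A", "B", "C"),
    equal_var: bool = False,
) -> PatternFlags:
    """Classify one gene's values across three cell types.

    ``groups`` are three replicate vectors.  The clear minimum is assigned to
    the lowest-mean cell type only if both pairwise t-tests against the other
    two give p < alpha (Welch by default; set ``equal_var`` for the pooled
    Student variant); the clear maximum symmetrically.  Both patterns can hold
    simultaneously; a tie in means yields no pattern.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) != 3:
        raise ValueError("expected replicate vectors for exactly three cell types")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each cell type needs >= 2 replicates for a t-test")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lo, p_lo, hi, p_hi = _extreme_pvalues(groups, equal_var)
    return PatternFlags(
        clear_min_in=labels[lo] if lo >= 0 and np.all(p_lo < alpha) else None,
        clear_max_in=labels[hi] if hi >= 0 and np.all(p_hi < alpha) else None,
    )


def census_triplet(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    triplet,
    alpha: float = 0.005,
    fdr: bool = False,
    equal_var: bool = False,
) -> PatternCensus:
    """Count clear-minimum and clear-maximum genes per cell type of a triplet.

    ``triplet`` is a :class:`LabeledTriplet` or any three cluster labels.  With
    ``fdr`` set, Benjamini-Hochberg adjustment is applied across all genes'
    t-test p-values within this triplet (minimum- and maximum-pattern families
    adjusted separately) before thresholding at ``alpha``.
    """
    labels = tuple(triplet.members) if isinstance(triplet, LabeledTriplet) else tuple(triplet)
    if len(set(labels)) != 3:
        raise ValueError("triplet must name three distinct clusters")
    counts = {lab: assignment.clusters.get(lab, 0) for lab in labels}
    missing = [lab for lab, n in counts.items() if n == 0]
    if missing:
        raise KeyError(f"clusters not present in assignment: {missing}")
    if any(n < 2 for n in counts.values()):
        small = [lab for lab, n in counts.items() if n < 2]
        raise ValueError(f"clusters with fewer than 2 members cannot be t-tested: {small}")

    blocks = [matrix.columns_for(assignment.members(lab)) for lab in labels]
    lo_idx, hi_idx = [], []
    lo_p, hi_p = [], []
    for i in range(matrix.n_genes):
        groups = [b[i] for b in blocks]
        lo, p_lo, hi, p_hi = _extreme_pvalues(groups, equal_var)
        lo_idx.append(lo)
        hi_idx.append(hi)
        lo_p.append(p_lo)
        hi_p.append(p_hi)
    lo_p = np.array(lo_p)
    hi_p = np.array(hi_p)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        lo_p = multipletests(lo_p.ravel(), method="fdr_bh")[1].reshape(lo_p.shape)
        hi_p = multipletests(hi_p.ravel(), method="fdr_bh")[1].reshape(hi_p.shape)

    n_min = {lab: 0 for lab in labels}
    n_max = {lab: 0 for lab in labels}
    for i in range(matrix.n_genes):
        if lo_idx[i] >= 0 and np.all(lo_p[i] < alpha):
            n_min[labels[lo_idx[i]]] += 1
        if hi_idx[i] >= 0 and np.all(hi_p[i] < alpha):
            n_max[labels[hi_idx[i]]] += 1

    total = sum(n_min.values())
    if total > 0:
        fractions = {lab: n_min[lab] / total for lab in labels}
        entropy = entropy_of_minima([fractions[lab] for lab in labels])
        best = max(n_min.values())
        leaders = [lab for lab in labels if n_min[lab] == best]
        majority = leaders[0] if len(leaders) == 1 else None
    else:
        fractions, entropy, majority = None, None, None
    return PatternCensus(
        labels=labels,
        n_clear_min=n_min,
        n_clear_max=n_max,
        fractions=fractions,
        entropy=entropy,
        majority_min_cell=majority,
    )


def entropy_of_minima(fractions) -> float:
    """Entropy S = -sum_i f_i ln f_i of the minima fractions (0 ln 0 := 0)."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {f.sum()!r})")
    nz = f[f > 0]
    return float(-np.sum(nz * np.log(nz)))


def relatedness_score(result) -> float:
    """Maximum non-null topology posterior: high for related triplets.

    Scoring a labeled collection of related and unrelated triplets with this
    statistic yields the ROC separating the two classes.
    """
    return float(np.max(np.asarray(result.posterior)[:3]))
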