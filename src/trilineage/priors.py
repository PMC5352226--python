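"""Prior configuration for the triplet model.

All marginal likelihoods are integrals of log-normal densities over a
rectangular (mu, sigma) grid weighted by a prior p(mu, sigma).  The grid, the
prior over it, the sparsity prior on transition genes and the prior over
topologies live in :class:`PriorConfig`.  Defaults follow the log2 microarray
scale: 2 < mu < 14 in log2 units, 0 < sigma <= 0.75, trapezoidal steps
d_mu = 0.05 and d_sigma = 0.01.  The sigma grid starts at d_sigma, not 0, so
every grid density is finite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["PriorConfig", "topology_prior_with_null", "empirical_prior"]


@dataclass(frozen=True)
class PriorConfig:
    """Model priors and the numeric-integration grid.

    Attributes
    ----------
    mu_min, mu_max
        Range of the uniform prior on the log2-scale mean.
    sigma_min, sigma_max
        Range of the prior on the log2-scale standard deviation.  The grid
        starts at ``max(sigma_min, d_sigma)`` so sigma = 0 is never evaluated.
    d_mu, d_sigma
        Trapezoidal step sizes.
    prior_odds_beta
        Sparsity parameter p(beta=1)/p(beta=0): the prior odds that a gene is
        a transition gene.  The only free parameter of the model.
    p_alpha_given_not_beta
        p(alpha=1 | beta=0): given a gene is not a transition gene, the prior
        probability that it is a marker gene rather than irrelevant.
    topology_prior
        Probabilities of the four topologies, ordered (A, B, C, null).
    prior_weights
        Optional empirical prior p(mu, sigma) evaluated on the grid
        (shape ``(len(mu_grid), len(sigma_grid))``); ``None`` means uniform.
    """

    mu_min: float = 2.0
    mu_max: float = 14.0
    sigma_min: float = 0.0
    sigma_max: float = 0.75
    d_mu: float = 0.05
    d_sigma: float = 0.01
    prior_odds_beta: float = 0.05
    p_alpha_given_not_beta: float = 0.5
    topology_prior: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    prior_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mu_max <= self.mu_min:
            raise ValueError("mu_max must exceed mu_min")
        if self.sigma_max <= max(self.sigma_min, 0.0):
            raise ValueError("sigma_max must exceed sigma_min and be positive")
        if self.d_mu <= 0 or self.d_sigma <= 0:
            raise ValueError("grid steps must be positive")
        if self.prior_odds_beta < 0:
            raise ValueError("prior_odds_beta must be >= 0")
        if not 0.0 <= self.p_alpha_given_not_beta <= 1.0:
            raise ValueError("p_alpha_given_not_beta must be in [0, 1]")
        tp = np.asarray(self.topology_prior, dtype=float)
        if tp.shape != (4,) or np.any(tp < 0) or not np.isclose(tp.sum(), 1.0, atol=1e-9):
            raise ValueError("topology_prior must be four nonnegative values summing to 1")
        if len(self.mu_grid) < 2 or len(self.sigma_grid) < 2:
            raise ValueError("integration grid must have at least 2 points per axis")
        if self.prior_weights is not None:
            w = np.asarray(self.prior_weights, dtype=float)
            if w.shape != (len(self.mu_grid), len(self.sigma_grid)):
                raise ValueError(
                    f"prior_weights shape {w.shape} does not match grid "
                    f"({len(self.mu_grid)}, {len(self.sigma_grid)})"
                )
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("prior_weights must be nonnegative and not all zero")
            object.__setattr__(self, "prior_weights", w)

    @property
    def mu_grid(self) -> np.ndarray:
        n = int(round((self.mu_max - self.mu_min) / self.d_mu)) + 1
        return self.mu_min + self.d_mu * np.arange(n)

    @property
    def sigma_grid(self) -> np.ndarray:
        start = self.sigma_min if self.sigma_min > 0 else self.d_sigma
        n = int(round((self.sigma_max - start) / self.d_sigma)) + 1
        return start + self.d_sigma * np.arange(n)

    def replace(self, **changes) -> "PriorConfig":
        return dataclasses.replace(self, **changes)

    def halved(self) -> "PriorConfig":
        """Half the step sizes over the identical domain (grid-refinement checks).

        The sigma range is pinned to the current grid's start so that halving
        refines the quadrature without extending the integration domain.
        """
        if self.prior_weights is not None:
            raise ValueError("cannot halve a grid carrying precomputed empirical weights")
        return self.replace(
            d_mu=self.d_mu / 2.0,
            d_sigma=self.d_sigma / 2.0,
            sigma_min=float(self.sigma_grid[0]),
        )

    @classmethod
    def for_data(cls, values: np.ndarray, **overrides) -> "PriorConfig":
        """Rescale the default microarray grid to the observed data range.

        Used for 90th-percentile-normalized single-cell data, whose scale is
        far from the [2, 14] log2 microarray range.  The mu range is the data
        range padded by 2%, and sigma_max and both step sizes keep the default
        configuration's proportions relative to the mu range (0.75/12 and
        0.05/12, 0.01/0.75 respectively).  Any field can still be overridden.
        """
        finite = np.asarray(values, dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size == 0:
            raise ValueError("no finite values to scale the prior to")
        lo, hi = float(finite.min()), float(finite.max())
        span = max(hi - lo, 1e-6)
        pad = 0.02 * span
        mu_min, mu_max = lo - pad, hi + pad
        mu_span = mu_max - mu_min
        defaults = dict(
            mu_min=mu_min,
            mu_max=mu_max,
            sigma_min=0.0,
            sigma_max=mu_span * 0.75 / 12.0,
            d_mu=mu_span * 0.05 / 12.0,
            d_sigma=mu_span * 0.01 / 12.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


def topology_prior_with_null(p_null: float) -> tuple[float, float, float, float]:
    """Topology prior with p(null) = ``p_null`` and the non-null mass split equally."""
    if not 0.0 <= p_null <= 1.0:
        raise ValueError("p_null must be in [0, 1]")
    p = (1.0 - p_null) / 3.0
    return (p, p, p, p_null)


def empirical_prior(matrix, assignment, config: PriorConfig | None = None) -> PriorConfig:
    """Estimate p(mu, sigma) from the data by kernel density estimation.

    For every (gene, cluster) pair with at least two members, the sample mean
    and sample SD of the log2 values form one observation; a Gaussian KDE over
    these observations is evaluated on the integration grid and stored as
    ``prior_weights`` (renormalization happens inside the integration engine).
    """
    from scipy.stats import gaussian_kde

    config = config or PriorConfig()
    means, sds = [], []
    for label in assignment.clusters:
        cols = matrix.columns_for(assignment.members(label))
        if cols.shape[1] < 2:
            continue
        means.append(cols.mean(axis=1))
        sds.append(cols.std(axis=1, ddof=1))
    if not means:
        raise ValueError("no cluster with >= 2 members to estimate an empirical prior from")
    obs = np.vstack([np.concatenate(means), np.concatenate(sds)])
    kde = gaussian_kde(obs)
    mu, sigma = np.meshgrid(config.mu_grid, config.sigma_grid, indexing="ij")
    weights = kde(np.vstack([mu.ravel(), sigma.ravel()])).reshape(mu.shape)
    weights = np.maximum(weights, weights.max() * 1e-12)  # keep log-weights finite
    return config.replace(prior_weights=weights)
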