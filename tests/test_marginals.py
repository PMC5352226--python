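"""Numerical checks of the grid-integrated marginal likelihoods."""

import numpy as np
import pytest
from scipy.special import logsumexp

import trilineage as tl
from trilineage.integrate import (
    GridTables,
    _log_tail,
    _log_unconstrained_product,
    compute_triplet_marginals,
    naive_log_min_constrained,
)

from conftest import random_gene


class TestLogDensity:
    def test_single_value_closed_form(self):
        expected = np.log(1.0 / (np.sqrt(2 * np.pi) * 0.5))
        assert tl.log_density_lognormal([8.0], 8.0, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_additivity_over_replicates(self):
        one = tl.log_density_lognormal([8.0], 8.0, 0.5)
        assert tl.log_density_lognormal([8.0, 8.0], 8.0, 0.5) == pytest.approx(2 * one)

    def test_three_sigma_exponent(self):
        base = tl.log_density_lognormal([8.0], 8.0, 0.5)
        assert tl.log_density_lognormal([9.5], 8.0, 0.5) == pytest.approx(base - 4.5)

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            tl.log_density_lognormal([8.0], 8.0, 0.0)


class TestIrrelevantMarginal:
    def test_concentrated_beats_split(self, prior_default):
        tight = np.full(6, 8.0)
        split = np.array([4.0, 4.0, 4.0, 12.0, 12.0, 12.0])
        assert tl.marginal_irrelevant(tight, prior_default) > tl.marginal_irrelevant(
            split, prior_default
        )

    def test_decreasing_in_spread(self, prior_default):
        # single-distribution marginal drops as within-pool variance grows past sigma_max
        values = [tl.marginal_irrelevant(8.0 + s * np.array([-1, -0.5, 0, 0, 0.5, 1]),
                                         prior_default) for s in (0.5, 1.5, 3.0)]
        assert values[0] > values[1] > values[2]

    def test_empty_input(self, prior_default):
        with pytest.raises(ValueError):
            tl.marginal_irrelevant([], prior_default)


class TestConstrainedMarginals:
    def test_symmetric_data_equal_marginals(self, prior_default):
        g = np.array([7.5, 8.0, 8.5])
        marg = compute_triplet_marginals([g[None], g[None], g[None]], prior_default)
        assert np.ptp(marg.log_min[0]) < 1e-9
        assert np.ptp(marg.log_marker_parts[0]) < 1e-9

    def test_clear_minimum_dominates(self, prior_default):
        rng = np.random.default_rng(10)
        g = random_gene(rng, (2.5, 8.0, 8.0), sigma=0.2, m=5)
        m_a = tl.marginal_min_constrained(*g, "A", prior_default)
        m_b = tl.marginal_min_constrained(*g, "B", prior_default)
        m_c = tl.marginal_min_constrained(*g, "C", prior_default)
        assert m_a - max(m_b, m_c) > 20  # log units

    def test_marker_pairing_dominates(self, prior_default):
        rng = np.random.default_rng(11)
        g = random_gene(rng, (8.0, 2.0, 2.0), sigma=0.2, m=5)
        marg = compute_triplet_marginals([v[None] for v in g], prior_default)
        parts = marg.log_marker_parts[0]
        assert parts[0] - max(parts[1], parts[2]) > 20

    @pytest.mark.parametrize("seed", [0, 1])
    def test_naive_triple_loop_equality(self, seed):
        small = tl.PriorConfig(mu_min=2, mu_max=11, d_mu=0.75, sigma_max=0.72, d_sigma=0.12)
        rng = np.random.default_rng(seed)
        g = random_gene(rng, rng.uniform(4, 10, 3), sigma=0.6, m=4)
        for xi in range(3):
            fast = tl.marginal_min_constrained(*g, xi, small)
            naive = naive_log_min_constrained(*g, xi, small)
            assert fast == pytest.approx(naive, abs=1e-10)

    def test_null_equals_mean_of_nonnull(self, prior_default):
        rng = np.random.default_rng(12)
        g = random_gene(rng, rng.uniform(4, 10, 3))
        null = tl.marginal_transition(*g, "null", prior_default)
        per_t = [tl.marginal_transition(*g, t, prior_default) for t in "ABC"]
        assert null == pytest.approx(logsumexp(per_t) - np.log(3.0), abs=1e-9)

    def test_null_matches_unconstrained_product(self, prior_default):
        """The unordered three-distribution integral agrees up to grid error."""
        rng = np.random.default_rng(13)
        g = [v[None] for v in random_gene(rng, rng.uniform(4, 10, 3))]
        marg = compute_triplet_marginals(g, prior_default)
        unconstrained = _log_unconstrained_product(g, prior_default)[0]
        assert marg.log_null[0] == pytest.approx(unconstrained, abs=1e-3)

    def test_planted_transition_orders_topologies(self, prior_default):
        # min in B: topologies A and C allow it, topology B does not
        rng = np.random.default_rng(14)
        g = random_gene(rng, (8.0, 4.0, 8.0), sigma=0.4, m=6)
        m = {t: tl.marginal_transition(*g, t, prior_default) for t in "ABC"}
        assert m["A"] > m["B"] and m["C"] > m["B"]

    def test_zero_variance_and_single_replicate(self, prior_default):
        marg = compute_triplet_marginals(
            [np.array([[8.0, 8.0]]), np.array([[6.0]]), np.array([[9.0, 9.0]])],
            prior_default,
        )
        assert np.isfinite(marg.log_min).all()
        assert np.isfinite(marg.log_marker).all()
        assert np.isfinite(marg.log_irrelevant).all()

    def test_out_of_range_mean_warns(self, prior_default, caplog):
        with caplog.at_level("WARNING"):
            compute_triplet_marginals(
                [np.full((1, 3), 0.5), np.full((1, 3), 8.0), np.full((1, 3), 9.0)],
                prior_default,
            )
        assert "prior range" in caplog.text

    def test_nan_rejected_with_gene_name(self, prior_default):
        blocks = [np.full((2, 3), 8.0) for _ in range(3)]
        blocks[1][1, 0] = np.nan
        with pytest.raises(ValueError, match="g1"):
            compute_triplet_marginals(blocks, prior_default, gene_ids=["g0", "g1"])


class TestGridConsistency:
    def test_halving_steps_barely_moves_pooled_marginal(self, prior_default):
        """Six tight pooled values: the single-distribution integral is grid-stable."""
        rng = np.random.default_rng(15)
        values = rng.normal(8.0, 0.5, 6)
        coarse = tl.marginal_irrelevant(values, prior_default)
        fine = tl.marginal_irrelevant(values, prior_default.halved())
        assert abs(coarse - fine) < 1e-3

    def test_halving_steps_barely_moves_posterior(self, prior_default):
        rng = np.random.default_rng(15)
        g = [v[None] for v in random_gene(rng, (6.0, 8.0, 9.0), sigma=0.5, m=3)]
        coarse = compute_triplet_marginals(g, prior_default)
        fine = compute_triplet_marginals(g, prior_default.halved())
        post_c = tl.topology_posterior(coarse, prior_default)
        post_f = tl.topology_posterior(fine, prior_default)
        assert np.abs(post_c - post_f).max() < 1e-4

    def test_constrained_marginals_converge_quadratically(self, prior_default):
        """Order-constrained integrals converge O(h^2) as both steps are halved.

        Their absolute discretization error at the default steps is a few
        1e-3 log units (driven by under-resolved likelihood tails), so the
        meaningful correctness check is the convergence rate, not a fixed
        small tolerance.
        """
        rng = np.random.default_rng(15)
        g = [v[None] for v in random_gene(rng, (6.0, 8.0, 9.0), sigma=0.5, m=3)]
        half = prior_default.halved()
        quarter = half.halved()
        m0 = compute_triplet_marginals(g, prior_default).log_min[0]
        m1 = compute_triplet_marginals(g, half).log_min[0]
        m2 = compute_triplet_marginals(g, quarter).log_min[0]
        step1 = np.abs(m0 - m1)
        step2 = np.abs(m1 - m2)
        # successive differences shrink ~4x for O(h^2); allow slack
        assert np.all(step2 < step1 / 2.5)

    def test_prior_partition_identities(self, prior_default):
        """Constrained-domain prior masses recombine to the full rectangle mass.

        Exact in the continuum; on the grid the deviation is O(d_mu^2) from the
        trapezoid corner, ~1.7e-5 at the default step and 4x smaller when halved.
        """
        t = GridTables(prior_default)
        assert abs(np.exp(np.log(2) + t.log_z_pair - 2 * t.log_z_full) - 1) < 1e-4
        assert abs(np.exp(np.log(3) + t.log_z_min - 3 * t.log_z_full) - 1) < 1e-4
        th = GridTables(prior_default.halved())
        coarse = abs(np.exp(np.log(3) + t.log_z_min - 3 * t.log_z_full) - 1)
        fine = abs(np.exp(np.log(3) + th.log_z_min - 3 * th.log_z_full) - 1)
        assert fine < coarse / 2

    def test_tail_is_subrange_trapezoid(self, prior_default):
        tables = GridTables(prior_default)
        rng = np.random.default_rng(16)
        log_f = rng.normal(size=(1, len(tables.mu)))
        tails = _log_tail(log_f, prior_default.d_mu)
        k = 100
        seg = log_f[0, k:]
        w = np.full(len(seg), np.log(prior_default.d_mu))
        w[0] = w[-1] = np.log(prior_default.d_mu / 2)
        assert tails[0, k] == pytest.approx(logsumexp(w + seg), abs=1e-10)


def _mc_min_constrained(g, xi, prior, rng, n_draws=10**6):
    """Rejection-sampled estimate of the min-constrained marginal with its SE."""
    mu = rng.uniform(prior.mu_min, prior.mu_max, (n_draws, 3))
    lo = prior.sigma_grid[0]
    sg = rng.uniform(lo, prior.sigma_max, (n_draws, 3))
    others = [i for i in range(3) if i != xi]
    keep = (mu[:, xi] < mu[:, others[0]]) & (mu[:, xi] < mu[:, others[1]])
    mu, sg = mu[keep], sg[keep]
    logd = np.zeros(len(mu))
    for c in range(3):
        gc = np.asarray(g[c])
        logd += -0.5 * len(gc) * np.log(2 * np.pi * sg[:, c] ** 2)
        logd += -((gc[None, :] - mu[:, c : c + 1]) ** 2).sum(axis=1) / (2 * sg[:, c] ** 2)
    estimate = logsumexp(logd) - np.log(len(logd))
    w = np.exp(logd - logd.max())
    rel_se = w.std() / (w.mean() * np.sqrt(len(w)))
    return estimate, rel_se


@pytest.mark.parametrize("seed", range(6))
def test_monte_carlo_oracle_min_constrained(seed, prior_default):
    """Grid integral within 3 Monte-Carlo standard errors of rejection sampling.

    The full 20-fixture panel runs in the acceptance suite; this spot-checks a
    spread of effect sizes.
    """
    rng = np.random.default_rng(100 + seed)
    means = rng.uniform(5, 10, 3)
    g = random_gene(rng, means, sigma=0.5, m=4)
    xi = seed % 3
    grid_val = tl.marginal_min_constrained(*g, xi, prior_default)
    mc_val, rel_se = _mc_min_constrained(g, xi, prior_default, rng)
    assert abs(grid_val - mc_val) < max(3 * rel_se, 1e-3)
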