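"""Topology posteriors, odds, gene roles, sweeps and top-N restriction."""

import numpy as np
import pytest

import trilineage as tl
from trilineage.bayes import (
    ClusterMarginalEngine,
    TripletResult,
    default_odds_grid,
    log_p_beta0,
    log_p_beta1,
    sweep_prior_odds,
)



def _triplet(rng, means_per_gene, sigma=0.5, m=8, labels=("A", "B", "C")):
    means = np.asarray(means_per_gene, dtype=float)
    blocks = tuple(rng.normal(means[:, [c]], sigma, (means.shape[0], m)) for c in range(3))
    return tl.TripletData(labels, [f"g{i}" for i in range(means.shape[0])], blocks)


class TestProbMin:
    def test_identical_data_uniform(self, prior_default):
        g = np.array([[7.0, 8.0, 9.0]])
        data = tl.TripletData(("A", "B", "C"), ["g0"], (g, g, g))
        for cell in "ABC":
            assert tl.prob_min(data, cell, prior_default)[0] == pytest.approx(1 / 3, abs=1e-9)

    def test_clear_minimum_certain(self, prior_default):
        rng = np.random.default_rng(0)
        data = _triplet(rng, [(2.5, 8.0, 8.0)], sigma=0.2, m=5)
        assert tl.prob_min(data, "A", prior_default)[0] > 0.99

    @pytest.mark.parametrize("seed", range(3))
    def test_sums_to_one(self, seed, prior_coarse):
        rng = np.random.default_rng(seed)
        data = _triplet(rng, rng.uniform(4, 10, (4, 3)), m=4)
        total = sum(tl.prob_min(data, cell, prior_coarse) for cell in "ABC")
        assert np.allclose(total, 1.0, atol=1e-9)


class TestTransitionOdds:
    def test_zero_prior_odds(self, prior_default):
        rng = np.random.default_rng(1)
        data = _triplet(rng, [(6.0, 8.0, 8.0)])
        prior = prior_default.replace(prior_odds_beta=0.0)
        assert tl.transition_odds(data, prior)[0] == 0.0

    def test_planted_clear_minimum_has_large_odds(self, prior_default):
        # separation 4 log2 units, sigma 0.3, 5 replicates: odds ~1e2 or far above
        rng = np.random.default_rng(2)
        data = _triplet(rng, [(4.0, 8.0, 8.0)], sigma=0.3, m=5)
        assert tl.transition_odds(data, prior_default)[0] > 1e2

    def test_flat_gene_below_prior_odds(self, prior_default):
        # order constraint costs an Occam factor, so a flat gene's odds
        # fall below the prior odds
        rng = np.random.default_rng(3)
        data = _triplet(rng, [(8.0, 8.0, 8.0)], sigma=0.4, m=8)
        odds = tl.transition_odds(data, prior_default)[0]
        assert 0.0 < odds < prior_default.prior_odds_beta


class TestTopologyPosterior:
    def test_prior_odds_zero_returns_topology_prior(self, prior_default):
        rng = np.random.default_rng(4)
        data = _triplet(rng, rng.uniform(4, 10, (5, 3)))
        post = tl.topology_posterior(data, prior_default, prior_odds=0.0)
        assert np.allclose(post, 0.25, atol=1e-9)
        skew = prior_default.replace(topology_prior=(0.1, 0.2, 0.3, 0.4))
        post = tl.topology_posterior(data, skew, prior_odds=0.0)
        assert np.allclose(post, (0.1, 0.2, 0.3, 0.4), atol=1e-9)

    def test_planted_topology_recovered(self, planted_path_triplet, prior_default):
        data, _truth = planted_path_triplet
        post = tl.topology_posterior(data, prior_default)
        assert post.argmax() == 0  # root A
        assert post[0] > 0.6

    def test_even_minima_favor_null(self, prior_default):
        matrix, assignment, _ = tl.generate_unrelated_triplet(60, seed=5)
        data = tl.TripletData.from_matrix(matrix, assignment, ("X1", "X2", "X3"))
        post = tl.topology_posterior(data, prior_default)
        assert post.argmax() == 3

    def test_normalization(self, prior_coarse):
        rng = np.random.default_rng(6)
        data = _triplet(rng, rng.uniform(4, 10, (6, 3)), m=4)
        for po in (0.0, 1e-4, 0.05, 10.0):
            assert tl.topology_posterior(data, prior_coarse, prior_odds=po).sum() == (
                pytest.approx(1.0, abs=1e-9)
            )

    def test_label_permutation_equivariance(self, prior_coarse):
        rng = np.random.default_rng(7)
        means = rng.uniform(4, 10, (5, 3))
        data = _triplet(rng, means)
        post = tl.topology_posterior(data, prior_coarse)
        for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
            permuted = tl.TripletData(
                tuple(data.labels[i] for i in perm),
                data.gene_ids,
                tuple(data.blocks[i] for i in perm),
            )
            post_p = tl.topology_posterior(permuted, prior_coarse)
            assert np.allclose(post_p[:3], post[list(perm)], atol=1e-12)
            assert post_p[3] == pytest.approx(post[3], abs=1e-12)

    def test_vote_form_identity(self, prior_default):
        """The posterior matches the explicit negative-vote product form."""
        rng = np.random.default_rng(8)
        data = _triplet(rng, rng.uniform(5, 10, (4, 3)), m=4)
        marg = data.marginals(prior_default)
        po = prior_default.prior_odds_beta
        odds = tl.transition_odds(marg, prior_default)
        post = tl.topology_posterior(marg, prior_default)
        scores = []
        for t in range(3):
            p_min = tl.prob_min(marg, t, prior_default)
            scores.append(0.25 * np.prod(1.0 + 1.5 * odds * (1.0 - p_min)))
        scores.append(0.25 * np.prod(1.0 + odds))
        scores = np.array(scores) / np.sum(scores)
        assert np.allclose(post, scores, atol=1e-9)

    def test_null_dominates_as_prior_odds_grow(self, prior_default):
        """On mixed-minimum data the null posterior rises monotonically with the odds."""
        matrix, assignment, _ = tl.generate_unrelated_triplet(10, s=1.0, m=4, seed=9)
        data = tl.TripletData.from_matrix(matrix, assignment, ("X1", "X2", "X3"))
        nulls = [
            tl.topology_posterior(data, prior_default, prior_odds=po)[3]
            for po in (1.0, 1e1, 1e2, 1e3)
        ]
        assert all(b > a for a, b in zip(nulls, nulls[1:]))
        assert nulls[-1] > 0.9


class TestSweep:
    def test_confident_dominant(self, planted_path_triplet, prior_default):
        data, _ = planted_path_triplet
        result = sweep_prior_odds(data, prior_default)
        assert result.dominant_topology == "A"
        assert result.confident
        assert result.sweep.shape == (len(default_odds_grid()), 4)
        assert result.roles is not None

    def test_weak_signal_not_confident(self, prior_default):
        rng = np.random.default_rng(10)
        data = _triplet(rng, [(8.0, 7.8, 8.1)], sigma=0.5, m=4)
        result = sweep_prior_odds(data, prior_default)
        assert not result.confident
        assert result.dominant_topology == tl.NULL
        assert result.max_nonnull < 0.6

    def test_ambiguous_when_two_topologies_reach_threshold(self):
        """Selection rule: two non-null topologies above threshold => excluded."""
        grid = np.logspace(-6, 2, 5)
        sweep = np.array(
            [
                [0.84, 0.05, 0.05, 0.06],
                [0.50, 0.30, 0.05, 0.15],
                [0.10, 0.70, 0.05, 0.15],
                [0.05, 0.40, 0.05, 0.50],
                [0.02, 0.02, 0.02, 0.94],
            ]
        )
        result = TripletResult(
            labels=("A", "B", "C"),
            posterior=sweep[0],
            prior_odds=0.05,
            odds_grid=grid,
            sweep=sweep,
        )
        dominant, confident = result.dominant_at(0.6)
        assert dominant == "ambiguous" and not confident
        # at a laxer threshold A alone qualifies... both still exceed 0.65;
        # at a stricter one neither does
        assert result.dominant_at(0.9) == (tl.NULL, False)

    def test_null_sweep(self, prior_default):
        matrix, assignment, _ = tl.generate_unrelated_triplet(40, seed=11)
        data = tl.TripletData.from_matrix(matrix, assignment, ("X1", "X2", "X3"))
        result = sweep_prior_odds(data, prior_default)
        assert result.dominant_topology == tl.NULL
        assert not result.confident


class TestGeneRoles:
    @pytest.fixture(scope="class")
    @staticmethod
    def role_result(prior_default):
        rng = np.random.default_rng(12)
        means = np.array(
            [
                (8.0, 4.0, 8.0),  # transition, min in leaf B
                (8.0, 8.0, 4.0),  # transition, min in leaf C
                (12.0, 8.0, 8.0),  # marker, high in A
                (8.0, 8.0, 8.0),  # irrelevant
            ]
        )
        data = _triplet(rng, means, sigma=0.3, m=5)
        return tl.gene_role_posterior(data, "A", prior_default)

    def test_recovered_roles(self, role_result):
        assert role_result.p_transition[0] > 0.8
        assert role_result.p_transition[1] > 0.8
        assert role_result.p_marker[2] > 0.8
        assert role_result.p_irrelevant[3] > 0.9

    def test_classes(self, role_result):
        assert role_result.transition_class[0] == "B"
        assert role_result.transition_class[1] == "C"
        assert role_result.marker_class[2] == "A"

    def test_normalized(self, role_result):
        total = role_result.p_transition + role_result.p_marker + role_result.p_irrelevant
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_null_topology_rejected(self, prior_default):
        rng = np.random.default_rng(13)
        data = _triplet(rng, [(8.0, 8.0, 8.0)], m=4)
        with pytest.raises(ValueError):
            tl.gene_role_posterior(data, 3, prior_default)


class TestRestrictTopN:
    @pytest.fixture(scope="class")
    @staticmethod
    def strong_triplet():
        # 10 strong planted transition genes (separation 4, sigma 0.3, 5 reps)
        rng = np.random.default_rng(14)
        means = np.vstack(
            [np.tile([8.0, 4.0, 8.0], (5, 1)), np.tile([8.0, 8.0, 4.0], (5, 1)),
             np.full((20, 3), 8.0)]
        )
        return _triplet(rng, means, sigma=0.3, m=5)

    def test_all_genes_identical_to_full_posterior(self, strong_triplet, prior_default):
        full = tl.topology_posterior(strong_triplet, prior_default)
        top = tl.restrict_top_n(strong_triplet, len(strong_triplet.gene_ids), prior_default)
        assert np.allclose(full, top, atol=1e-12)

    def test_recovery_for_all_n_at_least_4(self, strong_triplet, prior_default):
        for n in range(4, 31):
            post = tl.restrict_top_n(strong_triplet, n, prior_default)
            assert post.argmax() == 0, f"failed at n={n}"

    def test_single_gene_bound(self, strong_triplet, prior_default):
        """One gene's posterior equals the closed-form single-vote factor."""
        post, genes = tl.restrict_top_n(strong_triplet, 1, prior_default, return_genes=True)
        marg = strong_triplet.marginals(prior_default)
        i = marg.gene_ids.index(genes[0])
        odds = tl.transition_odds(marg, prior_default)[i]
        factors = [
            1.0 + 1.5 * odds * (1.0 - tl.prob_min(marg, t, prior_default)[i])
            for t in range(3)
        ]
        factors.append(1.0 + odds)
        expected = np.array(factors) / np.sum(factors)
        assert np.allclose(post, expected, atol=1e-9)
        # a single vote can never exceed the bound (1 + 3/2 O) / (4 + ... )
        assert post.max() <= max(expected) + 1e-12

    def test_invalid_n(self, strong_triplet, prior_default):
        with pytest.raises(ValueError):
            tl.restrict_top_n(strong_triplet, 0, prior_default)


class TestEngineConsistency:
    def test_engine_matches_direct_computation(self, prior_coarse):
        matrix, assignment, _ = tl.generate_tree_dataset(
            [("A", "B"), ("B", "C"), ("B", "D")],
            n_transition=3, n_marker=2, n_irrelevant=5, m=4, seed=15,
        )
        engine = ClusterMarginalEngine(matrix, assignment, prior_coarse)
        for labels in (("A", "B", "C"), ("B", "C", "D"), ("A", "C", "D")):
            from_engine = engine.marginals(labels)
            direct = tl.TripletData.from_matrix(matrix, assignment, labels).marginals(
                prior_coarse
            )
            assert np.allclose(from_engine.log_min, direct.log_min, atol=1e-10)
            assert np.allclose(from_engine.log_marker, direct.log_marker, atol=1e-10)
            assert np.allclose(from_engine.log_irrelevant, direct.log_irrelevant, atol=1e-10)

    def test_p_beta_mixtures(self, prior_coarse):
        rng = np.random.default_rng(16)
        data = _triplet(rng, rng.uniform(5, 10, (3, 3)), m=4)
        marg = data.marginals(prior_coarse)
        from scipy.special import logsumexp

        uniform = log_p_beta1(marg)
        assert np.allclose(uniform, logsumexp(marg.log_min, axis=1) - np.log(3), atol=1e-12)
        assert np.allclose(
            log_p_beta0(marg, 1.0), marg.log_marker, atol=1e-12
        )
        assert np.allclose(log_p_beta0(marg, 0.0), marg.log_irrelevant, atol=1e-12)
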