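import numpy as np
import pytest

import trilineage as tl


@pytest.fixture(scope="session")
def prior_default() -> tl.PriorConfig:
    """The microarray-scale grid: mu in [2, 14] step 0.05, sigma (0, 0.75] step 0.01."""
    return tl.PriorConfig()


@pytest.fixture(scope="session")
def prior_coarse() -> tl.PriorConfig:
    """Coarser grid for property tests where fine resolution is not the point."""
    return tl.PriorConfig(d_mu=0.2, d_sigma=0.05)


@pytest.fixture(scope="session")
def planted_path_triplet(prior_default):
    """Path B - A - C with 10 transition genes per branch direction (s=2, sigma=0.5, m=8)."""
    matrix, assignment, truth = tl.generate_tree_dataset(
        [("B", "A"), ("A", "C")],
        n_transition=10,
        n_marker=0,
        n_irrelevant=0,
        s=2.0,
        sigma=0.5,
        m=8,
        seed=42,
    )
    data = tl.TripletData.from_matrix(matrix, assignment, ("A", "B", "C"))
    return data, truth


def random_gene(rng, means, sigma=0.5, m=4):
    """Replicate vectors for one gene across three clusters."""
    return [rng.normal(mu, sigma, m) for mu in means]
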