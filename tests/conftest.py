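import numpy as np
import pytest

from strucnet import (
    SyntheticSpec,
    default_parcellation,
    generate_cohort,
    generate_expression_map,
    generate_parcellation,
)


@pytest.fixture(scope="session")
def parc85():
    return default_parcellation()


@pytest.fixture(scope="session")
def parc_small():
    """Tiny parcellation (4 cortical per hemisphere + 3 subcortical)."""
    return generate_parcellation(
        4, ["Brain-stem", "Left-caudate", "Right-caudate"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort(parc_small):
    """A small planted-effect cohort shared by read-only tests."""
    expr = generate_expression_map(parc_small, seed=11)
    spec = SyntheticSpec(n_pairs=4, seed=11, density=0.6)
    return generate_cohort(parc_small, expr, spec)


def random_weighted_graph(rng, n, density=0.5, unit=False):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = np.ones(present.sum()) if unit else rng.uniform(
        0.05, 1.0, present.sum()
    )
    flat = np.zeros(len(iu[0]))
    flat[present] = vals
    w[iu] = flat
    w.T[iu] = flat
    return w
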