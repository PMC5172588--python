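import numpy as np
import pytest

from zipflatent import CategoricalLatentDataset, EmpiricalDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def quarter_halves():
    """The {1/2, 1/4, 1/8, 1/8} toy distribution used in hand calculations."""
    return EmpiricalDistribution.from_probabilities(
        {"a": 0.5, "b": 0.25, "c": 0.125, "d": 0.125}
    )


@pytest.fixture
def two_category_toy():
    """One common grammatical item vs two rarer content items.

    Counts (2, 1, 1) give P(z) = (1/2, 1/2), energies log2 vs log4, zero
    within-category variance, hence PEEV exactly 1 with total variance
    (log2 / 2)^2.
    """
    return CategoricalLatentDataset.from_records(
        [("the", 2, "gram"), ("cat", 1, "content"), ("dog", 1, "content")]
    )


def random_distribution(rng, n_states, dirichlet=False):
    """A random strictly positive distribution over n_states labels."""
    if dirichlet:
        p = rng.dirichlet(np.full(n_states, 0.5))
        p = np.clip(p, 1e-300, None)
    else:
        w = rng.exponential(size=n_states)
        p = w / w.sum()
    p = p / p.sum()
    return EmpiricalDistribution(tuple(range(n_states)), p)
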