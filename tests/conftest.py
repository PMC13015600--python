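import numpy as np
import pytest

from ctrlcascade.synthgen import default_ground_truth, simulate_ela_items


@pytest.fixture(scope="session")
def five_factor_cohort():
    """Clean 67-item, 5-factor cohort (n=4000, unit total item variance)."""
    truth = default_ground_truth(seed=11)
    items, factors = simulate_ela_items(4000, truth, seed=11)
    return items.to_numpy(), factors.to_numpy(), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_stable_symmetric(rng, n):
    """Random symmetric nonnegative matrix, normalized to spectral radius < 1."""
    a = rng.random((n, n))
    a = np.triu(a, 1)
    a = a + a.T
    lam = np.linalg.eigvalsh(a)[-1]
    return a / (1.0 + lam)
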