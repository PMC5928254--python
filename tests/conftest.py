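import numpy as np
import pytest

from sphmm import EffectGrid, MixturePrior
from sphmm.simulate import NormalEffects, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_grid():
    return EffectGrid.default()


@pytest.fixture(scope="session")
def small_grid():
    return EffectGrid(np.array([-0.1, -0.05, 0.05, 0.1]))


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-noise dataset: every SNP null."""
    return simulate_dataset(SimConfig(m=5000, pi_true=0.0, seed=11))


@pytest.fixture(scope="session")
def signal_dataset():
    """Moderate dataset with 10% non-null SNPs, effects N(0, 0.03^2)."""
    return simulate_dataset(
        SimConfig(m=5000, pi_true=0.1, effect_dist=NormalEffects(0.03), seed=7)
    )


def naive_marginal_loglik(y, v, pi, masses, points):
    """Independent direct-summation likelihood (no caching, no rescaling)."""
    from scipy.stats import norm

    total = 0.0
    for yj, vj in zip(y, v):
        f0 = norm.pdf(yj, 0.0, np.sqrt(vj))
        f1 = sum(p * norm.pdf(yj, b, np.sqrt(vj)) for p, b in zip(masses, points))
        total += np.log((1 - pi) * f0 + pi * f1)
    return total
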