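import numpy as np
import pytest

from profgram.profile_io import ProfileMatrix
from profgram.synthetic import SyntheticConfig, generate_dataset


def random_profile(seed: int, L: int = 30, row_stochastic: bool = False) -> ProfileMatrix:
    rng = np.random.default_rng(seed)
    if row_stochastic:
        values = rng.dirichlet(np.ones(20), size=L)
    else:
        values = rng.random((L, 20))
    return ProfileMatrix(f"rand_{seed}", values, origin="HMM")


@pytest.fixture
def profile_seed11() -> ProfileMatrix:
    """The 30 x 20 random matrix used by the brute-force feature oracles."""
    return random_profile(11)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separated synthetic dataset (small n, fast to cross-validate)."""
    return generate_dataset(SyntheticConfig(n_pos=30, n_neg=30, effect=0.8, seed=5))
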