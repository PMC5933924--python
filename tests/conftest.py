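import numpy as np
import pytest

import msmfret as mf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def benchmark3():
    """The 3-state folding benchmark with well-separated efficiencies."""
    return mf.make_benchmark(
        M=3, bias_strength=0.5, efficiencies=(0.2, 0.5, 0.85), n_tau=0.5, seed=1
    )


@pytest.fixture(scope="session")
def fast_benchmark3():
    """Fast-mixing variant (basin dwell ~ tens of steps) for statistics
    that need many independent basin visits per sequence."""
    return mf.make_benchmark(
        M=3, bias_strength=0.5, efficiencies=(0.2, 0.5, 0.85), n_tau=0.5,
        base_rate=0.2, seed=1,
    )


def random_reversible_msm(M, rng, lag=1.0):
    """Random connected count matrix -> reversible MSM."""
    C = rng.integers(1, 20, size=(M, M)).astype(float)
    return mf.estimate_reversible_T(C, lag=lag)
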