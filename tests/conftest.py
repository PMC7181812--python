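import numpy as np
import pytest

import recruitcast as rc


@pytest.fixture(scope="session")
def ricker_grid():
    """Noiseless Ricker data R = 2 S exp(-0.5 S) on a dense S grid."""
    S = np.arange(0.1, 3.01, 0.1)
    return S, 2.0 * S * np.exp(-0.5 * S)


@pytest.fixture(scope="session")
def chaotic_series():
    """Deterministic chaotic Ricker skeleton (no noise, no forcing)."""
    return rc.simulate_truth(rc.CHAOTIC_PRESET)


@pytest.fixture(scope="session")
def linear_ar_series():
    """Noiseless linear AR(1) recruitment: R_{t+1} = 0.9 R_t + 1."""
    n = 40
    R = np.empty(n)
    R[0] = 0.5
    for t in range(n - 1):
        R[t + 1] = 0.9 * R[t] + 1.0
    return rc.StockRecruitSeries(
        "linear", "synthetic", np.arange(1960, 1960 + n), np.ones(n), R
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """Six synthetic stocks (3 SD + 3 DD) at default operating-model settings."""
    return rc.generate_ensemble(3, 3, seed=5)


@pytest.fixture(scope="session")
def small_series(small_ensemble):
    return rc.ensemble_series(small_ensemble)
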