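import numpy as np
import pytest

from consica import synthetic


@pytest.fixture(scope="session")
def sources5():
    """Five sparse Laplace sources over 1000 genes (disjoint active sets)."""
    return synthetic.generate_sources(1000, 5, 0.02, seed=1)


@pytest.fixture(scope="session")
def mixture(sources5):
    """300-sample mixture of sources5 at SNR 10 (noise_sd^2 = k/10)."""
    noise_sd = np.sqrt(sources5.n_components / 10)
    X, A = synthetic.generate_expression(sources5, 300, 1.0, noise_sd, seed=7)
    return X, A


@pytest.fixture(scope="session")
def survival_null(mixture):
    """Survival with no activity effect (all betas zero)."""
    _, A = mixture
    return synthetic.generate_survival(
        A, np.zeros(A.n_components), baseline_rate=0.02, censor_rate=0.015, seed=21
    )
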