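import numpy as np
import pytest

from erpstate.hmm import HMMParams
from erpstate.synth import SynthConfig, build_ground_truth


@pytest.fixture(scope="session")
def truth48():
    """A K=4, M=8 ground-truth model shared across tests."""
    return build_ground_truth(4, 8, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_subjects=4, n_trials=3, fs=64.0, smooth_len=1, seed=11)


def random_hmm_params(rng, K, M, df_scale=1.0):
    """Random valid HMM parameters for oracle tests."""
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    mu = rng.normal(0, 2, size=(K, M))
    Sigma = np.empty((K, M, M))
    for k in range(K):
        W = rng.normal(size=(M, M + 2))
        Sigma[k] = W @ W.T / (M + 2) * df_scale + 0.1 * np.eye(M)
    return HMMParams(pi=pi, A=A, mu=mu, Sigma=Sigma)
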