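import numpy as np
import pytest

import bymweights as bw


@pytest.fixture(scope="session")
def lattice3():
    return bw.grid_lattice(3, 3)


@pytest.fixture(scope="session")
def lattice12():
    return bw.grid_lattice(12, 12)


@pytest.fixture(scope="session")
def a1_12(lattice12):
    return bw.build_weights("A1", lattice12)


@pytest.fixture(scope="session")
def smooth_dataset():
    """One smooth-regime synthetic data set with ground truth."""
    return bw.generate_dataset("smooth", bw.GeneratorConfig(seed=42))


def make_posterior(alpha, beta, gamma, eps, x=None, sg2=None, se=None):
    """Assemble a PosteriorSample from explicit draw arrays (C, M[, N])."""
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    n = gamma.shape[2]
    return bw.PosteriorSample(
        alpha=alpha, beta=np.asarray(beta, dtype=float),
        gamma=gamma, eps=np.asarray(eps, dtype=float),
        sigma_gamma2=np.ones_like(alpha) if sg2 is None else np.asarray(sg2),
        sigma_eps=np.ones_like(alpha) if se is None else np.asarray(se),
        x=np.zeros(n) if x is None else np.asarray(x, dtype=float))
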