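import numpy as np
import pytest

import lethalwf as lw


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_valid_params(rng):
    """1000 random (h, u) draws covering recessive, partially recessive,
    overdominant and boundary regimes."""
    h = np.concatenate([
        rng.uniform(-2.0, 1.0, 700),
        rng.uniform(-0.05, 0.05, 200),
        np.array([1.0, 0.5, 0.0, -1e-6, -10.0]),
        rng.uniform(0.9, 1.0, 95),
    ])
    u = np.concatenate([
        10.0 ** rng.uniform(-12, -1, 900),
        rng.uniform(0.0, 1.0, 95),
        np.array([0.0, 1.0, 1e-15, 0.5, 1e-3]),
    ])
    return [lw.PopulationParams(u=float(ui), h=float(hi))
            for hi, ui in zip(h, u)]


def brute_force_stationary(W: np.ndarray) -> np.ndarray:
    """Independent stationary-vector oracle: eigendecomposition, taking
    the eigenvector of the eigenvalue closest to 1."""
    vals, vecs = np.linalg.eig(W)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@pytest.fixture(scope="session")
def stationary_oracle():
    return brute_force_stationary
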