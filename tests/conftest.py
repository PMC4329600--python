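import numpy as np
import pytest

from lmmscan import KinshipMatrix, SimConfig, simulate_dataset


def random_pd_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite matrix."""
    A = rng.standard_normal((n, n))
    return A @ A.T / n + np.eye(n)


def random_kinship(rng: np.random.Generator, n: int) -> KinshipMatrix:
    """Random PSD kinship-like matrix with unit-scale diagonal."""
    A = rng.standard_normal((n, max(2, n // 2)))
    values = A @ A.T / A.shape[1]
    values += np.eye(n) * 0.1
    d = np.sqrt(np.diag(values))
    values = values / np.outer(d, d)
    return KinshipMatrix(values=values, sample_ids=[f"S{i}" for i in range(n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture
def small_cohort():
    """A small simulated cohort shared by engine tests."""
    config = SimConfig(n=40, m=25, t=3, p=3, h2=0.5, seed=11)
    phi, genotypes, XL, Y, truth = simulate_dataset(config)
    return config, phi, genotypes, XL, Y
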