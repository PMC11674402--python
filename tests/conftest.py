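import numpy as np
import pytest

from fcbench.data_model import Cohort, FoldPartition
from fcbench.synthetic import SyntheticSpec, generate_cohort


def random_spd(rng: np.random.Generator, p: int) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    a = rng.standard_normal((p, p))
    return a @ a.T + p * np.eye(p)


def random_symmetric(rng: np.random.Generator, p: int) -> np.ndarray:
    a = rng.standard_normal((p, p))
    return (a + a.T) / 2.0


def correlation_from_samples(rng: np.random.Generator, p: int, t: int = 200) -> np.ndarray:
    """Full-rank sample correlation matrix (unit diagonal, PSD by construction)."""
    x = rng.standard_normal((t, p))
    c = np.corrcoef(x, rowvar=False)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort(rng):
    """Hand-assembled 6-subject cohort with 2 folds of 3, p=5 nodes."""
    n, p = 6, 5
    efc = np.stack([correlation_from_samples(rng, p) for _ in range(n)])
    pfc = np.stack([correlation_from_samples(rng, p) for _ in range(n)])
    sc = np.zeros((n, p, p))
    for i in range(n):
        m = np.abs(random_symmetric(rng, p))
        m[m < np.median(m)] = 0.0
        np.fill_diagonal(m, 0.0)
        sc[i] = (m + m.T) / 2.0
    folds = FoldPartition(n_folds=2, assignment=np.array([1, 1, 1, 2, 2, 2]))
    return Cohort(
        subject_ids=[f"s{i}" for i in range(n)], efc=efc, pfc=pfc, sc=sc, folds=folds
    )


@pytest.fixture
def synthetic_cohort():
    """Mid-size generated cohort shared across tests (deterministic)."""
    spec = SyntheticSpec(
        n_subjects=40, n_nodes=16, t_samples=120, n_folds=4, alpha=0.3, beta=0.9, seed=7
    )
    cohort, truth = generate_cohort(spec)
    return cohort, truth
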