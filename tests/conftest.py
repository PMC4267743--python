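import numpy as np
import pytest

import recombtest as rt


@pytest.fixture(scope="session")
def warm_kernels():
    """Trigger numba compilation once so timings elsewhere are honest."""
    t = np.array([1, 0], dtype=np.int8)
    p = np.array([[1, 0]], dtype=np.int8)
    pos = np.array([1.0, 2.0])
    params = rt.ModelParams(rho=1.0, gamma=1.0, lam=0.5, theta_hat=1.0)
    rt.conditional_log_prob(t, p, pos, params)
    rt.conditional_log_prob_crossover_only(t, p, pos, 1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_instance(rng, k_max=3, S_max=4, L=10.0):
    """A random small (target, panel, positions, params) HMM instance."""
    k = int(rng.integers(1, k_max + 1))
    S = int(rng.integers(1, S_max + 1))
    panel = rng.integers(0, 2, (k, S)).astype(np.int8)
    target = rng.integers(0, 2, S).astype(np.int8)
    positions = np.sort(rng.uniform(0, L, S))
    while S > 1 and np.any(np.diff(positions) <= 0):
        positions = np.sort(rng.uniform(0, L, S))
    params = rt.ModelParams(
        rho=float(rng.uniform(0, 3)),
        gamma=float(rng.uniform(0.01, 3)),
        lam=float(rng.uniform(0.1, 2)),
        theta_hat=float(rng.uniform(0.1, 1.5)),
    )
    return target, panel, positions, params


def random_matrix(rng, n=None, S=None, L=20.0):
    """A random valid HaplotypeMatrix (not from the coalescent)."""
    n = int(rng.integers(2, 8)) if n is None else n
    S = int(rng.integers(1, 12)) if S is None else S
    alleles = rng.integers(0, 2, (n, S)).astype(np.int8)
    positions = np.sort(rng.uniform(0, L, S))
    while S > 1 and np.any(np.diff(positions) <= 0):
        positions = np.sort(rng.uniform(0, L, S))
    return rt.HaplotypeMatrix(alleles=alleles, positions=positions, region_length=L)


def mean_pairwise_diff(mat):
    """Average number of pairwise differences (nucleotide diversity x L)."""
    f = mat.alleles.mean(axis=0)
    n = mat.n
    return float((2 * f * (1 - f)).sum() * n / (n - 1))
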