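import warnings
from itertools import combinations

import numpy as np
import pytest

import lapmix as lm


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def spec_345():
    return lm.ClusterGraphSpec(3, (3, 4, 5), 0.5)


@pytest.fixture
def basis_345(spec_345):
    graph = lm.interpolating_cluster_graph(spec_345)
    return lm.compute_eigenbasis(lm.build_laplacian(graph), 3)


def enumerate_polytope_vertices(omega: np.ndarray, m: int) -> list[np.ndarray]:
    """Brute-force vertex enumeration of {M : M^T e = e_1, omega M^T >= 0}.

    A vertex activates m(m-1) inequality rows on top of the m equality
    constraints (m^2 unknowns).  Only practical for tiny N and m.
    """
    n = omega.shape[0]
    rows = [(x, k) for x in range(n) for k in range(m)]
    a_eq = np.kron(np.ones((1, m)), np.eye(m))
    b_eq = np.zeros(m)
    b_eq[0] = 1.0
    need = m * m - m
    verts = []
    for combo in combinations(rows, need):
        blocks = [a_eq]
        for (x, k) in combo:
            row = np.zeros(m * m)
            row[k * m : (k + 1) * m] = omega[x]
            blocks.append(row[None, :])
        A = np.vstack(blocks)
        if np.linalg.matrix_rank(A) < m * m:
            continue
        b = np.concatenate([b_eq, np.zeros(need)])
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
        if np.linalg.norm(A @ sol - b) > 1e-9:
            continue
        M = sol.reshape(m, m)
        if (omega @ M.T).min() >= -1e-9:
            verts.append(M)
    return verts


def random_weighted_graph(n: int, rng: np.random.Generator) -> lm.WeightedGraph:
    a = rng.uniform(size=(n, n))
    a = np.triu(a, 1)
    return lm.WeightedGraph.from_dense(a + a.T)
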