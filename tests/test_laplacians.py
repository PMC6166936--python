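import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import lapmix as lm
from lapmix.laplacians import _lattice_neighbor_pairs


class TestBuildLaplacian:
    def test_empty_graph_gives_zero_laplacian(self):
        g = lm.WeightedGraph.from_dense(np.zeros((2, 2)))
        sys_ = lm.build_laplacian(g)
        assert sys_.laplacian.nnz == 0

    def test_single_edge(self):
        g = lm.WeightedGraph.from_dense(np.array([[0.0, 1.0], [1.0, 0.0]]))
        lap = lm.build_laplacian(g).laplacian.toarray()
        assert np.allclose(lap, [[1, -1], [-1, 1]])

    def test_complete_graph_spectrum(self):
        # complete graph on N vertices: second eigenvalue N with multiplicity N-1
        a = np.ones((4, 4)) - np.eye(4)
        lap = lm.build_laplacian(lm.WeightedGraph.from_dense(a)).laplacian
        vals = np.linalg.eigvalsh(lap.toarray())
        assert np.allclose(vals, [0, 4, 4, 4], atol=1e-10)

    def test_rejects_asymmetric(self):
        a = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            lm.WeightedGraph.from_dense(a)

    def test_rejects_negative_weight(self):
        a = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            lm.WeightedGraph.from_dense(a)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_row_sums_zero_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        a = np.triu(rng.uniform(size=(n, n)), 1)
        lap = lm.build_laplacian(lm.WeightedGraph.from_dense(a + a.T)).laplacian
        assert np.abs(np.asarray(lap.sum(axis=1))).max() < 1e-12


class TestDetailedBalance:
    def test_symmetric_rates_uniform_stationary_unchanged(self):
        q = sp.csr_matrix(np.array([[0.0, 0.3], [0.3, 0.0]]))
        sys_ = lm.symmetrize_detailed_balance(q, np.ones(2))
        expected = np.array([[0.3, -0.3], [-0.3, 0.3]])
        assert np.allclose(sys_.laplacian.toarray(), expected)

    def test_two_state_conjugation(self):
        # q(1<-2)=2, q(2<-1)=1 balances stationary (2,1); symmetrized
        # off-diagonal is -sqrt(q12*q21) = -sqrt(2)
        q = sp.csr_matrix(np.array([[0.0, 2.0], [1.0, 0.0]]))
        sys_ = lm.symmetrize_detailed_balance(q, np.array([2.0, 1.0]))
        lap = sys_.laplacian.toarray()
        assert np.allclose(lap[0, 1], -np.sqrt(2.0))
        assert np.allclose(lap, lap.T)

    def test_eigenvalues_preserved(self):
        rng = np.random.default_rng(3)
        n = 6
        pi = rng.uniform(0.5, 2.0, size=n)
        # build detailed-balance rates from a random symmetric flux matrix
        flux = np.triu(rng.uniform(size=(n, n)), 1)
        flux = flux + flux.T
        q = flux / pi[None, :]  # q_ij = flux_ij / pi_j satisfies balance
        np.fill_diagonal(q, 0.0)
        d = q.sum(axis=0)
        unsym = np.diag(d) - q
        sys_ = lm.symmetrize_detailed_balance(sp.csr_matrix(q), pi)
        v1 = np.sort(np.linalg.eigvals(unsym).real)
        v2 = np.sort(np.linalg.eigvalsh(sys_.laplacian.toarray()))
        assert np.allclose(v1, v2, atol=1e-10)

    def test_rejects_balance_violation(self):
        q = sp.csr_matrix(np.array([[0.0, 2.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="detailed balance"):
            lm.symmetrize_detailed_balance(q, np.array([1.0, 1.0]))


class TestSimilarityGraph:
    def test_two_identical_items_single_unit_edge(self):
        feats = np.zeros((2, 3))
        cfg = lm.SimilarityConfig(k_nn=1, k_min=0, min_weight_quantile=None,
                                  kernel_scale=1.0)
        g = lm.similarity_graph(feats, cfg)
        assert np.allclose(g.dense(), [[0, 1], [1, 0]])

    def test_dense_when_no_sparsification(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(6, 2))
        cfg = lm.SimilarityConfig(k_nn=5, k_min=0, min_weight_quantile=None)
        g = lm.similarity_graph(feats, cfg)
        w = g.dense()
        assert np.allclose(w, w.T)
        assert (w[~np.eye(6, dtype=bool)] > 0).all()

    def test_three_separated_clouds_give_three_blocks(self):
        rng = np.random.default_rng(42)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        feats = np.vstack([c + 0.1 * rng.normal(size=(20, 2)) for c in centers])
        cfg = lm.SimilarityConfig(k_nn=5, k_min=0, min_weight_quantile=None)
        g = lm.similarity_graph(feats, cfg)
        # drop numerically negligible cross-cloud edges, then count components
        w = g.dense()
        w[w < 1e-8] = 0.0
        n_comp, labels = sp.csgraph.connected_components(
            sp.csr_matrix(w), directed=False
        )
        assert n_comp == 3
        truth = np.repeat(np.arange(3), 20)
        assert lm.labeling_errors(labels, truth) == 0

    def test_rejects_nonfinite(self):
        feats = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            lm.similarity_graph(feats, lm.SimilarityConfig(k_nn=1))

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="k_min"):
            lm.similarity_graph(
                np.zeros((3, 2)), lm.SimilarityConfig(k_nn=1, k_min=2)
            )


class TestAdjacencyPreprocess:
    def test_row_stochastic_symmetric_unchanged(self):
        a = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        g = lm.WeightedGraph.from_dense(a)
        cfg = lm.SimilarityConfig(k_nn=2, k_min=0, min_weight_quantile=None)
        out = lm.adjacency_preprocess(g, cfg)
        assert np.allclose(out.dense(), a)

    def test_star_graph_max_symmetrization_keeps_spokes(self):
        n = 5
        a = np.zeros((n, n))
        a[0, 1:] = [0.9, 0.7, 0.5, 0.3]
        a = a + a.T
        g = lm.WeightedGraph.from_dense(a)
        cfg = lm.SimilarityConfig(k_nn=1, k_min=0, min_weight_quantile=None)
        out = lm.adjacency_preprocess(g, cfg).dense()
        # hub keeps only its strongest spoke before symmetrization, but the
        # elementwise max with the spokes' rows restores every spoke edge
        assert (out[0, 1:] > 0).all()

    def test_output_invariants(self):
        rng = np.random.default_rng(1)
        a = np.triu(rng.uniform(size=(10, 10)), 1)
        g = lm.WeightedGraph.from_dense(a + a.T)
        out = lm.adjacency_preprocess(g, lm.SimilarityConfig(k_nn=4, k_min=1))
        w = out.dense()
        assert np.allclose(w, w.T)
        assert w.min() >= 0 and w.max() <= 1 + 1e-12
        assert np.allclose(np.diag(w), 0)


class TestLargestComponent:
    def test_connected_identity(self):
        a = np.ones((4, 4)) - np.eye(4)
        g = lm.WeightedGraph.from_dense(a)
        sub, idx = lm.largest_connected_component(g)
        assert sub.n_vertices == 4
        assert np.array_equal(idx, np.arange(4))

    def test_two_blocks_returns_larger(self):
        a = np.zeros((8, 8))
        a[:5, :5] = 1.0
        a[5:, 5:] = 1.0
        np.fill_diagonal(a, 0)
        sub, idx = lm.largest_connected_component(lm.WeightedGraph.from_dense(a))
        assert sub.n_vertices == 5
        assert np.array_equal(idx, np.arange(5))


class TestSmoluchowski:
    def test_constant_density_gives_lattice_laplacian(self):
        grid = lm.DensityGrid(np.ones(6), (2, 3), (1.0, 1.0))
        sys_ = lm.smoluchowski_laplacian(grid, beta=3.0)
        i, j = _lattice_neighbor_pairs((2, 3))
        lattice = sp.csr_matrix((np.ones(i.size), (i, j)), shape=(6, 6))
        expected = sp.diags(np.asarray(lattice.sum(axis=0)).ravel()) - lattice
        assert np.allclose(sys_.laplacian.toarray(), expected.toarray())

    def test_two_point_hand_computation(self):
        # f = (1, 4), beta = 2: q(1<-2) = 1/4, q(2<-1) = 4
        grid = lm.DensityGrid(np.array([1.0, 4.0]), (2,), (1.0,))
        sys_ = lm.smoluchowski_laplacian(grid, beta=2.0)
        lap = sys_.laplacian.toarray()
        # symmetrized off-diagonal -sqrt(q12*q21) = -1
        assert np.allclose(lap, [[4.0, -1.0], [-1.0, 0.25]])
        # Perron vector of the symmetrized operator is f^(beta/2) = (1, 4)
        v = np.array([1.0, 4.0])
        assert np.linalg.norm(lap @ v) < 1e-12

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_annihilates_f_to_beta_half(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
        f = rng.uniform(0.1, 5.0, size=int(np.prod(shape)))
        beta = float(rng.uniform(0.2, 4.0))
        grid = lm.DensityGrid(f, shape, (1.0, 1.0))
        sys_ = lm.smoluchowski_laplacian(grid, beta)
        v = f ** (beta / 2.0)
        assert np.linalg.norm(sys_.laplacian @ v) <= 1e-8 * np.linalg.norm(v)

    def test_rejects_zero_density(self):
        with pytest.raises(ValueError, match="strictly positive"):
            grid = lm.DensityGrid(np.array([1.0, 0.0]), (2,), (1.0,))
            lm.smoluchowski_laplacian(grid, 1.0)


class TestPreprocessStability:
    def test_symmetric_row_stochastic_is_fixed_point(self):
        # a symmetric matrix with unit row sums passes through every step
        # unchanged, so re-running the pipeline on it is a no-op
        a = np.array(
            [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        g = lm.WeightedGraph.from_dense(a)
        cfg = lm.SimilarityConfig(k_nn=2, k_min=0, min_weight_quantile=None)
        once = lm.adjacency_preprocess(g, cfg)
        assert np.allclose(once.dense(), a)
        twice = lm.adjacency_preprocess(once, cfg)
        assert np.allclose(twice.dense(), once.dense())
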