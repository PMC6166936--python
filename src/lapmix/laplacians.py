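"""Laplacian construction for the three input types.

All inputs — weighted graphs, feature tables, and gridded density
estimates — are reduced to a sparse symmetric Laplacian ``L = D - A``
before spectral analysis.  Graphs map directly; feature tables go through
a k-nearest-neighbor similarity graph; densities on a regular Cartesian
grid are discretized into a drift-diffusion (Smoluchowski-type) rate
matrix whose stationary distribution tracks the density, then symmetrized
by diagonal conjugation so that standard symmetric eigensolvers apply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist


__all__ = [
    "WeightedGraph",
    "LaplacianSystem",
    "SimilarityConfig",
    "DensityGrid",
    "build_laplacian",
    "symmetrize_detailed_balance",
    "similarity_graph",
    "adjacency_preprocess",
    "largest_connected_component",
    "smoluchowski_laplacian",
]


@dataclass
class WeightedGraph:
    """Simple undirected graph with edge weights in [0, 1].

    ``weights`` is a sparse symmetric matrix with zero diagonal; vertex
    ``i`` corresponds to row/column ``i``.
    """

    n_vertices: int
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.weights)
        if w.shape != (self.n_vertices, self.n_vertices):
            raise ValueError(
                f"weights shape {w.shape} does not match n_vertices={self.n_vertices}"
            )
        w.setdiag(0.0)
        w.eliminate_zeros()
        self.weights = w
        _check_symmetric_nonnegative(w)

    @classmethod
    def from_dense(cls, a: np.ndarray) -> "WeightedGraph":
        a = np.asarray(a, dtype=float)
        return cls(a.shape[0], sp.csr_matrix(a))

    def dense(self) -> np.ndarray:
        return self.weights.toarray()


def _check_symmetric_nonnegative(w: sp.spmatrix, tol: float = 1e-12) -> None:
    diff = (w - w.T).tocoo()
    if diff.nnz:
        bad = np.argmax(np.abs(diff.data))
        if np.abs(diff.data[bad]) > tol * max(1.0, np.abs(w).max()):
            raise ValueError(
                "adjacency is not symmetric: entry "
                f"({diff.row[bad]}, {diff.col[bad]}) differs from its "
                f"transpose by {diff.data[bad]:.3e}"
            )
    wc = w.tocoo()
    if wc.nnz:
        neg = wc.data < -tol
        if neg.any():
            i = int(np.argmax(neg))
            raise ValueError(
                f"negative edge weight {wc.data[i]:.3e} at ({wc.row[i]}, {wc.col[i]})"
            )
        if wc.data.max() > 1.0 + 1e-9:
            i = int(np.argmax(wc.data))
            raise ValueError(
                f"edge weight {wc.data[i]:.3e} at ({wc.row[i]}, {wc.col[i]}) "
                "exceeds 1; weights must lie in [0, 1]"
            )


@dataclass
class LaplacianSystem:
    """A symmetric Laplacian together with the bookkeeping the solver needs.

    ``sym_scaling`` holds the positive diagonal S used to symmetrize a
    detailed-balance rate matrix (None on the plain graph path).
    ``stationary`` is the stationary probability vector of the underlying
    Markov generator (uniform for graph Laplacians).
    """

    laplacian: sp.csr_matrix
    degree: np.ndarray
    source_tag: str = "graph"
    sym_scaling: np.ndarray | None = None
    stationary: np.ndarray | None = None
    grid_shape: tuple[int, ...] | None = None

    @property
    def n(self) -> int:
        return self.laplacian.shape[0]


def build_laplacian(graph: WeightedGraph) -> LaplacianSystem:
    """Weighted graph Laplacian L = D - A with exactly zero row sums."""
    a = graph.weights.tocsr()
    d = np.asarray(a.sum(axis=1)).ravel()
    lap = sp.diags(d) - a
    n = graph.n_vertices
    stat = np.full(n, 1.0 / n) if n else np.zeros(0)
    return LaplacianSystem(
        laplacian=lap.tocsr(), degree=d, source_tag="graph", stationary=stat
    )


def symmetrize_detailed_balance(
    rates: sp.spmatrix,
    stationary: np.ndarray,
    *,
    tol: float = 1e-8,
    source_tag: str = "graph",
    grid_shape: tuple[int, ...] | None = None,
) -> LaplacianSystem:
    """Symmetrize a detailed-balance rate matrix by diagonal conjugation.

    ``rates[i, j]`` is the transition rate into state ``i`` from state
    ``j`` (column convention), with nonnegative off-diagonal entries.
    Detailed balance ``pi_j q_ij = pi_i q_ji`` is required; the returned
    operator is ``S^-1 (D - Q) S`` with ``S = diag(sqrt(pi))``, which is
    symmetric and shares the eigenvalues of the unsymmetrized Laplacian
    ``D - Q`` (D holds column sums, so Q - D conserves probability).
    """
    q = sp.csr_matrix(rates, dtype=float)
    q.setdiag(0.0)
    q.eliminate_zeros()
    pi = np.asarray(stationary, dtype=float)
    if (pi <= 0).any():
        raise ValueError("stationary vector must be strictly positive")
    pi = pi / pi.sum()
    qc = q.tocoo()
    if (qc.data < 0).any():
        raise ValueError("off-diagonal rates must be nonnegative")
    flux_fwd = pi[qc.col] * qc.data  # pi_j q_ij
    flux_bwd = np.asarray(q.T[qc.row, qc.col]).ravel() * pi[qc.row]  # pi_i q_ji
    scale = max(flux_fwd.max(initial=0.0), 1e-300)
    viol = np.abs(flux_fwd - flux_bwd)
    if qc.nnz and viol.max() > tol * scale:
        k = int(np.argmax(viol))
        raise ValueError(
            "detailed balance violated at "
            f"({qc.row[k]}, {qc.col[k]}): |pi_j q_ij - pi_i q_ji| = {viol[k]:.3e}"
        )
    d = np.asarray(q.sum(axis=0)).ravel()  # column sums: outflow of each state
    lap = sp.diags(d) - q
    s = np.sqrt(pi)
    sym = sp.diags(1.0 / s) @ lap @ sp.diags(s)
    sym = 0.5 * (sym + sym.T)  # kill roundoff asymmetry
    return LaplacianSystem(
        laplacian=sym.tocsr(),
        degree=d,
        source_tag=source_tag,
        sym_scaling=s,
        stationary=pi,
        grid_shape=grid_shape,
    )


@dataclass
class SimilarityConfig:
    """Knobs for turning feature vectors or raw adjacencies into graphs.

    k_nn
        Nearest-neighbor cutoff: each item keeps only its ``k_nn``
        strongest similarities (sparsification).
    k_min
        Minimum strongly-connected neighbor count: each item's top
        ``k_min`` similarities are raised to at least the global
        ``min_weight_quantile`` value, guarding small clusters and
        outliers against disconnection.
    min_weight_quantile
        Quantile (over all pairwise weights) used both as the floor for
        weakly connected items and as the strengthening level for k_min.
        Set to ``None`` to disable the floor/strengthen steps.
    kernel_scale
        Length scale of the decaying similarity kernel, or ``"auto"``
        (median distance to the k_nn-th neighbor).
    kernel
        ``"gaussian"`` (default) or ``"inverse_quadratic"``.
    """

    k_nn: int = 125
    k_min: int = 0
    min_weight_quantile: float | None = 0.99
    kernel_scale: float | str = "auto"
    kernel: str = "gaussian"

    def validate(self, n: int) -> None:
        if not (0 <= self.k_min <= self.k_nn <= max(n - 1, 1)):
            raise ValueError(
                f"need 0 <= k_min ({self.k_min}) <= k_nn ({self.k_nn}) <= n-1 ({n - 1})"
            )


def _kernel_similarity(features: np.ndarray, config: SimilarityConfig) -> np.ndarray:
    dist = cdist(features, features)
    if config.kernel_scale == "auto":
        k = min(config.k_nn, features.shape[0] - 1)
        knn_dist = np.sort(dist, axis=1)[:, k]
        scale = float(np.median(knn_dist))
        if scale <= 0:
            scale = max(float(np.median(dist[dist > 0])) if (dist > 0).any() else 1.0, 1e-12)
    else:
        scale = float(config.kernel_scale)
        if scale <= 0:
            raise ValueError("kernel_scale must be positive")
    if config.kernel == "gaussian":
        sim = np.exp(-0.5 * (dist / scale) ** 2)
    elif config.kernel == "inverse_quadratic":
        sim = 1.0 / (1.0 + (dist / scale) ** 2)
    else:
        raise ValueError(f"unknown kernel {config.kernel!r}")
    np.fill_diagonal(sim, 0.0)
    return sim


def _sparsify_normalize(sim: np.ndarray, config: SimilarityConfig) -> np.ndarray:
    """Steps (2)-(7) of the similarity pipeline on a dense matrix."""
    n = sim.shape[0]
    off = ~np.eye(n, dtype=bool)
    if config.min_weight_quantile is not None:
        vals = sim[off]
        vals = vals[vals > 0] if (vals > 0).any() else vals
        q = float(np.quantile(vals, config.min_weight_quantile))
        # floor: weakly connected items get one edge raised to the quantile
        row_max = sim.max(axis=1)
        for i in np.nonzero(row_max < q)[0]:
            sim[i, int(np.argmax(sim[i]))] = q
        # strengthen each item's top k_min similarities
        if config.k_min > 0:
            order = np.argsort(sim, axis=1)[:, ::-1][:, : config.k_min]
            for i in range(n):
                js = order[i]
                sim[i, js] = np.maximum(sim[i, js], q)
    # nearest-neighbor cutoff; edges tied with the k-th largest are kept,
    # so the step is well defined on graphs with repeated weights
    k = min(config.k_nn, n - 1)
    if k < n - 1:
        thr = np.partition(sim, n - k, axis=1)[:, n - k]
        sim[sim < thr[:, None]] = 0.0
    # row-normalize to unit sum
    sums = sim.sum(axis=1)
    sums[sums == 0] = 1.0
    sim = sim / sums[:, None]
    # symmetrize by elementwise max, zero diagonal
    sim = np.maximum(sim, sim.T)
    np.fill_diagonal(sim, 0.0)
    return sim


def similarity_graph(features: np.ndarray, config: SimilarityConfig) -> WeightedGraph:
    """Build a sparse similarity graph from an items x dims feature matrix.

    Fixed pipeline: decaying kernel of Euclidean distance; quantile floor
    for weakly connected items; k_min strengthening; k_nn cutoff; row
    normalization to unit sum; elementwise-max symmetrization; zero
    diagonal.  Warns (with a component report) if the result is
    disconnected — callers usually extract the largest component.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 items")
    if not np.isfinite(features).all():
        raise ValueError("feature matrix contains non-finite values")
    config.validate(features.shape[0])
    sim = _kernel_similarity(features, config)
    sim = _sparsify_normalize(sim, config)
    graph = WeightedGraph.from_dense(sim)
    _warn_if_disconnected(graph)
    return graph


def adjacency_preprocess(graph: WeightedGraph, config: SimilarityConfig) -> WeightedGraph:
    """Apply the sparsify/normalize/symmetrize steps to a raw adjacency.

    This is the network path: k_min strengthening at the quantile level,
    k_nn cutoff, row normalization, elementwise-max symmetrization.
    Zero-degree vertices are reported and kept isolated.
    """
    config.validate(graph.n_vertices)
    sim = graph.dense().astype(float)
    deg0 = np.nonzero(sim.sum(axis=1) == 0)[0]
    if deg0.size:
        warnings.warn(
            f"{deg0.size} zero-degree vertices kept as isolated: {deg0[:10].tolist()}"
        )
    out = _sparsify_normalize(sim, config)
    out[deg0, :] = 0.0
    out[:, deg0] = 0.0
    return WeightedGraph.from_dense(out)


def _warn_if_disconnected(graph: WeightedGraph) -> None:
    n_comp, labels = sp.csgraph.connected_components(graph.weights, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        warnings.warn(
            f"similarity graph has {n_comp} connected components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)}; consider "
            "largest_connected_component()"
        )


def largest_connected_component(
    graph: WeightedGraph,
) -> tuple[WeightedGraph, np.ndarray]:
    """Vertex-induced subgraph of the largest component.

    Returns the subgraph and the array of original vertex indices kept
    (old index of new vertex ``i`` is ``index_map[i]``).
    """
    n_comp, labels = sp.csgraph.connected_components(graph.weights, directed=False)
    if n_comp <= 1:
        return graph, np.arange(graph.n_vertices)
    keep = np.nonzero(labels == np.argmax(np.bincount(labels)))[0]
    sub = graph.weights[np.ix_(keep, keep)]
    return WeightedGraph(keep.size, sp.csr_matrix(sub)), keep


@dataclass
class DensityGrid:
    """Nonnegative density values sampled on a regular Cartesian grid."""

    values: np.ndarray
    shape: tuple[int, ...]
    spacing: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        self.shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        if v.size != int(np.prod(self.shape)):
            raise ValueError(
                f"{v.size} values do not fill a grid of shape {self.shape}"
            )
        if self.spacing is None:
            self.spacing = tuple(1.0 for _ in self.shape)
        else:
            self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(self.spacing) != len(self.shape):
            raise ValueError("spacing and shape dimensionality differ")
        if (v < 0).any():
            raise ValueError("density values must be nonnegative")
        if not (v > 0).any():
            raise ValueError("density must be strictly positive somewhere")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def normalized(self) -> np.ndarray:
        """Values rescaled to a probability vector (sum x cell volume = 1)."""
        return self.values / (self.values.sum() * self.cell_volume)


def _lattice_neighbor_pairs(shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) of von Neumann lattice neighbors, reflecting edges."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    rows, cols = [], []
    for axis in range(len(shape)):
        a = np.take(idx, np.arange(shape[axis] - 1), axis=axis).ravel()
        b = np.take(idx, np.arange(1, shape[axis]), axis=axis).ravel()
        rows.append(a)
        cols.append(b)
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    return np.concatenate([i, j]), np.concatenate([j, i])


def smoluchowski_laplacian(grid: DensityGrid, beta: float) -> LaplacianSystem:
    """Discrete drift-diffusion operator whose stationary law tracks ``f^beta``.

    Off-diagonal rates couple lattice nearest neighbors only, with
    ``q(i<-j) = (f_i / f_j)^(beta/2)``; the diagonal conserves
    probability, and boundaries are reflecting (edge nodes simply have
    fewer neighbors).  The operator is returned in its detailed-balance
    symmetrized form, whose Perron vector is proportional to
    ``f^(beta/2)`` — the inverse-temperature parameter beta sharpens
    (beta large) or flattens (beta -> 0) the density's influence.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    f = grid.values
    if (f <= 0).any():
        bad = int(np.argmin(f))
        raise ValueError(
            f"density must be strictly positive on the grid; value {f[bad]:.3e} "
            f"at flat index {bad} (grid index {np.unravel_index(bad, grid.shape)})"
        )
    i, j = _lattice_neighbor_pairs(grid.shape)
    logf = np.log(f)
    rates = np.exp(0.5 * beta * (logf[i] - logf[j]))
    q = sp.csr_matrix((rates, (i, j)), shape=(grid.n, grid.n))
    pi = np.exp(beta * (logf - logf.max()))
    return symmetrize_detailed_balance(
        q, pi, source_tag="density", grid_shape=grid.shape
    )
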