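"""Synthetic inputs with known ground truth.

Interpolating cluster graphs blend a union of complete blocks with the
complete graph through a separation parameter epsilon, and admit
closed-form eigenvectors and a closed-form optimal partition — the
analytic oracle every numerical component is validated against.  A
uniform-mixing noise model (optionally with fully connected outlier
vertices) corrupts them, and randomized radial-basis mixture densities
provide ground truth for the density-unmixing path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .laplacians import DensityGrid, WeightedGraph, build_laplacian

__all__ = [
    "ClusterGraphSpec",
    "NoiseSpec",
    "MixtureDensitySpec",
    "interpolating_cluster_graph",
    "analytic_eigenvectors",
    "analytic_solution",
    "add_noise",
    "radial_mixture_density",
]


@dataclass
class ClusterGraphSpec:
    """K complete blocks of given sizes, cross-linked with weight 1 - epsilon.

    epsilon = 1 gives the disjoint cluster graph; epsilon = 0 the
    complete graph.  In between every vertex pair is connected, but
    within-block edges (weight 1) dominate cross-block edges.
    """

    K: int
    sizes: tuple[int, ...]
    epsilon: float

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if self.K < 2 or len(self.sizes) != self.K:
            raise ValueError("need K >= 2 block sizes")
        if any(s < 1 for s in self.sizes):
            raise ValueError("block sizes must be >= 1")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")

    @property
    def n(self) -> int:
        return sum(self.sizes)

    @property
    def block_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.K), self.sizes)


def interpolating_cluster_graph(spec: ClusterGraphSpec) -> WeightedGraph:
    """Adjacency with within-block weight 1, cross-block 1 - epsilon, zero diagonal."""
    labels = spec.block_labels
    same = labels[:, None] == labels[None, :]
    b = np.where(same, 1.0, 1.0 - spec.epsilon)
    np.fill_diagonal(b, 0.0)
    return WeightedGraph.from_dense(b)


def analytic_eigenvectors(spec: ClusterGraphSpec) -> np.ndarray:
    """Closed-form low eigenvectors of the interpolating cluster graph.

    Column 0 is the constant vector; column j (1..K-1) equals 1 on block
    1, -N_1/N_{j+1} on block j+1, and 0 elsewhere — each an eigenvector
    of the Laplacian with eigenvalue N(1 - epsilon) (multiplicity K-1).
    The eigen-residual is verified numerically at construction.
    """
    if spec.epsilon >= 1.0:
        raise ValueError("epsilon must be < 1 (connected graph)")
    n, K = spec.n, spec.K
    labels = spec.block_labels
    phi = np.zeros((n, K))
    phi[:, 0] = 1.0
    for j in range(1, K):
        phi[labels == 0, j] = 1.0
        phi[labels == j, j] = -spec.sizes[0] / spec.sizes[j]
    lap = build_laplacian(interpolating_cluster_graph(spec)).laplacian
    lam = n * (1.0 - spec.epsilon)
    for j in range(1, K):
        resid = np.linalg.norm(lap @ phi[:, j] - lam * phi[:, j])
        if resid > 1e-8 * max(1.0, np.linalg.norm(lam * phi[:, j])):
            raise AssertionError(
                f"analytic eigenvector {j} residual {resid:.3e} exceeds tolerance"
            )
    return phi


def analytic_solution(spec: ClusterGraphSpec) -> np.ndarray:
    """Closed-form optimal partition: the exact binary block indicator.

    p_1 = (1/N) sum_i N_i phi_{i-1}; the remaining components are
    p_j = (N_j / N_1)(p_1 - phi_{j-1}).  Zero loss by construction.
    """
    phi = analytic_eigenvectors(spec)
    n, K = spec.n, spec.K
    sizes = np.asarray(spec.sizes, dtype=float)
    p = np.zeros((n, K))
    p[:, 0] = (phi * sizes[None, :]).sum(axis=1) / n
    for j in range(1, K):
        p[:, j] = (sizes[j] / sizes[0]) * (p[:, 0] - phi[:, j])
    binary = np.where(p > 0.5, 1.0, 0.0)
    if np.abs(p - binary).max() > 1e-10:
        raise AssertionError("analytic solution is not binary to tolerance")
    return binary


@dataclass
class NoiseSpec:
    """Uniform edge-mixing noise plus optional fully connected outliers.

    Each unordered edge weight moves toward an independent U(0, 1) draw:
    b~ = (1 - alpha) b + alpha u, keeping weights in [0, 1].  ``n_out``
    outlier vertices with i.i.d. U(0, 1) edges to every other vertex are
    appended before the mixing step.
    """

    alpha: float = 0.0
    n_out: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_out < 0:
            raise ValueError("n_out must be nonnegative")


def add_noise(graph: WeightedGraph, noise: NoiseSpec) -> WeightedGraph:
    """Corrupt a graph per the uniform-mixing noise model (seeded)."""
    rng = np.random.default_rng(noise.seed)
    b = graph.dense()
    n0 = b.shape[0]
    if noise.n_out > 0:
        n = n0 + noise.n_out
        bb = np.zeros((n, n))
        bb[:n0, :n0] = b
        iu = np.triu_indices(n, k=1)
        outlier = (iu[0] >= n0) | (iu[1] >= n0)
        u = rng.uniform(size=int(outlier.sum()))
        bb[iu[0][outlier], iu[1][outlier]] = u
        bb[iu[1][outlier], iu[0][outlier]] = u
        b = bb
    if noise.alpha > 0.0:
        n = b.shape[0]
        iu = np.triu_indices(n, k=1)
        u = rng.uniform(size=iu[0].size)
        mixed = (1.0 - noise.alpha) * b[iu] + noise.alpha * u
        b[iu] = mixed
        b[(iu[1], iu[0])] = mixed
    np.fill_diagonal(b, 0.0)
    return WeightedGraph.from_dense(b)


@dataclass
class MixtureDensitySpec:
    """Randomized radial-basis mixture on a regular grid.

    Each component is a sum of ``n_basis`` anisotropic radial functions
    of one profile family (gaussian, laplace, or sech), with randomized
    centers and covariance transforms.  Components are individually
    normalized and superimposed with equal mass by default.
    """

    n_components: int = 3
    profiles: tuple[str, ...] = ("gaussian", "laplace", "sech")
    grid_shape: tuple[int, ...] = (200, 200)
    extent: tuple[tuple[float, float], ...] = ((-10.0, 10.0), (-10.0, 10.0))
    n_basis: int = 3
    center_spread: float = 6.0
    scale_range: tuple[float, float] = (0.6, 1.6)
    floor: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        self.profiles = tuple(self.profiles)
        if len(self.profiles) != self.n_components:
            raise ValueError("need one profile per component")
        unknown = set(self.profiles) - {"gaussian", "laplace", "sech"}
        if unknown:
            raise ValueError(f"unknown radial profiles: {sorted(unknown)}")
        if len(self.extent) != len(self.grid_shape):
            raise ValueError("extent and grid_shape dimensionality differ")


_PROFILES = {
    "gaussian": lambda r: np.exp(-0.5 * r * r),
    "laplace": lambda r: np.exp(-r),
    "sech": lambda r: 1.0 / np.cosh(r),
}


def _grid_points(spec: MixtureDensitySpec) -> tuple[np.ndarray, tuple[float, ...]]:
    axes, spacing = [], []
    for (lo, hi), npts in zip(spec.extent, spec.grid_shape):
        ax = np.linspace(lo, hi, npts)
        axes.append(ax)
        spacing.append(float(ax[1] - ax[0]) if npts > 1 else 1.0)
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    return pts, tuple(spacing)


def radial_mixture_density(
    spec: MixtureDensitySpec,
) -> tuple[DensityGrid, np.ndarray]:
    """Generate the mixture density and its true components on the grid.

    Returns ``(grid, components)`` where ``components`` is (n_points,
    n_components) with each column integrating to one, and the grid
    values are proportional to the equal-weight superposition (plus a
    tiny positivity floor so log-ratios are defined everywhere).
    """
    rng = np.random.default_rng(spec.seed)
    pts, spacing = _grid_points(spec)
    dim = pts.shape[1]
    cell = float(np.prod(spacing))
    comps = np.zeros((pts.shape[0], spec.n_components))
    # well-separated component centers by jittered placement on a circle/line
    base_angles = np.linspace(0, 2 * np.pi, spec.n_components, endpoint=False)
    for k, profile in enumerate(spec.profiles):
        fn = _PROFILES[profile]
        if dim >= 2:
            center_k = spec.center_spread * np.array(
                [np.cos(base_angles[k]), np.sin(base_angles[k])] + [0.0] * (dim - 2)
            )
        else:
            span = spec.center_spread
            center_k = np.array(
                [-span + 2 * span * k / max(spec.n_components - 1, 1)]
            )
        for _ in range(spec.n_basis):
            c = center_k + rng.normal(scale=0.15 * spec.center_spread, size=dim)
            scales = rng.uniform(*spec.scale_range, size=dim)
            if dim > 1:
                q, _r = np.linalg.qr(rng.normal(size=(dim, dim)))
                transform = q / scales[:, None]
            else:
                transform = np.eye(1) / scales[:, None]
            r = np.linalg.norm((pts - c) @ transform.T, axis=1)
            comps[:, k] += fn(r)
        total = comps[:, k].sum() * cell
        if total <= 0:
            raise ValueError(f"component {k} vanished on the grid (too coarse)")
        comps[:, k] /= total
    f = comps.mean(axis=1) + spec.floor
    grid = DensityGrid(values=f, shape=spec.grid_shape, spacing=spacing)
    return grid, comps
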