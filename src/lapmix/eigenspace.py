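"""Low eigenspace of the symmetric Laplacian.

The solver consumes the first m eigenvectors (ascending eigenvalue
magnitude) of the symmetric system.  The Perron-Frobenius vector phi_0 is
sign-fixed positive; its entrywise square is the stationary weight used
for all expectations, and the ratio matrix omega = phi_k / phi_0 is the
basis the partition-of-unity estimate is expanded in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["EigenBasis", "compute_eigenbasis", "basis_ratios"]

_DENSE_FALLBACK_N = 4000


@dataclass
class EigenBasis:
    """First m orthonormal eigenvectors of a symmetric Laplacian.

    vectors : (N, m) orthonormal columns phi_0 .. phi_{m-1}
    eigenvalues : ascending magnitudes lambda_0 .. lambda_{m-1}
    weight : phi_0**2, normalized to sum to one (the expectation weight)
    ratios : omega with omega[:, k] = phi_k / phi_0; column 0 is all ones
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    weight: np.ndarray
    ratios: np.ndarray

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def m(self) -> int:
        return self.vectors.shape[1]

    def truncate(self, m: int) -> "EigenBasis":
        """Sub-basis of the first m eigenpairs (no recomputation)."""
        if not 1 <= m <= self.m:
            raise ValueError(f"cannot truncate basis of size {self.m} to m={m}")
        return EigenBasis(
            vectors=self.vectors[:, :m],
            eigenvalues=self.eigenvalues[:m],
            weight=self.weight,
            ratios=self.ratios[:, :m],
        )


def _small_eigenpairs(lap: sp.csr_matrix, m: int) -> tuple[np.ndarray, np.ndarray]:
    n = lap.shape[0]
    if n <= max(3 * m, 200) or m >= n - 1:
        vals, vecs = np.linalg.eigh(lap.toarray())
        return vals[:m], vecs[:, :m]
    # shift-invert about a slightly negative sigma: L - sigma*I is PD for
    # PSD Laplacians, making the factorization robust at lambda_0 = 0
    sigma = -1e-3 * max(float(lap.diagonal().mean()), 1e-12)
    try:
        vals, vecs = spla.eigsh(lap, k=m, sigma=sigma, which="LM")
    except Exception:
        if n <= _DENSE_FALLBACK_N:
            dense_vals, dense_vecs = np.linalg.eigh(lap.toarray())
            return dense_vals[:m], dense_vecs[:, :m]
        raise
    order = np.argsort(vals)
    return vals[order], vecs[:, order]


def compute_eigenbasis(system, m: int) -> EigenBasis:
    """Compute the first ``m`` eigenpairs of a :class:`LaplacianSystem`.

    Uses a sparse shift-invert eigensolver with a dense fallback for
    small systems.  phi_0 is flipped entrywise positive (its positivity
    is also the connectedness diagnostic); the remaining columns are
    sign-fixed so their largest-magnitude entry is positive, which makes
    the basis deterministic across solver backends.
    """
    if m < 2:
        raise ValueError("need m >= 2 eigenvectors")
    lap = system.laplacian
    if m > lap.shape[0]:
        raise ValueError(f"m={m} exceeds system size {lap.shape[0]}")
    asym = abs(lap - lap.T).max()
    if asym > 1e-10 * max(abs(lap).max(), 1e-300):
        raise ValueError("system is not symmetric; symmetrize before eigensolving")
    vals, vecs = _small_eigenpairs(sp.csr_matrix(lap), m)

    phi0 = vecs[:, 0]
    if phi0.sum() < 0:
        phi0 = -phi0
    floor = -1e-8 * np.abs(phi0).max()
    if phi0.min() < floor:
        raise ValueError(
            "Perron vector has a negative entry "
            f"({phi0.min():.3e} at vertex {int(np.argmin(phi0))}); the graph "
            "is likely disconnected — extract the largest component first"
        )
    phi0 = np.abs(phi0)
    vecs = vecs.copy()
    vecs[:, 0] = phi0
    for k in range(1, m):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]

    weight = phi0**2
    weight = weight / weight.sum()
    basis = EigenBasis(
        vectors=vecs,
        eigenvalues=np.asarray(vals, dtype=float),
        weight=weight,
        ratios=np.empty(0),
    )
    basis.ratios = basis_ratios(basis)
    return basis


def basis_ratios(basis: EigenBasis) -> np.ndarray:
    """Ratio matrix omega_ik = phi_k(i) / phi_0(i); column 0 is exactly 1."""
    phi0 = basis.vectors[:, 0]
    eps_div = 1e-12 * np.abs(phi0).max()
    if (phi0 < eps_div).any():
        v = int(np.argmin(phi0))
        raise ValueError(
            f"phi_0 entry {phi0[v]:.3e} at vertex {v} is below the division "
            "floor; the graph is effectively disconnected there"
        )
    omega = basis.vectors / phi0[:, None]
    omega[:, 0] = 1.0
    return omega
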