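"""Assembly of the fitted Laplacian mixture model.

Given the optimized transform M* and the eigenbasis, this module builds
the partition-of-unity matrix p, component weights a_k, hard labels,
per-component fuzziness scores, and (on the density path) the unmixed
component densities f_k = p_k f / a_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eigenspace import EigenBasis
from .optimizer import SearchParams, SolveResult, check_feasible, solve

__all__ = [
    "LaplacianMixtureModel",
    "conditional_probabilities",
    "component_weights",
    "component_densities",
    "hard_threshold",
    "component_losses",
    "fit_model",
]


@dataclass
class LaplacianMixtureModel:
    """A fitted m-component soft partition.

    p : (N, m) conditional probabilities, rows summing to 1, clipped to [0, 1]
    M_star : optimized expansion-coefficient matrix
    loss : 1 - tr(M*^T M*), the model's total fuzziness in [0, 1)
    component_losses : per-component fuzziness c_k in [0, 1]
    weights : component masses a_k summing to 1
    labels : argmax hard assignments (0-based)
    """

    p: np.ndarray
    M_star: np.ndarray
    loss: float
    component_losses: np.ndarray
    weights: np.ndarray
    labels: np.ndarray
    m: int
    clip_magnitude: float = 0.0
    report: dict = field(default_factory=dict)


def conditional_probabilities(M: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """p(x)^T = M omega(x) for a feasible M; rows sum to one exactly."""
    M = np.asarray(M, dtype=float)
    m = M.shape[0]
    ok, viol = check_feasible(M, basis)
    if not ok:
        raise ValueError(f"infeasible transform matrix (violation {viol:.3e})")
    return basis.ratios[:, :m] @ M.T


def component_weights(p: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Component masses a_k = sum_x p_k(x) w(x); sums to one."""
    w = np.asarray(weight, dtype=float)
    return p.T @ (w / w.sum())


def component_densities(
    p: np.ndarray, f: np.ndarray, cell_volume: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Unmixed component densities f_k = p_k f / a_k on the density path.

    ``f`` is the input mixture density on the grid (normalized
    internally).  Returns (densities, weights) with each density column
    integrating to one and ``sum_k a_k f_k`` reproducing ``f`` exactly.
    """
    f = np.asarray(f, dtype=float)
    fn = f / (f.sum() * cell_volume)
    a = p.T @ fn * cell_volume
    dens = np.empty_like(p)
    for k in range(p.shape[1]):
        if a[k] < 1e-12:
            raise ValueError(f"component {k} is empty (weight {a[k]:.3e})")
        dens[:, k] = p[:, k] * fn / a[k]
    return dens, a


def hard_threshold(p: np.ndarray) -> np.ndarray:
    """Argmax labels; ties go to the lowest component index."""
    return np.argmax(p, axis=1)


def component_losses(p: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Per-component fuzziness c_k = 1 - <p_k^2>_w / <p_k>_w.

    Zero iff the component is perfectly binary; an empty component
    (zero mass) scores 1.
    """
    w = np.asarray(weight, dtype=float)
    w = w / w.sum()
    first = p.T @ w
    second = (p * p).T @ w
    c = np.ones_like(first)
    nz = first > 0
    c[nz] = 1.0 - second[nz] / first[nz]
    return c


def assemble(result: SolveResult, basis: EigenBasis) -> LaplacianMixtureModel:
    """Build the full model object from a successful solve."""
    if not result.ok or result.p is None:
        raise ValueError(f"cannot assemble a model from status {result.status!r}")
    p_raw = result.p
    clip = float(max(0.0, -p_raw.min(), p_raw.max() - 1.0))
    p = np.clip(p_raw, 0.0, 1.0)
    labels = hard_threshold(p)
    return LaplacianMixtureModel(
        p=p,
        M_star=result.M,
        loss=result.loss,
        component_losses=component_losses(p, basis.weight),
        weights=component_weights(p, basis.weight),
        labels=labels,
        m=p.shape[1],
        clip_magnitude=clip,
        report=result.report,
    )


def fit_model(
    basis: EigenBasis, m: int | None = None, params: SearchParams | None = None
) -> LaplacianMixtureModel:
    """Solve the global optimization and assemble the model.

    Raises ``RuntimeError`` when no nondegenerate m-factor solution is
    found (use :func:`lapmix.optimizer.solve` directly to inspect the
    per-restart report instead).
    """
    result = solve(basis, params, m=m)
    if not result.ok:
        raise RuntimeError(f"no {m or basis.m}-factor solution found")
    return assemble(result, basis)
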