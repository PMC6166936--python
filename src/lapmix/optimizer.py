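"""Global optimization of the partition-of-unity transform matrix.

The model is p-hat = M omega with M an m x m expansion-coefficient
matrix, subject to M^T e = e_1 (rows of p sum to one) and
(M omega)(x) >= 0 at every item x.  The quadratic loss
L(M) = 1 - tr(M^T M) is concave, so its minimum over the constraint
polytope sits at a vertex; we attack the (NP-hard) problem with a
multi-start modified Frank-Wolfe heuristic: each sweep linearizes the
objective at the current point and jumps to the vertex returned by a
linear program, descending monotonically until no improvement remains.
Candidates for which some component captures no item under argmax hard
assignment are rejected as degenerate (assigned infinite loss), which is
how invertibility of M is enforced in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .eigenspace import EigenBasis

__all__ = [
    "SearchParams",
    "SolveResult",
    "loss",
    "check_feasible",
    "uniform_start",
    "frank_wolfe_local",
    "solve",
]


@dataclass
class SearchParams:
    """Multi-start search parameters.

    ``n_restarts`` defaults to ``32 * m`` when left at 0 (resolved at
    solve time); every source of randomness derives from ``seed``.
    """

    n_restarts: int = 0
    seed: int = 0
    max_fw_iters: int = 100
    tol_obj: float = 1e-10
    tol_feas: float = 1e-9

    def resolved_restarts(self, m: int) -> int:
        return self.n_restarts if self.n_restarts > 0 else 32 * m

    def validate(self) -> None:
        if self.max_fw_iters <= 0 or self.tol_obj <= 0 or self.tol_feas <= 0:
            raise ValueError("max_fw_iters, tol_obj, tol_feas must be positive")


@dataclass
class SolveResult:
    """Outcome of the multi-start search.

    ``status`` is "ok", "degenerate" (no restart produced a nondegenerate
    candidate: there is no m-factor solution), or "trivial" (m = 1).
    """

    M: np.ndarray | None
    loss: float
    p: np.ndarray | None
    status: str
    report: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status in ("ok", "trivial")


def loss(M: np.ndarray) -> float:
    """Quadratic fuzziness loss L = 1 - ||M||_F^2."""
    M = np.asarray(M, dtype=float)
    return 1.0 - float(np.sum(M * M))


def uniform_start(m: int) -> np.ndarray:
    """The maximally fuzzy interior point: p identically 1/m."""
    M = np.zeros((m, m))
    M[:, 0] = 1.0 / m
    return M


def check_feasible(
    M: np.ndarray, basis: EigenBasis, tol_feas: float = 1e-9
) -> tuple[bool, float]:
    """Check M^T e = e_1 and (M omega)(x) >= 0; returns (ok, max violation)."""
    M = np.asarray(M, dtype=float)
    m = M.shape[0]
    e1 = np.zeros(m)
    e1[0] = 1.0
    eq_viol = float(np.abs(M.sum(axis=0) - e1).max())
    p = basis.ratios[:, :m] @ M.T
    ineq_viol = float(max(0.0, -p.min()))
    viol = max(eq_viol, ineq_viol)
    return viol <= tol_feas, viol


def _lp_vertex(
    M_t: np.ndarray, omega: np.ndarray, a_ub: sp.csr_matrix, a_eq: np.ndarray
) -> np.ndarray | None:
    """One Frank-Wolfe step: maximize <M_t, M> over the polytope via LP."""
    m = M_t.shape[0]
    c = -M_t.ravel()
    b_eq = np.zeros(m)
    b_eq[0] = 1.0
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=np.zeros(a_ub.shape[0]),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(None, None),
        method="highs",
    )
    if not res.success:
        return None
    return res.x.reshape(m, m)


def _constraint_matrices(omega: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    """Constraint data for M flattened row-major (index k*m + j).

    Inequalities: -(M omega)(x)_k <= 0 for every item x and component k,
    i.e. -kron(I_m, omega).  Equalities: column sums of M equal e_1.
    """
    n, m = omega.shape
    a_ub = -sp.kron(sp.eye(m, format="csr"), sp.csr_matrix(omega), format="csr")
    a_eq = np.kron(np.ones((1, m)), np.eye(m))
    return a_ub, a_eq


def _descend(
    M0: np.ndarray,
    omega: np.ndarray,
    a_ub: sp.csr_matrix,
    a_eq: np.ndarray,
    params: SearchParams,
) -> list[np.ndarray]:
    """Monotone Frank-Wolfe descent; returns the vertex iterates in order.

    Each iteration solves the LP maximizing tr(M_t^T M) (the
    linearization of -L at M_t); by concavity the returned vertex never
    increases the loss, and the sweep stops once the improvement drops
    below ``tol_obj``.
    """
    M_t = np.asarray(M0, dtype=float)
    path: list[np.ndarray] = []
    for _ in range(params.max_fw_iters):
        M_new = _lp_vertex(M_t, omega, a_ub, a_eq)
        if M_new is None:
            break
        if loss(M_new) < loss(M_t):
            path.append(M_new)
        if loss(M_new) >= loss(M_t) - params.tol_obj:
            break
        M_t = M_new
    if not path:
        path.append(M_t)
    return path


_BACKTRACK_STEPS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


def _descend_admissible(
    M0: np.ndarray,
    omega: np.ndarray,
    a_ub: sp.csr_matrix,
    a_eq: np.ndarray,
    params: SearchParams,
    m: int,
) -> list[np.ndarray]:
    """Degeneracy-aware descent; returns the nondegenerate points visited.

    The minimum-loss polytope vertices are very often degenerate (some
    component empty under argmax), and pure Frank-Wolfe descent drains
    into them, so the admissible optimum may not sit at a vertex at all.
    This variant collects every nondegenerate feasible point it visits —
    the start (when it is a sampled vertex), improving LP vertices, and
    backtracked partial steps taken when the LP vertex is degenerate
    (the largest step toward it that keeps all components occupied,
    after which the objective is relinearized).
    """
    M = np.asarray(M0, dtype=float)
    cands: list[np.ndarray] = []
    if not is_degenerate(omega @ M.T, m):
        cands.append(M)
    for _ in range(params.max_fw_iters):
        V = _lp_vertex(M, omega, a_ub, a_eq)
        if V is None:
            break
        nondeg = not is_degenerate(omega @ V.T, m)
        if nondeg:
            cands.append(V)
        if loss(V) >= loss(M) - params.tol_obj:
            break
        if nondeg:
            M = V
            continue
        moved = False
        for s in _BACKTRACK_STEPS:
            Mi = M + s * (V - M)
            if loss(Mi) < loss(M) - params.tol_obj and not is_degenerate(
                omega @ Mi.T, m
            ):
                cands.append(Mi)
                M = Mi
                moved = True
                break
        if not moved:
            break
    return cands


def frank_wolfe_local(
    M0: np.ndarray,
    basis: EigenBasis,
    params: SearchParams,
    *,
    _constraints=None,
) -> np.ndarray:
    """Descend from a feasible M0 to a local-minimum polytope vertex."""
    params.validate()
    m = M0.shape[0]
    omega = basis.ratios[:, :m]
    ok, viol = check_feasible(M0, basis, params.tol_feas)
    if not ok:
        raise ValueError(f"starting point infeasible (violation {viol:.3e})")
    a_ub, a_eq = _constraints if _constraints is not None else _constraint_matrices(omega)
    return _descend(M0, omega, a_ub, a_eq, params)[-1]


def _farthest_point_anchors(omega: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """m anchor items by farthest-point sampling in the omega row space.

    Distances between omega rows are invariant to orthonormal rotations
    of degenerate eigenspaces, which is what makes the restart scheme
    rotation invariant.
    """
    n = omega.shape[0]
    anchors = [int(rng.integers(n))]
    d = np.linalg.norm(omega - omega[anchors[0]], axis=1)
    while len(anchors) < m:
        nxt = int(np.argmax(d))
        anchors.append(nxt)
        d = np.minimum(d, np.linalg.norm(omega - omega[nxt], axis=1))
    return np.asarray(anchors)


def _anchor_start(
    omega: np.ndarray, m: int, rng: np.random.Generator, tol_feas: float
) -> np.ndarray | None:
    """Feasible start mapping m anchor items toward distinct component vertices.

    Solves M W = I for W the m x m matrix of anchor omega rows (so each
    anchor's p row is a one-hot), then shrinks toward the uniform start
    until the nonnegativity constraints hold.  The equality constraint
    M^T e = e_1 is automatic because the first omega coordinate is 1.
    """
    anchors = _farthest_point_anchors(omega, m, rng)
    W = omega[anchors].T  # columns are anchor omega rows
    if np.linalg.cond(W) > 1e10:
        return None
    M = np.linalg.solve(W.T, np.eye(m)).T  # M @ W = I
    p = omega @ M.T
    p_min = float(p.min())
    if p_min >= -tol_feas:
        return M
    # p(t) = t*p + (1-t)/m; keep min >= 0 with a small safety margin
    t = (1.0 / m) / (1.0 / m - p_min)
    t *= 0.999
    M_u = uniform_start(m)
    return t * M + (1.0 - t) * M_u


def hard_labels(p: np.ndarray) -> np.ndarray:
    """Argmax component per item; ties broken toward the lowest index."""
    return np.argmax(p, axis=1)


def is_degenerate(p: np.ndarray, m: int) -> bool:
    """True if some component captures no item under hard assignment."""
    counts = np.bincount(hard_labels(p), minlength=m)
    return bool((counts == 0).any())


def solve(basis: EigenBasis, params: SearchParams | None = None, m: int | None = None) -> SolveResult:
    """Multi-start search for the minimum-loss nondegenerate model.

    Restarts alternate between two seeded vertex-sampling strategies —
    farthest-point anchor starts in the omega row space, and polytope
    vertices drawn by maximizing random linear directions — each
    followed by monotone Frank-Wolfe descent.  Every vertex visited on a
    descent path is a candidate; degenerate candidates (some component
    empty under argmax hard assignment) receive infinite loss, and the
    minimum-loss admissible vertex over all paths wins.  Returns a
    ``SolveResult`` with status "degenerate" (not an exception) when no
    admissible candidate exists.
    """
    params = params or SearchParams()
    m = m if m is not None else basis.m
    if m < 1 or m > basis.m:
        raise ValueError(f"m={m} outside 1..{basis.m}")
    if m == 1:
        p = np.ones((basis.n, 1))
        return SolveResult(np.ones((1, 1)), 0.0, p, "trivial")

    omega = basis.ratios[:, :m]
    a_ub, a_eq = _constraint_matrices(omega)
    n_restarts = params.resolved_restarts(m)
    rng_root = np.random.default_rng(params.seed)
    child_seeds = rng_root.integers(0, 2**31 - 1, size=n_restarts)

    best_M, best_loss, best_p = None, np.inf, None
    restart_log = []
    for r in range(n_restarts):
        rng = np.random.default_rng(int(child_seeds[r]))
        if r == 0:
            M0 = uniform_start(m)
        elif r % 2 == 1:
            M0 = _anchor_start(omega, m, rng, params.tol_feas)
        else:
            # a random polytope vertex: maximize a random linear direction
            M0 = _lp_vertex(rng.normal(size=(m, m)), omega, a_ub, a_eq)
        if M0 is None:
            restart_log.append({"restart": r, "status": "start_failed"})
            continue
        cands = _descend_admissible(M0, omega, a_ub, a_eq, params, m)
        if not cands:
            restart_log.append({"restart": r, "status": "degenerate"})
            continue
        losses = [loss(M_s) for M_s in cands]
        i_best = int(np.argmin(losses))
        L_s, M_s = losses[i_best], cands[i_best]
        restart_log.append({"restart": r, "status": "ok", "loss": L_s,
                            "n_candidates": len(cands)})
        if L_s < best_loss:
            best_M, best_loss, best_p = M_s, L_s, omega @ M_s.T

    report = {
        "m": m,
        "seed": params.seed,
        "n_restarts": n_restarts,
        "restarts": restart_log,
        "loss": None if best_M is None else best_loss,
    }
    if best_M is None:
        return SolveResult(None, np.inf, None, "degenerate", report)
    return SolveResult(best_M, best_loss, best_p, "ok", report)
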