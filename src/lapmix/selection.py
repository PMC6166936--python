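"""Evaluation metrics and model/parameter selection.

Covers labeling error under optimal component matching, relative
unmixing error for recovered densities, the inverse-temperature (beta)
grid search on the density path, silhouette-vs-loss robust-fit model
selection, and the (k_min, k_NN) sparsification grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

from .eigenspace import compute_eigenbasis
from .laplacians import (
    DensityGrid,
    SimilarityConfig,
    WeightedGraph,
    adjacency_preprocess,
    build_laplacian,
    largest_connected_component,
    smoluchowski_laplacian,
)
from .model import LaplacianMixtureModel, component_densities, fit_model
from .optimizer import SearchParams, solve

__all__ = [
    "ModelSequence",
    "labeling_errors",
    "relative_error",
    "beta_search",
    "silhouette_profile",
    "select_model",
    "knn_grid_search",
    "fit_model_sequence",
]


@dataclass
class ModelSequence:
    """Models for m = 2..m_max, truncated at the first unsolvable m."""

    models: list[LaplacianMixtureModel] = field(default_factory=list)
    statuses: dict[int, str] = field(default_factory=dict)

    @property
    def ms(self) -> list[int]:
        return [mod.m for mod in self.models]


def fit_model_sequence(
    system, m_max: int, params: SearchParams | None = None
) -> ModelSequence:
    """Fit models for m = 2..m_max, stopping at the first degenerate m.

    The eigenbasis is computed once at m_max and truncated per m.
    """
    basis = compute_eigenbasis(system, m_max)
    seq = ModelSequence()
    for m in range(2, m_max + 1):
        result = solve(basis, params, m=m)
        seq.statuses[m] = result.status
        if not result.ok:
            break
        from .model import assemble

        seq.models.append(assemble(result, basis))
    return seq


def labeling_errors(labels: np.ndarray, truth: np.ndarray) -> int:
    """Minimum Hamming distance over component-to-cluster matchings.

    The optimal assignment of inferred component ids to true cluster ids
    is found on the confusion matrix, so the score is invariant to
    permutations of either labeling.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labelings differ in length")
    la, lb = np.unique(labels, return_inverse=True)[1], np.unique(truth, return_inverse=True)[1]
    k = max(la.max(), lb.max()) + 1
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (la, lb), 1)
    row, col = linear_sum_assignment(-confusion)
    return int(labels.size - confusion[row, col].sum())


def _match_components(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permutation of estimated columns best matching the truth columns."""
    m = truth.shape[1]
    cost = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            denom = np.linalg.norm(truth[:, j])
            cost[i, j] = np.linalg.norm(est[:, i] - truth[:, j]) / max(denom, 1e-300)
    if m <= 8:
        best, best_perm = np.inf, None
        for perm in permutations(range(m)):
            c = sum(cost[perm[j], j] for j in range(m))
            if c < best:
                best, best_perm = c, perm
        return np.asarray(best_perm)
    row, col = linear_sum_assignment(cost)
    return row[np.argsort(col)]


def relative_error(
    estimated: np.ndarray, truth: np.ndarray, *, stacked: bool = False
) -> float:
    """Mean per-component relative 2-norm error after optimal matching.

    With ``stacked=True``, the single relative norm of the stacked
    residual is returned instead of the per-component mean.
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("estimated and true component arrays differ in shape")
    perm = _match_components(estimated, truth)
    est = estimated[:, perm]
    if stacked:
        return float(np.linalg.norm(est - truth) / np.linalg.norm(truth))
    errs = [
        np.linalg.norm(est[:, k] - truth[:, k]) / np.linalg.norm(truth[:, k])
        for k in range(truth.shape[1])
    ]
    return float(np.mean(errs))


def beta_search(
    grid: DensityGrid,
    m: int,
    betas: list[float],
    params: SearchParams | None = None,
    truth: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """One-dimensional grid search over the inverse temperature beta.

    Fits an m-component model per beta; scores by relative unmixing
    error against ``truth`` when supplied, otherwise by model loss.
    Betas at which no nondegenerate solution exists are excluded from
    the argmin and flagged in the returned curve.
    """
    if not betas or any(b <= 0 for b in betas):
        raise ValueError("betas must be a nonempty list of positive reals")
    rows = []
    for beta in betas:
        system = smoluchowski_laplacian(grid, beta)
        basis = compute_eigenbasis(system, m)
        result = solve(basis, params, m=m)
        if not result.ok:
            rows.append({"beta": beta, "status": result.status, "loss": np.nan,
                         "relative_error": np.nan})
            continue
        row = {"beta": beta, "status": "ok", "loss": result.loss}
        if truth is not None:
            p = np.clip(result.p, 0.0, 1.0)
            dens, _ = component_densities(p, grid.values, grid.cell_volume)
            row["relative_error"] = relative_error(dens, truth)
        else:
            row["relative_error"] = np.nan
        rows.append(row)
    curve = pd.DataFrame(rows)
    ok = curve[curve["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("no beta produced a nondegenerate model")
    score = ok["relative_error"] if truth is not None else ok["loss"]
    best = float(ok.loc[score.idxmin(), "beta"])
    return best, curve


def silhouette_profile(
    model: LaplacianMixtureModel,
    features: np.ndarray,
    n_subsamples: int = 10,
    subsample_size: int = 2000,
    seed: int = 0,
) -> float:
    """Mean Euclidean silhouette of the hard labels over seeded subsamples.

    A subsample that hits fewer than two distinct labels is redrawn (a
    bounded number of times).  With ``subsample_size >= N`` the plain
    silhouette is returned without resampling variance.
    """
    features = np.asarray(features, dtype=float)
    labels = model.labels
    n = features.shape[0]
    if labels.shape[0] != n:
        raise ValueError("features and model labels differ in length")
    if subsample_size >= n:
        return float(silhouette_score(features, labels))
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_subsamples):
        for _attempt in range(20):
            idx = rng.choice(n, size=subsample_size, replace=False)
            if np.unique(labels[idx]).size >= 2:
                break
        else:
            raise RuntimeError("could not draw a subsample with 2+ labels")
        scores.append(silhouette_score(features[idx], labels[idx]))
    return float(np.mean(scores))


def select_model(sequence: ModelSequence, scores: list[float]) -> int:
    """Pick m by robust-fit residuals of score vs. optimal loss.

    An iteratively reweighted least-squares line (Tukey bisquare) is fit
    to (loss, score); the chosen model is the highest-dimensional one
    whose score sits above the line (positive residual).  If none does,
    the smallest m is returned with a warning.
    """
    if len(sequence.models) < 3 or len(scores) != len(sequence.models):
        raise ValueError("need scores for >= 3 models")
    losses = np.array([mod.loss for mod in sequence.models])
    scores_arr = np.asarray(scores, dtype=float)
    exog = sm.add_constant(losses)
    fit = sm.RLM(scores_arr, exog, M=sm.robust.norms.TukeyBiweight()).fit()
    resid = scores_arr - fit.predict(exog)
    positive = [mod.m for mod, r in zip(sequence.models, resid) if r > 0]
    if not positive:
        import warnings

        warnings.warn("no model has a positive robust-fit residual; "
                      "falling back to the smallest m")
        return sequence.models[0].m
    return max(positive)


def knn_grid_search(
    graph: WeightedGraph,
    k_min_range,
    k_nn_range,
    m: int = 5,
    params: SearchParams | None = None,
    eigen_m: int | None = None,
) -> pd.DataFrame:
    """Hard-cluster size distributions over a (k_min, k_NN) grid.

    For each cell the graph is re-sparsified, its largest component
    solved at dimension ``m``, and the sorted hard-assignment cluster
    sizes recorded (largest and second largest in their own columns, the
    diagnostic used to pick a sparsification plateau).  Degenerate cells
    are marked, not fatal.
    """
    rows = []
    for k_min in k_min_range:
        for k_nn in k_nn_range:
            config = SimilarityConfig(k_nn=int(k_nn), k_min=int(k_min))
            try:
                pre = adjacency_preprocess(graph, config)
                sub, _ = largest_connected_component(pre)
                basis = compute_eigenbasis(
                    build_laplacian(sub), eigen_m or m
                )
                result = solve(basis, params, m=m)
            except (ValueError, RuntimeError) as exc:
                rows.append({"k_min": k_min, "k_nn": k_nn, "status": f"error: {exc}"})
                continue
            if not result.ok:
                rows.append({"k_min": k_min, "k_nn": k_nn, "status": "degenerate"})
                continue
            labels = np.argmax(result.p, axis=1)
            sizes = np.sort(np.bincount(labels, minlength=m))[::-1]
            rows.append(
                {
                    "k_min": k_min,
                    "k_nn": k_nn,
                    "status": "ok",
                    "loss": result.loss,
                    "largest": int(sizes[0]),
                    "second_largest": int(sizes[1]) if m > 1 else 0,
                    "sizes": sizes.tolist(),
                }
            )
    return pd.DataFrame(rows)
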