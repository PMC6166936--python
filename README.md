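# lapmix — Laplacian mixture models

`lapmix` computes **soft spectral partitions**: it turns the first *m*
eigenvectors of a graph Laplacian into a globally optimized **partition of
unity** — per-item probabilities p_k(x) ≥ 0 with Σ_k p_k(x) = 1 — that
identifies overlapping clusters, communities, or mixture components.  It is
aimed at people analysing unlabeled network data (e.g. protein–protein
interactomes), high-dimensional feature profiles (e.g. single-cell
expression), or gridded density estimates, who want probabilistic
memberships and a global, non-hierarchical view rather than hard labels.

## The model

All three input types are reduced to a symmetric Laplacian Δ = D − A:

* **graphs** use the weighted adjacency directly;
* **feature tables** go through a k-nearest-neighbor similarity graph
  (Gaussian kernel of Euclidean distance, with `k_NN` sparsification and a
  `k_min` outlier guard);
* **densities on a regular grid** are discretized into a lattice
  drift-diffusion (Smoluchowski-type) rate matrix with nearest-neighbor
  rates q(i←j) = (f_i/f_j)^(β/2), symmetrized by diagonal conjugation so
  that its Perron vector is f^(β/2).

With φ_0, …, φ_{m−1} the eigenvectors of smallest eigenvalue and
ω_k = φ_k/φ_0, any candidate partition in the eigenspace is p̂ = Mω for an
m×m coefficient matrix M, subject to Mᵀe = e_1 and (Mω)(x) ≥ 0.  The model
minimizes the expected fuzziness

L(M) = 1 − Σ_k ⟨p̂_k²⟩ = 1 − tr MᵀM,

a **concave** quadratic over a polytope, whose optima sit at vertices
(NP-hard in general).  `lapmix` attacks it with a seeded multi-start
modified Frank–Wolfe search: each restart jumps between polytope vertices
returned by linear programs, and candidates in which some component wins no
item under argmax (degenerate solutions) are rejected with infinite loss.
On interpolating cluster graphs — complete blocks blended with the complete
graph by a separation parameter ε — the optimum is known in closed form
(the binary block indicator, L = 0), which the solver reproduces exactly.

## Worked example

```python
import numpy as np
import lapmix as lm

spec = lm.ClusterGraphSpec(K=3, sizes=(3, 4, 5), epsilon=0.5)
graph = lm.interpolating_cluster_graph(spec)
basis = lm.compute_eigenbasis(lm.build_laplacian(graph), m=3)
model = lm.fit_model(basis, params=lm.SearchParams(seed=1, n_restarts=8))
print(np.round(basis.eigenvalues, 6))
print(f"{model.loss:.2e}", lm.labeling_errors(model.labels, spec.block_labels))
```

prints

```
[0. 6. 6.]
-1.78e-15 0
```

the second eigenvalue N(1−ε) = 6 with multiplicity K−1 = 2, a loss at its
theoretical lower bound of zero, and zero labeling errors: the solver has
recovered the planted three-block structure exactly, as the closed-form
analysis says it must.  The scripts in `examples/` walk through each
capability — exact recovery, noisy community detection (large blocks stay
perfectly recovered under uniform edge noise), feature clustering with the
denoised unit-max normalization and silhouette model selection, and
nonparametric density unmixing with the β grid search (relative error
≈ 0.002 on a two-Gaussian test mixture).

A thin CLI mirrors the library:

```sh
lapmix synth-graph --sizes 10,50,200 --epsilon 0.5 --alpha 0.2 graph.mtx
lapmix fit-graph graph.mtx --m-min 2 --m-max 3 --seed 1 --out-dir out/
lapmix eval out/m3_p.tsv graph.truth.txt
```

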