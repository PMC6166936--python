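"""Readers and writers for the on-disk formats.

Graphs: Matrix Market coordinate files (1-based, symmetric or general)
or whitespace-delimited edge lists ``src dst weight`` (0-based by
default, switchable).  Feature tables: delimited text with a header row,
items as columns.  Densities: delimited text of values plus grid
shape/spacing in a JSON sidecar.  Models: a delimited probability table
plus JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .laplacians import DensityGrid, WeightedGraph
from .model import LaplacianMixtureModel

__all__ = [
    "read_graph",
    "write_graph",
    "read_features",
    "read_density",
    "write_density",
    "write_model",
    "read_model_table",
]


def read_graph(
    path: str | Path, dialect: str = "auto", one_based: bool = False
) -> WeightedGraph:
    """Read a weighted graph from Matrix Market or edge-list text.

    ``dialect`` is "mtx", "edgelist", or "auto" (by file suffix /
    header).  Edge lists are 0-based unless ``one_based=True``; an
    index-base mismatch (no vertex 0 but a vertex N) is detected
    heuristically and reported.
    """
    path = Path(path)
    if dialect == "auto":
        head = path.open().readline()
        dialect = "mtx" if (path.suffix == ".mtx" or head.startswith("%%MatrixMarket")) else "edgelist"
    if dialect == "mtx":
        mat = sp.csr_matrix(scipy.io.mmread(path))
        asym = abs(mat - mat.T).max()
        if asym > 1e-12 * max(abs(mat).max(), 1e-300):
            raise ValueError(
                f"{path}: general Matrix Market input is not symmetric "
                f"(max asymmetry {asym:.3e})"
            )
        return WeightedGraph(mat.shape[0], mat)
    if dialect != "edgelist":
        raise ValueError(f"unknown graph dialect {dialect!r}")
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 2:
        data = np.column_stack([data, np.ones(data.shape[0])])
    src, dst, w = data[:, 0].astype(int), data[:, 1].astype(int), data[:, 2]
    if one_based:
        src, dst = src - 1, dst - 1
    elif src.min() >= 1 and dst.min() >= 1:
        import warnings

        warnings.warn(
            f"{path}: no vertex index 0 found; if this edge list is "
            "1-based pass one_based=True"
        )
    n = int(max(src.max(), dst.max())) + 1
    mat = sp.coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
    mat = mat.maximum(mat.T)
    return WeightedGraph(n, mat)


def write_graph(graph: WeightedGraph, path: str | Path) -> None:
    """Write a graph as Matrix Market coordinate (symmetric) text."""
    scipy.io.mmwrite(str(path), sp.coo_matrix(graph.weights), symmetry="symmetric")


def read_features(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Delimited feature table with header row; items are columns."""
    table = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                        index_col=0)
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: feature table contains non-finite values")
    return table


def read_density(
    path: str | Path,
    shape: tuple[int, ...] | None = None,
    spacing: tuple[float, ...] | None = None,
) -> DensityGrid:
    """Density values from delimited text plus shape/spacing metadata.

    Metadata comes from the arguments or from a ``<path>.json`` sidecar
    with keys ``shape`` and ``spacing``.
    """
    path = Path(path)
    if shape is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"no grid shape given and no sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        spacing = tuple(meta.get("spacing") or ()) or None
    values = np.loadtxt(path).ravel()
    return DensityGrid(values=values, shape=tuple(shape), spacing=spacing)


def write_density(grid: DensityGrid, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, grid.values)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"shape": list(grid.shape), "spacing": list(grid.spacing)})
    )


def write_model(
    model: LaplacianMixtureModel, out_dir: str | Path, tag: str = "model",
    extra_meta: dict | None = None,
) -> Path:
    """Write the probability table (TSV) and JSON metadata; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {f"p_{k + 1}": model.p[:, k] for k in range(model.m)}
    table = pd.DataFrame({"item": np.arange(model.p.shape[0]), **cols,
                          "label": model.labels + 1})
    table.to_csv(out / f"{tag}_p.tsv", sep="\t", index=False, float_format="%.12g")
    meta = {
        "m": model.m,
        "loss": model.loss,
        "component_losses": model.component_losses.tolist(),
        "weights": model.weights.tolist(),
        "clip_magnitude": model.clip_magnitude,
        "report": {k: v for k, v in model.report.items() if k != "restarts"},
    }
    if extra_meta:
        meta.update(extra_meta)
    (out / f"{tag}_meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_model_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a probability table; returns (p, labels 0-based)."""
    table = pd.read_csv(path, sep="\t")
    pcols = [c for c in table.columns if c.startswith("p_")]
    return table[pcols].to_numpy(), table["label"].to_numpy() - 1
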