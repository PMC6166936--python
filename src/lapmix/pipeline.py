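"""End-to-end pipeline: input -> Laplacian -> eigenbasis -> models on disk."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as lio
from .eigenspace import compute_eigenbasis
from .laplacians import (
    SimilarityConfig,
    build_laplacian,
    largest_connected_component,
    similarity_graph,
    smoluchowski_laplacian,
)
from .model import assemble
from .optimizer import SearchParams, solve
from .preprocessing import denoised_unit_max, unit_median

log = logging.getLogger("lapmix")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable description of one analysis run.

    ``input_type`` is "graph", "features", or "density"; ``m_range`` is
    an inclusive (lo, hi) pair of component counts to fit.
    """

    input_path: str
    input_type: str
    out_dir: str
    m_range: tuple[int, int] = (2, 2)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    search: SearchParams = field(default_factory=SearchParams)
    beta: float = 1.0
    normalization: str = "unit_max"  # none | unit_max | unit_median
    extract_largest_component: bool = True
    graph_dialect: str = "auto"
    one_based: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["similarity"] = SimilarityConfig(**raw.get("similarity", {}))
        raw["search"] = SearchParams(**raw.get("search", {}))
        raw["m_range"] = tuple(raw["m_range"])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _build_system(config: RunConfig):
    if config.input_type == "graph":
        graph = lio.read_graph(
            config.input_path, config.graph_dialect, config.one_based
        )
        if config.extract_largest_component:
            graph, kept = largest_connected_component(graph)
            log.info("largest component: %d vertices kept", graph.n_vertices)
        return build_laplacian(graph), None
    if config.input_type == "features":
        table = lio.read_features(config.input_path)
        if config.normalization in ("unit_max", "unit_median"):
            table, report = denoised_unit_max(table)
            log.info("denoised unit-max removal report: %s", report)
            if config.normalization == "unit_median":
                table = unit_median(table)
        features = table.to_numpy().T  # items are columns on disk
        graph = similarity_graph(features, config.similarity)
        if config.extract_largest_component:
            graph, _ = largest_connected_component(graph)
        return build_laplacian(graph), features
    if config.input_type == "density":
        grid = lio.read_density(config.input_path)
        return smoluchowski_laplacian(grid, config.beta), None
    raise ValueError(f"unknown input_type {config.input_type!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns a per-m status summary.

    Model files, the solver report, and the config itself are written to
    ``config.out_dir``; the run is deterministic given the seed in
    ``config.search``.  Degeneracy at some m is recorded as a status and
    truncates the m sweep, as for any model sequence.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    t0 = time.time()
    system, _features = _build_system(config)
    log.info("system built (%d vertices) in %.2fs", system.n, time.time() - t0)

    lo, hi = config.m_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid m_range {config.m_range}")
    basis = compute_eigenbasis(system, max(hi, 2))
    log.info("eigenbasis (m=%d) in %.2fs", max(hi, 2), time.time() - t0)

    statuses: dict[int, str] = {}
    for m in range(lo, hi + 1):
        result = solve(basis, config.search, m=m)
        statuses[m] = result.status
        if not result.ok:
            log.info("m=%d: no nondegenerate solution; truncating sweep", m)
            break
        model = assemble(result, basis)
        lio.write_model(
            model, out, tag=f"m{m}",
            extra_meta={"seed": config.search.seed, "config_hash": config.config_hash},
        )
        log.info("m=%d: loss=%.6g", m, model.loss)
    (out / "statuses.json").write_text(json.dumps({str(k): v for k, v in statuses.items()}))
    return statuses
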