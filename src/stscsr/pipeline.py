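"""End-to-end orchestration: preprocess → spatial graph → solve → Leiden."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionData
from .preprocess import PreprocessConfig, run_preprocess
from .spatial_graph import SpatialGraph, build_knn_graph
from .optimizer import AffinityGraph, SolverConfig, TriFactorModel, solve
from .domains import (DomainLabels, affinity_to_graph, estimate_n_domains,
                      leiden_domains)

logger = logging.getLogger("stscsr")


@dataclass
class PipelineResult:
    labels: DomainLabels
    model: TriFactorModel
    affinity: AffinityGraph
    graph: SpatialGraph
    features: ExpressionData = field(repr=False, default=None)


def run_pipeline(data: ExpressionData,
                 n_domains: int | str = "auto",
                 pre_config: PreprocessConfig | None = None,
                 solver_config: SolverConfig | None = None,
                 K_neighbors: int = 5,
                 weight_mode: str = "inverse_expression_distance",
                 auto_candidates: list[int] | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Identify spatial domains in ``data`` (raw counts + coordinates).

    ``n_domains`` may be an integer (honored via Leiden resolution
    bisection) or ``"auto"`` (consensus-NMF stability over
    ``auto_candidates``, default 2..15). ``seed`` overrides the solver
    config seed for the whole run.
    """
    pre_config = pre_config or PreprocessConfig()
    solver_config = solver_config or SolverConfig()
    if seed is not None:
        solver_config.seed = seed
    rng_seed = solver_config.seed

    feats = run_preprocess(data, pre_config, seed=rng_seed)
    graph = build_knn_graph(data.coords, feats, K_neighbors, weight_mode)

    # the optimizer works in features × spots orientation
    X = feats.matrix.T
    model, affinity = solve(X, graph.adjacency, graph.laplacian_matrix,
                            solver_config)

    g = affinity_to_graph(affinity.Z)
    if n_domains == "auto":
        candidates = auto_candidates or list(range(2, 16))
        n_domains = estimate_n_domains(feats.matrix, candidates, seed=rng_seed)
        logger.info("run_pipeline: estimated %d domains", n_domains)
    labels = leiden_domains(g, n_domains=int(n_domains), seed=rng_seed,
                            barcodes=data.barcodes)
    return PipelineResult(labels, model, affinity, graph, feats)
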