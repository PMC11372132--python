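"""Spatial KNN network over spots: adjacency W and Laplacian L = D − W.

Neighbors are found on the spatial coordinates; edge weights default to the
inverse distance between the two spots' expression profiles, w_ij =
1/‖x_i − x_j‖, so that nearby spots with similar expression carry heavy
weights. Inverse spatial-distance and binary weights are also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionData

logger = logging.getLogger("stscsr")

WEIGHT_MODES = ("inverse_expression_distance", "inverse_spatial_distance", "binary")


@dataclass
class SpatialGraph:
    """Symmetric non-negative weighted adjacency with degree and Laplacian."""

    adjacency: np.ndarray
    K: int
    weight_mode: str
    degree: np.ndarray = field(init=False)
    laplacian_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.adjacency, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("adjacency must be square")
        if np.abs(W - W.T).max() > 1e-10:
            raise ValueError("adjacency must be symmetric")
        if (W < 0).any():
            raise ValueError("adjacency must be non-negative")
        if np.abs(np.diag(W)).max() > 0:
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = W
        self.degree = W.sum(axis=1)
        self.laplacian_matrix = np.diag(self.degree) - W

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]


def build_knn_graph(coords: np.ndarray, expr: ExpressionData | None, K: int,
                    weight_mode: str = "inverse_expression_distance",
                    normalize: bool = True) -> SpatialGraph:
    """Build the symmetrized K-nearest-neighbor graph on spatial coordinates.

    The edge set is the union-symmetrized KNN relation (edge if i ∈ KNN(j)
    or j ∈ KNN(i)). Edge weights are 1/distance between the profiles chosen
    by ``weight_mode`` (expression columns, spatial coordinates, or constant
    1); coincident profiles receive the maximum finite weight in the graph.
    With ``normalize`` the adjacency is scaled to maximum entry 1 so the
    spatial reconstruction term is on the same scale as the expression term.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if K <= 0:
        raise ValueError("K must be positive")
    if n < K + 1:
        raise ValueError(f"need at least K+1={K + 1} spots, got {n}")
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    if weight_mode == "inverse_expression_distance" and expr is None:
        raise ValueError("expression data required for inverse_expression_distance")

    if len(np.unique(coords, axis=0)) < n:
        logger.warning("duplicate spot coordinates; KNN ties broken by spot index")

    nn = NearestNeighbors(n_neighbors=K + 1).fit(coords)
    _, idx = nn.kneighbors(coords)

    profiles = expr.matrix if weight_mode == "inverse_expression_distance" else coords

    W = np.zeros((n, n))
    pending_zero: list[tuple[int, int]] = []
    for i in range(n):
        for j in idx[i]:
            if j == i:
                continue
            if weight_mode == "binary":
                W[i, j] = W[j, i] = 1.0
                continue
            d = float(np.linalg.norm(profiles[i] - profiles[j]))
            if d == 0.0:
                pending_zero.append((i, j))
            else:
                w = 1.0 / d
                W[i, j] = W[j, i] = w
    if pending_zero:
        wmax = W.max() if W.max() > 0 else 1.0
        for i, j in pending_zero:
            W[i, j] = W[j, i] = wmax
        logger.warning("%d coincident-profile edge(s) set to max weight",
                       len(pending_zero))
    if normalize and W.max() > 0:
        W = W / W.max()
    return SpatialGraph(W, K=K, weight_mode=weight_mode)


def laplacian(graph: SpatialGraph | np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D − W; satisfies fᵀLf = ½ Σ w_ij (f_i − f_j)² ≥ 0."""
    if isinstance(graph, SpatialGraph):
        return graph.laplacian_matrix.copy()
    W = np.asarray(graph, dtype=float)
    if np.abs(W - W.T).max() > 1e-10:
        raise ValueError("adjacency must be symmetric")
    return np.diag(W.sum(axis=1)) - W
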