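"""From learned affinity to spatial-domain labels.

The affinity matrix Z becomes a weighted undirected graph (positive
entries only), Leiden community detection partitions it (with a
resolution bisection when a target domain count is requested), and the
number of domains can be chosen by consensus-NMF stability when unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import NMF

logger = logging.getLogger("stscsr")


@dataclass
class DomainLabels:
    """Integer domain assignment per spot (labels contiguous from 0)."""

    assignment: np.ndarray
    barcodes: list[str] | None = None
    n_domains: int = 0
    resolution_used: float = float("nan")
    ground_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        uniq = np.unique(self.assignment)
        if uniq.size and (uniq.min() != 0 or not np.array_equal(uniq, np.arange(uniq.size))):
            # relabel to contiguous 0-based ids, preserving order of appearance
            _, self.assignment = np.unique(self.assignment, return_inverse=True)
            uniq = np.unique(self.assignment)
        self.n_domains = int(uniq.size)
        if self.barcodes is None:
            self.barcodes = [f"spot{i}" for i in range(self.assignment.size)]
        if len(self.barcodes) != self.assignment.size:
            raise ValueError("barcodes length does not match assignment")
        if self.ground_truth is not None:
            self.ground_truth = np.asarray(self.ground_truth)
            if self.ground_truth.size != self.assignment.size:
                raise ValueError("ground_truth length does not match assignment")


def affinity_to_graph(Z: np.ndarray, threshold: float = 1e-8) -> ig.Graph:
    """Weighted undirected graph from a symmetric zero-diagonal affinity.

    Edges are pairs with max(Z_ij, 0) > threshold; negative entries carry no
    edge interpretation and are dropped (counted in the log).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if Z.shape != (n, n) or np.abs(Z - Z.T).max() > 1e-8:
        raise ValueError("Z must be square and symmetric")
    if np.abs(np.diag(Z)).max() > 1e-12:
        raise ValueError("Z must have zero diagonal")
    n_negative = int(np.count_nonzero(np.triu(Z, 1) < 0))
    if n_negative:
        logger.info("affinity_to_graph: dropped %d negative entries", n_negative)
    iu, ju = np.triu_indices(n, 1)
    w = Z[iu, ju]
    keep = w > threshold
    if not keep.any():
        raise ValueError("affinity matrix is entirely non-positive: empty graph")
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = w[keep].tolist()
    return g


def _leiden_once(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def leiden_domains(graph: ig.Graph, n_domains: int | None = None,
                   resolution: float | None = None, seed: int = 0,
                   barcodes: list[str] | None = None,
                   max_probes: int = 50) -> DomainLabels:
    """Leiden clustering of the affinity graph.

    With an explicit ``resolution`` a single run is performed. With a target
    ``n_domains`` the resolution is bisected in [1e-3, 10] (at most
    ``max_probes`` runs) until the partition has exactly that many
    communities; if unreachable, the nearest achieved count is returned with
    a warning. Deterministic given ``seed``.
    """
    if (n_domains is None) == (resolution is None):
        raise ValueError("specify exactly one of n_domains or resolution")
    if resolution is not None:
        memb = _leiden_once(graph, resolution, seed)
        return DomainLabels(memb, barcodes=barcodes, resolution_used=resolution)
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")

    lo, hi = 1e-3, 10.0
    best_memb, best_res, best_gap = None, None, np.inf
    for _ in range(max_probes):
        mid = np.sqrt(lo * hi)  # geometric bisection suits the log-scaled range
        memb = _leiden_once(graph, mid, seed)
        k = int(np.unique(memb).size)
        gap = abs(k - n_domains)
        if gap < best_gap:
            best_memb, best_res, best_gap = memb, mid, gap
        if k == n_domains:
            break
        if k < n_domains:
            lo = mid
        else:
            hi = mid
    if best_gap > 0:
        logger.warning("leiden_domains: target %d communities unreachable, "
                       "returning nearest achieved (%d off)", n_domains, best_gap)
    return DomainLabels(best_memb, barcodes=barcodes, resolution_used=best_res)


def consensus_stability(X: np.ndarray, k: int, n_repeats: int,
                        rep_seeds: list[int]) -> float:
    """Dispersion of the consensus co-clustering matrix over repeated NMFs.

    Each repeat fits a rank-k NMF from a seeded random init and assigns each
    row of X to its argmax component; the consensus matrix averages the
    co-assignment indicators. Dispersion 4·mean((c−½)²) is 1 for perfectly
    reproducible clusterings and tends to 0 for coin-flip consensus.
    """
    n = X.shape[0]
    consensus = np.zeros((n, n))
    import warnings as _warnings
    for r in range(n_repeats):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            nmf = NMF(n_components=k, init="random", random_state=rep_seeds[r],
                      max_iter=200, tol=1e-4)
            scores = nmf.fit_transform(X)
        assign = scores.argmax(axis=1)
        consensus += (assign[:, None] == assign[None, :])
    consensus /= n_repeats
    return float(4.0 * np.mean((consensus - 0.5) ** 2))


def estimate_n_domains(X: np.ndarray, k_candidates: list[int],
                       n_repeats: int = 10, seed: int = 0,
                       rep_seeds: list[int] | None = None) -> int:
    """Pick the domain count whose repeated-NMF clustering is most stable.

    Returns the candidate with the highest consensus dispersion; ties go to
    the smallest candidate. Rank-1 (degenerate) inputs return 2 with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    if any(k < 2 for k in k_candidates):
        raise ValueError("all candidates must be >= 2")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if np.linalg.matrix_rank(X) <= 1:
        logger.warning("estimate_n_domains: input has rank <= 1, returning 2")
        return 2
    if rep_seeds is None:
        rng = np.random.default_rng(seed)
        rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_repeats)]
    scores = {k: consensus_stability(X, k, n_repeats, rep_seeds)
              for k in k_candidates}
    best = max(sorted(k_candidates), key=lambda k: (scores[k], -k))
    logger.info("estimate_n_domains: stabilities %s -> %d",
                {k: round(v, 4) for k, v in scores.items()}, best)
    return int(best)


def meta_similarity(C: np.ndarray, F_e: np.ndarray,
                    labels: np.ndarray) -> np.ndarray:
    """Domain–domain similarity induced by the shared core C.

    Each domain d is summarized by the mean coefficient vector u_d of its
    spots (columns of Fₑ), normalized to unit length; the similarity of
    domains a and b is the bilinear form u_aᵀ C u_b. Returns a d × d
    symmetric matrix.
    """
    labels = np.asarray(labels)
    doms = np.unique(labels)
    U = np.stack([F_e[:, labels == d].mean(axis=1) for d in doms], axis=1)
    norms = np.linalg.norm(U, axis=0)
    norms[norms == 0] = 1.0
    U = U / norms
    S = U.T @ C @ U
    return 0.5 * (S + S.T)


def umap_embed(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding for visualization only (requires the viz extra)."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 10:
        raise ValueError("need at least 10 spots to embed")
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(features), dtype=float)
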