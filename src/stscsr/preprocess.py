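"""Pre-processing chain: gene filtering, library-size normalization,
highly-variable-gene selection, spatial neighbor augmentation, PCA.

The pipeline order is fixed: filter → normalize → HVG → augment → PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionData

logger = logging.getLogger("stscsr")


@dataclass
class PreprocessConfig:
    """Knobs of the pre-processing chain.

    ``min_spots_per_gene=10`` and ``n_hvg=3000`` are the standard Visium
    defaults; ``target_sum="median"`` scales each spot to the median raw
    library size; ``augment_lambda`` weights the concatenated
    mean-of-neighbors block; ``n_pcs`` is the PCA dimension.

    ``target_scale`` fixes the mean per-spot squared ℓ2 norm of the matrix
    handed to the factorization. The default solver settings (α=2, β=1,
    γ=50) operate at the scale of a full-size panel (≈3000 highly variable
    genes, doubled by augmentation, log-normalized → squared spot norms of
    a couple of thousand); pinning the scale keeps those settings in their
    working regime regardless of panel size. Set to None to skip.
    """

    min_spots_per_gene: int = 10
    n_hvg: int = 3000
    target_sum: float | str = "median"
    log1p: bool = True
    augment_lambda: float = 0.2
    augment_K: int = 6
    n_pcs: int = 30
    use_pca_shifted: bool = False
    target_scale: float | None = 2000.0


def filter_genes(data: ExpressionData, min_spots_per_gene: int) -> ExpressionData:
    """Drop genes expressed (count > 0) in fewer than ``min_spots_per_gene`` spots."""
    if data.layer_tag != "raw":
        raise ValueError("filter_genes expects raw counts")
    n_expressing = (data.matrix > 0).sum(axis=0)
    keep = n_expressing >= min_spots_per_gene
    if not keep.any():
        raise ValueError("all genes removed by filter_genes")
    kept_names = [g for g, k in zip(data.gene_names, keep) if k]
    return data.with_matrix(data.matrix[:, keep], "raw", kept_names)


def normalize_library(data: ExpressionData, target_sum: float | str = "median",
                      log1p: bool = True) -> ExpressionData:
    """Scale each spot to a common library size, optionally log(1+x)."""
    sums = data.matrix.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"spot(s) with zero total count: {[data.barcodes[i] for i in zero[:5]]}"
        )
    target = float(np.median(sums)) if target_sum == "median" else float(target_sum)
    if target <= 0:
        raise ValueError("target_sum must be positive")
    out = data.matrix * (target / sums)[:, None]
    if log1p:
        out = np.log1p(out)
    return data.with_matrix(out, "normalized")


def gene_dispersion(matrix: np.ndarray) -> np.ndarray:
    """Per-gene dispersion var/mean of the (normalized) values; 0 where mean is 0."""
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def select_hvg(data: ExpressionData, n_hvg: int) -> ExpressionData:
    """Keep the ``n_hvg`` most dispersed genes (ties → lexicographic name order).

    Column order of the surviving genes is preserved.
    """
    if data.layer_tag != "normalized":
        raise ValueError("select_hvg expects the normalized layer")
    if n_hvg > data.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {data.n_genes}")
    disp = gene_dispersion(data.matrix)
    order = sorted(range(data.n_genes),
                   key=lambda j: (-disp[j], data.gene_names[j]))
    keep = np.zeros(data.n_genes, dtype=bool)
    keep[order[:n_hvg]] = True
    kept_names = [g for g, k in zip(data.gene_names, keep) if k]
    return data.with_matrix(data.matrix[:, keep], "normalized", kept_names)


def spatial_knn_indices(coords: np.ndarray, K: int) -> np.ndarray:
    """Indices of the K nearest spatial neighbors of each spot (self excluded)."""
    nn = NearestNeighbors(n_neighbors=K + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    # first neighbor is the spot itself (distance 0); keep the next K
    return idx[:, 1:K + 1]


def neighbor_augment(data: ExpressionData, coords: np.ndarray,
                     augment_lambda: float, K: int) -> ExpressionData:
    """Concatenate a weighted mean-of-K-spatial-neighbors block to each profile.

    Each spot's profile becomes ``[sqrt(1-λ)·own, sqrt(λ)·neighbor_mean]``;
    the feature dimension doubles. λ=0 keeps the own profile untouched with a
    zero neighbor block. This smoothing emulates neighborhood-aware feature
    augmentation for lattice data.
    """
    if data.layer_tag != "normalized":
        raise ValueError("neighbor_augment expects the normalized layer")
    if not 0.0 <= augment_lambda < 1.0:
        raise ValueError("augment_lambda must be in [0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= data.n_spots:
        raise ValueError(f"K={K} must be smaller than the spot count {data.n_spots}")
    idx = spatial_knn_indices(np.asarray(coords, dtype=float), K)
    neighbor_mean = data.matrix[idx].mean(axis=1)
    own = np.sqrt(1.0 - augment_lambda) * data.matrix
    nbr = np.sqrt(augment_lambda) * neighbor_mean
    names = [f"{g}|own" for g in data.gene_names] + \
            [f"{g}|nbr" for g in data.gene_names]
    return data.with_matrix(np.hstack([own, nbr]), "augmented", names)


def reduce_pca(data: ExpressionData, n_pcs: int, seed: int = 0) -> ExpressionData:
    """Project to ``n_pcs`` principal components (deterministic sign convention).

    Features are centered; each component is flipped so its largest-magnitude
    loading is positive, making the result independent of solver sign choices.
    """
    if data.layer_tag not in ("normalized", "augmented"):
        raise ValueError("reduce_pca expects a normalized or augmented layer")
    bound = min(data.n_spots - 1, data.n_genes)
    if not 2 <= n_pcs <= bound:
        raise ValueError(f"n_pcs={n_pcs} outside [2, {bound}]")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(data.matrix)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(n_pcs)]
    return data.with_matrix(scores, "reduced", names)


def run_preprocess(data: ExpressionData, config: PreprocessConfig,
                   seed: int = 0) -> ExpressionData:
    """Run the full chain and return the matrix to feed the factorization.

    By default the result is the non-negative augmented matrix (log-normalized
    values are ≥ 0, and the augmentation preserves sign). With
    ``use_pca_shifted`` the PCA scores are shifted by their global minimum to
    restore non-negativity before factorization.
    """
    out = filter_genes(data, config.min_spots_per_gene)
    out = normalize_library(out, config.target_sum, config.log1p)
    n_hvg = min(config.n_hvg, out.n_genes)
    out = select_hvg(out, n_hvg)
    out = neighbor_augment(out, data.coords, config.augment_lambda, config.augment_K)
    if config.use_pca_shifted:
        out = reduce_pca(out, config.n_pcs, seed)
        shifted = out.matrix - out.matrix.min()
        out = out.with_matrix(shifted, "reduced")
    if config.target_scale is not None:
        mean_sq = float((out.matrix ** 2).sum(axis=1).mean())
        if mean_sq > 0:
            out = out.with_matrix(
                out.matrix * np.sqrt(config.target_scale / mean_sq),
                out.layer_tag)
    return out
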