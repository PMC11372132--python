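"""Readers and writers for the file formats the tool touches.

The internal orientation is always **spots × genes** (10x MTX ships
genes × barcodes and is transposed on load); spot order is always the
coordinate-table order and no operation silently reorders it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("stscsr")

LAYER_TAGS = ("raw", "normalized", "augmented", "reduced")


class FormatError(ValueError):
    """Input file violates its declared format."""


class AlignmentError(ValueError):
    """Barcode / spot-id sets of two inputs do not match."""


@dataclass
class ExpressionData:
    """A spots × genes expression matrix with coordinates and identifiers.

    Parameters
    ----------
    matrix
        Dense ``(n_spots, n_genes)`` array. Raw counts are non-negative.
    gene_names, barcodes
        Unique identifiers for columns and rows respectively.
    coords
        ``(n_spots, 2)`` spatial coordinates (array row/col or pixel x/y;
        treated as Euclidean plane in whatever units the file provides).
    layer_tag
        Provenance of ``matrix``: one of ``raw``, ``normalized``,
        ``augmented``, ``reduced``.
    """

    matrix: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    coords: np.ndarray
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = list(self.gene_names)
        self.barcodes = list(self.barcodes)
        self.validate()

    def validate(self) -> None:
        n, g = self.matrix.shape
        if len(self.barcodes) != n or self.coords.shape != (n, 2):
            raise FormatError(
                f"row mismatch: matrix has {n} spots, "
                f"{len(self.barcodes)} barcodes, coords shape {self.coords.shape}"
            )
        if len(self.gene_names) != g:
            raise FormatError(
                f"column mismatch: matrix has {g} genes, "
                f"{len(self.gene_names)} gene names"
            )
        if len(set(self.barcodes)) != n:
            raise FormatError("barcodes are not unique")
        if len(set(self.gene_names)) != g:
            raise FormatError("gene names are not unique")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if not np.isfinite(self.matrix).all() or not np.isfinite(self.coords).all():
            raise FormatError("non-finite values in matrix or coords")
        if self.layer_tag == "raw" and (self.matrix < 0).any():
            raise FormatError("raw layer contains negative entries")

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(self, matrix: np.ndarray, layer_tag: str,
                    gene_names: Sequence[str] | None = None) -> "ExpressionData":
        """Copy with a new matrix/layer (and optionally new feature names)."""
        return replace(
            self,
            matrix=np.asarray(matrix, dtype=float),
            layer_tag=layer_tag,
            gene_names=list(gene_names) if gene_names is not None else list(self.gene_names),
        )


# ---------------------------------------------------------------------------
# Visium-style triplet input
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                     "pxl_row_in_fullres", "pxl_col_in_fullres"]


def _read_positions(positions_path: str | Path) -> pd.DataFrame:
    """Read a tissue-positions table, headered or headerless dialect.

    Detection: if the first line mentions ``barcode`` it is headered;
    otherwise the six canonical columns are assumed in order.
    """
    with open(positions_path) as fh:
        first = fh.readline()
    if "barcode" in first.lower():
        pos = pd.read_csv(positions_path)
        pos.columns = [c.strip().lower() for c in pos.columns]
        missing = [c for c in _POSITION_COLUMNS if c not in pos.columns]
        if missing:
            raise FormatError(f"positions file missing columns {missing}")
        pos = pos[_POSITION_COLUMNS]
    else:
        pos = pd.read_csv(positions_path, header=None)
        if pos.shape[1] < 6:
            raise FormatError(
                f"headerless positions file has {pos.shape[1]} columns, expected 6"
            )
        pos = pos.iloc[:, :6]
        pos.columns = _POSITION_COLUMNS
    pos["barcode"] = pos["barcode"].astype(str)
    return pos


def read_visium(matrix_path: str | Path, features_path: str | Path,
                barcodes_path: str | Path, positions_path: str | Path) -> ExpressionData:
    """Read a 10x-style MTX + features/barcodes TSV + tissue-positions CSV.

    The MTX is genes × barcodes and is transposed to spots × genes. Spots
    with ``in_tissue == 0`` are dropped; the returned spot order is the
    positions-table order restricted to in-tissue barcodes.
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = scipy.sparse.csr_matrix(mat) if scipy.sparse.issparse(mat) else np.asarray(mat)
    n_genes_mtx, n_bc_mtx = mat.shape

    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    # 10x features.tsv: id, name, type — use the id column (unique)
    gene_names = features.iloc[:, 0].astype(str).tolist()
    barcode_names = barcodes.iloc[:, 0].astype(str).tolist()

    if len(gene_names) != n_genes_mtx:
        raise FormatError(
            f"MTX declares {n_genes_mtx} genes but features file has "
            f"{len(gene_names)} lines"
        )
    if len(barcode_names) != n_bc_mtx:
        raise FormatError(
            f"MTX declares {n_bc_mtx} barcodes but barcodes file has "
            f"{len(barcode_names)} lines"
        )

    pos = _read_positions(positions_path)
    pos_barcodes = set(pos["barcode"])
    missing = [b for b in barcode_names if b not in pos_barcodes]
    if missing:
        raise AlignmentError(
            f"barcode(s) present in matrix but absent from positions: {missing[:5]}"
        )

    in_tissue = pos[pos["in_tissue"].astype(int) == 1]
    keep = in_tissue[in_tissue["barcode"].isin(set(barcode_names))]
    col_of = {b: j for j, b in enumerate(barcode_names)}
    idx = [col_of[b] for b in keep["barcode"]]

    dense = np.asarray(mat.T[idx].todense() if scipy.sparse.issparse(mat)
                       else mat.T[idx], dtype=float)
    coords = keep[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(dtype=float)
    logger.info("read_visium: %d/%d spots in tissue, %d genes",
                len(idx), n_bc_mtx, n_genes_mtx)
    return ExpressionData(dense, gene_names, keep["barcode"].tolist(), coords, "raw")


# ---------------------------------------------------------------------------
# Dense CSV pair
# ---------------------------------------------------------------------------

def read_csv_pair(expr_csv: str | Path, coords_csv: str | Path,
                  layer_tag: str = "raw") -> ExpressionData:
    """Read a dense spots × genes CSV plus a spot-id → (x, y) coordinate CSV.

    Rows of the result follow the coordinate-table order.
    """
    expr = pd.read_csv(expr_csv, index_col=0)
    coords = pd.read_csv(coords_csv, index_col=0)
    expr.index = expr.index.astype(str)
    coords.index = coords.index.astype(str)
    if coords.shape[1] < 2:
        raise FormatError("coords CSV needs two numeric columns")

    expr_ids, coord_ids = set(expr.index), set(coords.index)
    if expr_ids != coord_ids:
        only_expr = sorted(expr_ids - coord_ids)
        only_coords = sorted(coord_ids - expr_ids)
        raise AlignmentError(
            f"spot-id sets differ: only in expression {only_expr[:5]}, "
            f"only in coords {only_coords[:5]}"
        )
    expr = expr.loc[coords.index]
    return ExpressionData(
        expr.to_numpy(dtype=float),
        [str(g) for g in expr.columns],
        list(coords.index),
        coords.iloc[:, :2].to_numpy(dtype=float),
        layer_tag,
    )


def write_csv_pair(data: ExpressionData, expr_csv: str | Path,
                   coords_csv: str | Path) -> None:
    """Write the canonical dense CSV pair; round-trips bit-exactly via repr."""
    pd.DataFrame(data.matrix, index=data.barcodes, columns=data.gene_names) \
        .to_csv(expr_csv, float_format="%.17g")
    pd.DataFrame(data.coords, index=data.barcodes, columns=["x", "y"]) \
        .to_csv(coords_csv, float_format="%.17g")


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def write_labels(labels, path: str | Path) -> None:
    """Write domain assignments as a barcode,domain CSV.

    If ground-truth labels are attached they are written as a third column.
    """
    from .domains import DomainLabels  # local import, avoids cycle at import time

    if not isinstance(labels, DomainLabels):
        raise TypeError("labels must be a DomainLabels")
    df = pd.DataFrame({"barcode": labels.barcodes,
                       "domain": labels.assignment})
    if labels.ground_truth is not None:
        df["ground_truth"] = labels.ground_truth
    df.to_csv(path, index=False)


def read_labels(path: str | Path):
    """Read a labels CSV written by :func:`write_labels`."""
    from .domains import DomainLabels

    df = pd.read_csv(path)
    truth = df["ground_truth"].to_numpy() if "ground_truth" in df.columns else None
    return DomainLabels(
        assignment=df["domain"].to_numpy(dtype=int),
        barcodes=df["barcode"].astype(str).tolist(),
        ground_truth=truth,
    )


def to_anndata(data: ExpressionData):
    """Optional AnnData adapter (requires the ``anndata`` extra)."""
    import anndata as ad

    adata = ad.AnnData(X=data.matrix.copy())
    adata.obs_names = data.barcodes
    adata.var_names = data.gene_names
    adata.obsm["spatial"] = data.coords.copy()
    adata.uns["layer_tag"] = data.layer_tag
    return adata
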