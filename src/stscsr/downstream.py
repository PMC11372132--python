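"""Marker-gene discovery per domain and external clustering metrics.

A gene is called a domain marker when it is expressed (value > 0) in at
least 80 % of the domain's spots, its log2 fold change of mean expression
against all other spots is ≥ 1.5, and its one-vs-rest Wilcoxon rank-sum
FDR (Benjamini–Hochberg within the domain) is ≤ 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from statsmodels.stats.multitest import multipletests

from .io import ExpressionData
from .domains import DomainLabels

logger = logging.getLogger("stscsr")

FRACTION_MIN = 0.8
LOG2FC_MIN = 1.5
FDR_MAX = 0.05
_PSEUDO = 1e-9

MARKER_COLUMNS = ["gene", "domain", "fraction_expressing",
                  "log_fold_change", "p_value", "fdr", "passes"]


def rank_markers(data: ExpressionData, labels: DomainLabels,
                 fraction_min: float = FRACTION_MIN,
                 log2fc_min: float = LOG2FC_MIN,
                 fdr_max: float = FDR_MAX,
                 data_is_log1p: bool = True) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per gene per domain.

    Returns a table with fraction expressing, log2 fold change of means
    (pseudocount 1e-9), rank-sum p-value, per-domain BH FDR, and the
    ``passes`` flag combining the three thresholds. Domains with fewer than
    3 spots are excluded with a warning.

    With ``data_is_log1p`` (the default — the pipeline's normalization ends
    in log(1+x)) the group means are mapped back through expm1 before the
    fold change, so the reported value is a fold change of expression, not
    of log-expression.
    """
    if data.layer_tag != "normalized":
        raise ValueError("rank_markers expects normalized expression")
    assign = labels.assignment
    if assign.size != data.n_spots:
        raise ValueError("labels length does not match spot count")
    domains = np.unique(assign)
    if domains.size < 2:
        raise ValueError("need at least 2 domains")

    X = data.matrix
    rows = []
    for d in domains:
        mask = assign == d
        if mask.sum() < 3:
            logger.warning("rank_markers: domain %d has <3 spots, excluded", d)
            continue
        inside, outside = X[mask], X[~mask]
        frac = (inside > 0).mean(axis=0)
        mean_in, mean_out = inside.mean(axis=0), outside.mean(axis=0)
        if data_is_log1p:
            mean_in, mean_out = np.expm1(mean_in), np.expm1(mean_out)
        lfc = np.log2((mean_in + _PSEUDO) / (mean_out + _PSEUDO))
        res = mannwhitneyu(inside, outside, axis=0, alternative="two-sided",
                           method="auto")
        pvals = np.atleast_1d(res.pvalue)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        passes = (frac >= fraction_min) & (lfc >= log2fc_min) & (fdr <= fdr_max)
        for j, gene in enumerate(data.gene_names):
            rows.append((gene, int(d), float(frac[j]), float(lfc[j]),
                         float(pvals[j]), float(fdr[j]), bool(passes[j])))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (chance-corrected pair-counting agreement)."""
    a, b = _as_label_arrays(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = _as_label_arrays(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def _as_label_arrays(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = labels_a.assignment if isinstance(labels_a, DomainLabels) else np.asarray(labels_a)
    b = labels_b.assignment if isinstance(labels_b, DomainLabels) else np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError(f"label lengths differ: {a.size} vs {b.size}")
    return a, b
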