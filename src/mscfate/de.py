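"""Wilcoxon rank-sum differential expression with the study's stated gate.

A gene passes when |log2 fold change| > 1 and the Benjamini-Hochberg
adjusted two-sided rank-sum p-value is below 1e-5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_de", "LFC_THRESHOLD", "ADJ_P_THRESHOLD"]

LFC_THRESHOLD = 1.0
ADJ_P_THRESHOLD = 1e-5
_EXACT_MAX = 8  # use the exact rank-sum null when both groups are this small

_LN2 = float(np.log(2.0))


def rank_sum_de(norm, gene_ids, cells_a, cells_b) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two disjoint cell groups.

    ``norm`` is cells x genes natural-log intensities.  The log2 fold
    change is the difference of group means of log2 intensities (A - B).
    The exact null is used when both groups have at most 8 cells and the
    gene has no ties across groups; otherwise the tie-corrected normal
    approximation.  Constant genes get p = 1 and lfc = 0 by definition.
    """
    norm = np.asarray(norm, dtype=float)
    a = np.asarray(cells_a)
    b = np.asarray(cells_b)
    if a.dtype == bool:
        a = np.flatnonzero(a)
    if b.dtype == bool:
        b = np.flatnonzero(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 cells")
    if np.intersect1d(a, b).size:
        raise ValueError("cell groups overlap")

    A, B = norm[a], norm[b]
    lfc = (A.mean(axis=0) - B.mean(axis=0)) / _LN2
    n_genes = norm.shape[1]
    constant = np.array([np.ptp(np.concatenate([A[:, g], B[:, g]])) == 0 for g in range(n_genes)])

    pvals = np.ones(n_genes)
    small = max(len(a), len(b)) <= _EXACT_MAX
    if small:
        for g in np.flatnonzero(~constant):
            pooled = np.concatenate([A[:, g], B[:, g]])
            method = "exact" if np.unique(pooled).size == pooled.size else "asymptotic"
            pvals[g] = stats.mannwhitneyu(
                A[:, g], B[:, g], alternative="two-sided", method=method
            ).pvalue
    else:
        idx = np.flatnonzero(~constant)
        if idx.size:
            res = stats.mannwhitneyu(
                A[:, idx], B[:, idx], alternative="two-sided", method="asymptotic", axis=0
            )
            pvals[idx] = np.minimum(res.pvalue, 1.0)
    lfc = np.where(constant, 0.0, lfc)

    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    padj = np.maximum(padj, pvals)  # BH never reports below the raw p
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "lfc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "pass": (np.abs(lfc) > LFC_THRESHOLD) & (padj < ADJ_P_THRESHOLD),
        }
    )
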