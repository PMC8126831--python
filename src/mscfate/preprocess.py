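"""Normalization, highly-variable-gene selection, and PCA embedding.

All estimators follow the scikit-learn contract (``fit`` / ``transform``,
parameters in ``__init__``, fitted attributes with a trailing underscore)
and operate on cells x genes arrays.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LogNormalizer",
    "HighlyVariableGenes",
    "PCAEmbedding",
    "normalize_log",
    "select_hvg",
    "pca_embed",
]


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Library-size log normalization: ``log(1 + count * scale / cell_total)``.

    Natural log; ``scale`` is the counts-per-cell equivalent (default
    10,000).  A zero count maps to exactly 0, so sparsity is preserved.
    Cells with zero total count are rejected unless ``drop_empty`` is set,
    in which case they are dropped and recorded in ``dropped_cells_``.

    Parameters
    ----------
    scale : float
        Target total count per cell after rescaling; must be positive.
    drop_empty : bool
        Drop zero-total cells instead of raising.
    """

    def __init__(self, scale: float = 1e4, drop_empty: bool = False):
        self.scale = scale
        self.drop_empty = drop_empty

    def fit(self, X, y=None):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        X = _as_dense(X)
        totals = X.sum(axis=1)
        empty = np.flatnonzero(totals == 0)
        self.dropped_cells_ = empty
        if empty.size:
            if not self.drop_empty:
                raise ValueError(
                    f"{empty.size} cell(s) with zero total count at rows {empty.tolist()[:20]}"
                )
            keep = totals > 0
            X, totals = X[keep], totals[keep]
        return np.log1p(X * (self.scale / totals[:, None]))


class HighlyVariableGenes(BaseEstimator, TransformerMixin):
    """Select the genes with the highest mean-binned dispersion z-score.

    Dispersion is variance/mean of the normalized intensities.  Genes are
    grouped into ``n_bins`` equal-occupancy bins by mean expression and the
    dispersion is z-scored within each bin, which removes the mean-dispersion
    trend before ranking.  Zero-variance genes are never selected while any
    positive-variance gene remains; ties are broken lexicographically by
    gene id (or by index when no ids are given), so the selection is
    deterministic and invariant to gene order.
    """

    def __init__(self, n_top: int = 1000, n_bins: int = 20):
        self.n_top = n_top
        self.n_bins = n_bins

    def fit(self, X, y=None, gene_ids=None):
        if self.n_top <= 0:
            raise ValueError("n_top must be positive")
        X = _as_dense(X)
        n_genes = X.shape[1]
        if self.n_top > n_genes:
            raise ValueError(f"n_top={self.n_top} exceeds {n_genes} genes")
        if gene_ids is None:
            gene_ids = [f"{i:06d}" for i in range(n_genes)]
        gene_ids = np.asarray(gene_ids, dtype=object)

        means = X.mean(axis=0)
        var = X.var(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            disp = np.where(means > 0, var / means, 0.0)

        # equal-occupancy mean bins via rank quantiles; bin members are
        # processed in canonical (mean, gene_id) order so the statistics are
        # bit-identical under any permutation of the input genes
        order = np.lexsort((gene_ids, means))
        bin_of_rank = np.minimum(
            (np.arange(n_genes) * self.n_bins) // n_genes, self.n_bins - 1
        )
        z = np.zeros(n_genes)
        for b in range(self.n_bins):
            members = order[bin_of_rank == b]
            if members.size == 0:
                continue
            vals = disp[members]
            mu, sd = vals.mean(), vals.std()
            z[members] = (vals - mu) / sd if sd > 0 else 0.0
        z = np.where(var > 0, z, -np.inf)

        # sort by (-z, gene_id): highest score first, lexicographic
        # tie-break; the key is quantized so float jitter in the last bits
        # (memory-layout dependent) cannot mask genuine ties
        rank = np.lexsort((gene_ids, -np.round(z, 9)))
        self.dispersion_z_ = z
        self.support_ = np.sort(rank[: self.n_top])
        self.selected_ids_ = gene_ids[self.support_].tolist()
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _as_dense(X)
        return X[:, self.support_]


class PCAEmbedding(BaseEstimator, TransformerMixin):
    """Gene-centered PCA of the (HVG-restricted) normalized intensities.

    Thin wrapper over :class:`sklearn.decomposition.PCA` with full SVD, so
    scores are deterministic up to the fixed sign convention (largest
    absolute loading positive).  With ``unit_variance`` each gene is scaled
    to unit variance first (values clipped at ``clip`` standard deviations,
    the usual guard against a handful of extreme cells), so every selected
    gene contributes comparably.  Fitted attributes: ``components_``,
    ``explained_variance_ratio_`` (non-increasing fractions in [0, 1]).
    """

    def __init__(self, n_comps: int = 30, seed: int = 0,
                 unit_variance: bool = False, clip: float = 10.0):
        self.n_comps = n_comps
        self.seed = seed
        self.unit_variance = unit_variance
        self.clip = clip

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = _as_dense(X)
        if self.unit_variance:
            sd = X.std(axis=0)
            self.gene_mean_ = X.mean(axis=0)
            self.gene_sd_ = np.where(sd > 0, sd, 1.0)
            X = np.clip((X - self.gene_mean_) / self.gene_sd_, -self.clip, self.clip)
        n_cells, n_genes = X.shape
        if self.n_comps > min(n_cells, n_genes):
            raise ValueError(f"n_comps={self.n_comps} exceeds min(n_cells, n_genes)")
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("degenerate input: all genes constant, PCA undefined")
        self._pca = PCA(n_components=self.n_comps, svd_solver="full", random_state=self.seed)
        scores = self._pca.fit_transform(X)
        # deterministic sign: largest-|loading| entry of each component positive
        flip = np.sign(self._pca.components_[np.arange(self.n_comps),
                                             np.abs(self._pca.components_).argmax(axis=1)])
        self._pca.components_ *= flip[:, None]
        scores *= flip[None, :]
        self.components_ = self._pca.components_
        self.mean_ = self._pca.mean_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        return scores

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = _as_dense(X)
        if self.unit_variance:
            X = np.clip((X - self.gene_mean_) / self.gene_sd_, -self.clip, self.clip)
        return (X - self.mean_) @ self.components_.T


def regress_out(X, covariate) -> np.ndarray:
    """Remove the per-gene linear component of ``covariate`` (e.g. log
    library depth) from a cells x genes matrix.

    Sequencing depth leaks into log-normalized sparse data through the
    detection rate and would otherwise masquerade as a biological axis in
    PCA; this is the usual single-covariate residualization.
    """
    X = _as_dense(X)
    c = np.asarray(covariate, dtype=float)
    if c.shape[0] != X.shape[0]:
        raise ValueError("covariate length must equal the number of cells")
    c = c - c.mean()
    var = float(c @ c)
    if var == 0:
        return X.copy()
    beta = (c @ (X - X.mean(axis=0))) / var
    return X - np.outer(c, beta)


def standard_embedding(
    norm, gene_ids, totals=None, n_hvg: int = 1000, n_pcs: int = 30, seed: int = 0
):
    """The pipeline's embedding chain: HVG selection, per-gene unit-variance
    scaling, optional depth regression, PCA.  Returns (scores, hvg_support,
    fitted PCAEmbedding)."""
    norm = _as_dense(norm)
    hvg = HighlyVariableGenes(n_top=min(n_hvg, norm.shape[1])).fit(norm, gene_ids=gene_ids)
    X = norm[:, hvg.get_support()]
    sd = X.std(axis=0)
    X = np.clip((X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), -10.0, 10.0)
    if totals is not None:
        X = regress_out(X, np.log(np.asarray(totals, dtype=float)))
    pca = PCAEmbedding(n_comps=n_pcs, seed=seed)
    scores = pca.fit_transform(X)
    return scores, hvg.get_support(), pca


def normalize_log(counts, scale: float = 1e4, drop_empty: bool = False) -> np.ndarray:
    """Functional form of :class:`LogNormalizer` (cells x genes in and out)."""
    return LogNormalizer(scale=scale, drop_empty=drop_empty).transform(counts)


def select_hvg(norm, n_top: int, gene_ids=None, n_bins: int = 20) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes (sorted ascending)."""
    return HighlyVariableGenes(n_top=n_top, n_bins=n_bins).fit(norm, gene_ids=gene_ids).get_support()


def pca_embed(norm, genes=None, n_comps: int = 30, seed: int = 0):
    """PCA scores and the fitted embedding for (optionally gene-restricted) data."""
    X = _as_dense(norm)
    if genes is not None:
        X = X[:, np.asarray(genes)]
    est = PCAEmbedding(n_comps=n_comps, seed=seed)
    scores = est.fit_transform(X)
    return scores, est
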