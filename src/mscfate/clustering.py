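"""Subpopulation discovery in PCA space and cluster characterization."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import pairwise_distances_argmin_min
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "KMeansSubpopulations",
    "kmeans_cluster",
    "signature_score",
    "cluster_summary",
]


class KMeansSubpopulations(BaseEstimator, ClusterMixin):
    """Best-of-``n_init`` Lloyd's k-means with k-means++ seeding.

    An explicit Lloyd loop is used so the within-cluster sum of squares can
    be asserted non-increasing at every iteration (``inertia_path_`` keeps
    the trace of the winning run).  Deterministic given ``seed``.
    """

    def __init__(self, k: int = 9, n_init: int = 50, max_iter: int = 300,
                 tol: float = 1e-7, seed: int = 0):
        self.k = k
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds {n} cells")
        best = None
        seeds = np.random.SeedSequence(self.seed).spawn(self.n_init)
        for ss in seeds:
            rng = np.random.default_rng(ss)
            labels, centers, path = self._lloyd(X, rng)
            if best is None or path[-1] < best[2][-1]:
                best = (labels, centers, path)
        self.labels_, self.cluster_centers_, self.inertia_path_ = best
        self.inertia_ = self.inertia_path_[-1]
        self.cluster_sizes_ = np.bincount(self.labels_, minlength=self.k)
        return self

    def _lloyd(self, X, rng):
        centers, _ = kmeans_plusplus(
            X, self.k, random_state=int(rng.integers(2**31 - 1))
        )
        path: list[float] = []
        labels = None
        prev = None
        for _ in range(self.max_iter):
            labels, dists = pairwise_distances_argmin_min(X, centers)
            inertia = float(np.sum(dists**2))
            if prev is not None and inertia > prev * (1 + 1e-12) + 1e-12:
                raise AssertionError("k-means objective increased across a Lloyd iteration")
            path.append(inertia)
            if prev is not None and (prev - inertia) <= self.tol * max(prev, 1e-30):
                break
            prev = inertia
            for j in range(self.k):
                mask = labels == j
                if mask.any():
                    centers[j] = X[mask].mean(axis=0)
                else:  # re-seed empty cluster at the farthest point
                    centers[j] = X[np.argmax(dists)]
        return labels, centers, path

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        labels, _ = pairwise_distances_argmin_min(np.asarray(X, float), self.cluster_centers_)
        return labels


def kmeans_cluster(embedding, k: int, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """Per-cell cluster labels in 0..k-1 (functional form)."""
    return KMeansSubpopulations(k=k, n_init=n_init, seed=seed).fit_predict(embedding)


def signature_score(norm, gene_ids, gene_set) -> tuple[np.ndarray, list[str]]:
    """Per-cell signature score: mean of gene-wise z-scored intensities.

    Parameters
    ----------
    norm : cells x genes normalized intensities.
    gene_ids : identifiers for the columns of ``norm``.
    gene_set : iterable of gene ids making up the signature.

    Returns the score vector and the list of set genes missing from the
    matrix.  Raises if no set gene is present.  Zero-variance genes get a
    z-score of 0 (no information), so the population mean score is 0.
    """
    norm = np.asarray(norm, dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if not present:
        raise ValueError(f"no signature gene found in matrix; missing: {missing}")
    cols = [index[g] for g in present]
    sub = norm[:, cols]
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z.mean(axis=1), missing


def cluster_summary(
    labels, cell_table: pd.DataFrame, scores: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Per-cluster composition: size, day/matrix fractions, mean signatures.

    ``cell_table`` rows must align with ``labels`` (same cells, same order);
    day fractions sum to 1 within a cluster, as do matrix fractions.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cell_table):
        raise ValueError("labels and cell table length mismatch")
    scores = scores or {}
    for name, s in scores.items():
        if len(s) != len(labels):
            raise ValueError(f"signature score {name!r} length mismatch")
    df = cell_table.reset_index(drop=True).copy()
    df["cluster"] = labels
    rows = []
    for c in sorted(np.unique(labels)):
        sub = df[df["cluster"] == c]
        row: dict[str, object] = {"cluster": c, "n_cells": len(sub)}
        for day in ("D0", "D3", "D6"):
            row[f"frac_{day}"] = float((sub["day"] == day).mean())
        for m in ("PS", "soft", "stiff"):
            row[f"frac_{m}"] = float((sub["matrix"] == m).mean())
        for name, s in scores.items():
            row[f"mean_{name}"] = float(np.asarray(s)[sub.index].mean())
        rows.append(row)
    return pd.DataFrame(rows)
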