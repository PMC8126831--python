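"""Per-condition trajectory inference.

Diffusion map with local-scaling Gaussian kernel, diffusion pseudotime
(random-walk distance from a root cell), Y-shaped elastic principal tree
with support nodes, branch assignment, and kernel-smoothed expression
profiles along a root-to-tip projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.base import BaseEstimator
from sklearn.metrics import pairwise_distances, pairwise_distances_argmin_min
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DiffusionMap",
    "rescale_rank",
    "diffusion_pseudotime",
    "ElasticPrincipalTree",
    "PseudotimeAssignment",
    "assign_branches",
    "TrajectoryProfile",
    "smooth_profiles",
    "select_root",
    "select_tips",
]


class GraphConnectivityError(RuntimeError):
    """kNN graph splits into several components; raise knn to reconnect."""


class DiffusionMap(BaseEstimator):
    """Spectral embedding of a locally-scaled kNN transition operator.

    Construction: Gaussian kernel ``exp(-d_ij^2 / (sigma_i sigma_j))`` on
    the symmetrized kNN graph, with ``sigma_i`` the distance from cell i to
    its ``ceil(knn/2)``-th neighbor; density normalization (divide each
    entry by the product of row sums); row normalization to a stochastic
    operator; eigendecomposition of the symmetric conjugate.  The trivial
    eigenpair (eigenvalue 1, constant vector) is dropped.

    Fitted attributes: ``eigenvalues_`` (descending, in (0, 1)),
    ``eigenvectors_`` (cells x n_comps, unit norm, deterministic sign).
    """

    def __init__(self, knn: int = 30, n_comps: int = 10):
        self.knn = knn
        self.n_comps = n_comps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if not np.all(np.isfinite(X)):
            raise ValueError("embedding contains non-finite values")
        if n < self.knn + 1:
            raise ValueError(f"need at least knn+1={self.knn + 1} cells, got {n}")

        nn = NearestNeighbors(n_neighbors=self.knn + 1).fit(X)
        dist, idx = nn.kneighbors(X)
        dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
        sigma = dist[:, int(np.ceil(self.knn / 2)) - 1]
        sigma = np.maximum(sigma, 1e-12)

        rows = np.repeat(np.arange(n), self.knn)
        cols = idx.ravel()
        vals = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
        W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        W = W.maximum(W.T)  # symmetrized kNN graph (edge union)

        n_comp, labels = connected_components(W, directed=False)
        if n_comp > 1:
            sizes = np.bincount(labels).tolist()
            raise GraphConnectivityError(
                f"kNN graph has {n_comp} components of sizes {sizes}; raise knn"
            )

        q = np.asarray(W.sum(axis=1)).ravel()  # density normalization
        Dq = sp.diags(1.0 / q)
        W = Dq @ W @ Dq
        d = np.asarray(W.sum(axis=1)).ravel()
        d_isqrt = sp.diags(1.0 / np.sqrt(d))
        S = d_isqrt @ W @ d_isqrt  # symmetric conjugate of the row-normalized operator

        k = min(self.n_comps + 1, n - 1)
        evals, evecs = eigsh(S, k=k, which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if not np.isclose(evals[0], 1.0, atol=1e-8):
            raise RuntimeError("leading eigenvalue of the transition operator is not 1")
        evals, evecs = evals[1:], evecs[:, 1:]
        if np.any(np.abs(evals - 1.0) < 1e-10):
            raise RuntimeError("trivial eigenvalue retained among nontrivial components")

        psi = d_isqrt @ evecs  # right eigenvectors of the transition operator
        psi /= np.linalg.norm(psi, axis=0, keepdims=True)
        flip = np.sign(psi[np.abs(psi).argmax(axis=0), np.arange(psi.shape[1])])
        psi *= flip[None, :]
        self.eigenvalues_ = evals
        self.eigenvectors_ = psi
        self.n_cells_ = n
        return self

    def dpt_coords(self) -> np.ndarray:
        """Cells embedded so Euclidean distance equals the dpt distance."""
        check_is_fitted(self, "eigenvalues_")
        w = self.eigenvalues_ / (1.0 - self.eigenvalues_)
        return self.eigenvectors_ * w[None, :]


def diffusion_pseudotime(dmap: DiffusionMap, root: int) -> np.ndarray:
    """Random-walk pseudotime: dpt distance of every cell from ``root``.

    ``t(x) = sqrt(sum_i (l_i/(1-l_i))^2 (psi_i(x) - psi_i(root))^2)``;
    the root has t = 0.
    """
    coords = dmap.dpt_coords()
    if not 0 <= root < dmap.n_cells_:
        raise ValueError(f"root index {root} out of range")
    return np.linalg.norm(coords - coords[root], axis=1)


def select_root(embedding, d0_cells) -> int:
    """Day-0 medoid: the D0 cell with minimal mean distance to other D0 cells."""
    d0 = np.asarray(d0_cells)
    if d0.dtype == bool:
        d0 = np.flatnonzero(d0)
    if d0.size < 1:
        raise ValueError("no day-0 cells to choose a root from")
    D = pairwise_distances(np.asarray(embedding, float)[d0])
    return int(d0[np.argmin(D.sum(axis=1))])



def _split_arms(coords, depth, seed, min_frac=0.2, max_peel=3):
    """Partition cells into two trajectory arms.

    Works on coordinates residualized against progression depth (arms
    separate orthogonally to the trajectory) and peels off minority
    clusters (e.g. a cycling-cell cloud) until a balanced two-way split
    remains; peeled cells are then attached to the nearer arm centroid.
    Returns a 0/1 label per cell.
    """
    from .clustering import KMeansSubpopulations

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 4:
        return (depth > np.median(depth)).astype(int)
    c = depth - depth.mean()
    Xc = coords - coords.mean(axis=0)
    denom = float(c @ c)
    beta = (c @ Xc) / denom if denom > 0 else np.zeros(coords.shape[1])
    R = Xc - np.outer(c, beta)

    active = np.arange(n)
    labels = None
    for _ in range(max_peel + 1):
        km = KMeansSubpopulations(k=2, n_init=10, seed=seed).fit(R[active])
        lab = km.labels_
        frac = min(np.mean(lab == 0), np.mean(lab == 1))
        labels = (active, lab, km.cluster_centers_)
        if frac >= min_frac or active.size < 10:
            break
        keep = lab != np.argmin(np.bincount(lab))  # peel the minority cloud
        active = active[keep]
    active, lab, centers = labels
    out = np.empty(n, dtype=int)
    out[active] = lab
    rest = np.setdiff1d(np.arange(n), active)
    if rest.size:
        d = np.linalg.norm(R[rest, None, :] - centers[None, :, :], axis=2)
        out[rest] = np.argmin(d, axis=1)
    return out


def select_tips(dmap: DiffusionMap, root: int, candidate_cells) -> tuple[int, int]:
    """Two branch tips among candidates (day-6 cells of the condition).

    Candidates are partitioned into the two post-bifurcation arms
    (two-means on depth-residualized diffusion coordinates, peeling
    minority clouds); each arm's tip is its cell farthest from the root
    in dpt distance.
    """
    cand = np.asarray(candidate_cells)
    if cand.dtype == bool:
        cand = np.flatnonzero(cand)
    if cand.size < 2:
        raise ValueError("need at least two candidate cells for tips")
    coords = dmap.dpt_coords()
    t_root = np.linalg.norm(coords[cand] - coords[root], axis=1)
    arms = _split_arms(coords[cand], t_root, seed=0)
    if len(np.unique(arms)) < 2:
        order = np.argsort(t_root)
        return int(cand[order[-1]]), int(cand[order[-2]])
    g1, g2 = cand[arms == 0], cand[arms == 1]
    tip1 = int(g1[np.argmax(t_root[arms == 0])])
    tip2 = int(g2[np.argmax(t_root[arms == 1])])
    if tip1 == tip2:
        raise ValueError("tip selection collapsed to a single cell")
    return tip1, tip2


class ElasticPrincipalTree(BaseEstimator):
    """Elastic principal tree with fixed path or Y topology.

    Minimizes ``U = (1/N) sum_cells ||x - node(x)||^2
    + lambda_stretch * sum_edges ||n_i - n_j||^2
    + mu_bend * sum_{2-edge paths i-j-k} ||n_i - 2 n_j + n_k||^2``
    by alternating nearest-node assignment with the exact linear node
    update.  With two tips the Y scaffold is initialized from anchor
    distances: the fork starts at the cell minimizing the summed distance
    to the root and both tips, the trunk holds the cells no farther from
    the root than the fork, every other cell starts on the branch of its
    nearer tip, and each segment becomes a bin-averaged polyline.  The
    fork node has degree 3.  The energy is asserted non-increasing at
    every iteration (trace kept in ``energies_``).
    """

    def __init__(self, n_nodes: int = 30, lambda_stretch: float = 0.01,
                 mu_bend: float = 0.1, max_iter: int = 100, tol: float = 1e-6,
                 seed: int = 0):
        self.n_nodes = n_nodes
        self.lambda_stretch = lambda_stretch
        self.mu_bend = mu_bend
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    # -- scaffold construction -------------------------------------------
    @staticmethod
    def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
        """n points at even arc length along a polyline."""
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] == 0:
            return np.repeat(points[:1], n, axis=0)
        targets = np.linspace(0.0, s[-1], n)
        out = np.empty((n, points.shape[1]))
        for d in range(points.shape[1]):
            out[:, d] = np.interp(targets, s, points[:, d])
        return out

    @staticmethod
    def _binned_polyline(X, members, order_key, start, end, n_bins=12):
        """Polyline from ``start`` to ``end`` through bin means of member
        cells sorted by ``order_key`` (robust to noise around the curve)."""
        pts = [start]
        if members.size:
            o = members[np.argsort(order_key[members])]
            n_bins = min(n_bins, o.size)
            for chunk in np.array_split(o, n_bins):
                pts.append(X[chunk].mean(axis=0))
        pts.append(end)
        return np.asarray(pts)

    def _init_skeleton(self, X, root, tips):
        d_root = np.linalg.norm(X - X[root], axis=1)
        if len(tips) == 1:  # path topology: single polyline root -> tip
            members = np.arange(X.shape[0])
            poly = self._binned_polyline(X, members, d_root, X[root], X[tips[0]])
            nodes = self._resample_polyline(poly, self.n_nodes)
            edges = [(i, i + 1) for i in range(self.n_nodes - 1)]
            return nodes, edges, ["trunk"] * self.n_nodes, None

        tip1, tip2 = tips
        d1 = np.linalg.norm(X - X[tip1], axis=1)
        d2 = np.linalg.norm(X - X[tip2], axis=1)
        fork = int(np.argmin(d_root + d1 + d2))
        on_trunk = d_root <= d_root[fork]
        g_trunk = np.flatnonzero(on_trunk)
        post = np.flatnonzero(~on_trunk)

        # partition post-fork cells into the two arms on depth-residualized
        # coordinates: raw distances to single tip cells are dominated by
        # where a cell sits along the trajectory, while the arms separate
        # orthogonally to it
        if post.size >= 4:
            arms = _split_arms(X[post], d_root[post], seed=self.seed)
        else:
            arms = (d1[post] > d2[post]).astype(int)
        ga, gb = post[arms == 0], post[arms == 1]
        # branch1 is the arm whose centroid lies nearer tip1 (deterministic)
        if ga.size and gb.size:
            if np.linalg.norm(X[ga].mean(axis=0) - X[tip1]) > np.linalg.norm(
                X[gb].mean(axis=0) - X[tip1]
            ):
                ga, gb = gb, ga
        end1 = X[ga[np.argmax(d_root[ga])]] if ga.size else X[tip1]
        end2 = X[gb[np.argmax(d_root[gb])]] if gb.size else X[tip2]

        polys = [
            self._binned_polyline(X, g_trunk, d_root, X[root], X[fork]),
            self._binned_polyline(X, ga, d_root, X[fork], end1),
            self._binned_polyline(X, gb, d_root, X[fork], end2),
        ]
        lengths = np.maximum(
            [np.linalg.norm(np.diff(p, axis=0), axis=1).sum() for p in polys], 1e-9
        )
        # >=2 nodes per segment, remainder proportional to arc length
        alloc = np.full(3, 2)
        extra = self.n_nodes - 2 - alloc.sum()  # arms share the fork node with the trunk
        if extra < 0:
            raise ValueError("n_nodes must be at least 4 for a Y topology")
        frac = lengths / lengths.sum()
        add = np.floor(frac * extra).astype(int)
        for i in np.argsort(frac)[::-1]:
            if add.sum() >= extra:
                break
            add[i] += extra - add.sum()
        alloc += add

        trunk = self._resample_polyline(polys[0], alloc[0])
        arm1 = self._resample_polyline(polys[1], alloc[1] + 1)[1:]
        arm2 = self._resample_polyline(polys[2], alloc[2] + 1)[1:]
        nodes = np.vstack([trunk, arm1, arm2])
        fork_node = alloc[0] - 1
        edges = [(i, i + 1) for i in range(alloc[0] - 1)]
        a1 = list(range(alloc[0], alloc[0] + alloc[1]))
        a2 = list(range(alloc[0] + alloc[1], alloc[0] + alloc[1] + alloc[2]))
        for chain in (a1, a2):
            prev = fork_node
            for j in chain:
                edges.append((prev, j))
                prev = j
        branch = (["trunk"] * alloc[0]) + (["branch1"] * alloc[1]) + (["branch2"] * alloc[2])
        return nodes, edges, branch, fork_node

    # -- quadratic penalty operators -------------------------------------
    @staticmethod
    def _penalty_matrices(n_nodes, edges):
        L = np.zeros((n_nodes, n_nodes))
        for i, j in edges:
            L[i, i] += 1
            L[j, j] += 1
            L[i, j] -= 1
            L[j, i] -= 1
        nbrs = [[] for _ in range(n_nodes)]
        for i, j in edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        rows = []
        for j in range(n_nodes):
            ns = nbrs[j]
            for a in range(len(ns)):
                for b in range(a + 1, len(ns)):
                    row = np.zeros(n_nodes)
                    row[ns[a]] += 1
                    row[ns[b]] += 1
                    row[j] -= 2
                    rows.append(row)
        B = np.array(rows) if rows else np.zeros((0, n_nodes))
        return L, B

    def _energy(self, X, nodes, labels, L, B):
        data = np.mean(np.sum((X - nodes[labels]) ** 2, axis=1))
        stretch = self.lambda_stretch * float(np.einsum("ij,ik,jk->", L, nodes, nodes))
        bend = self.mu_bend * float(np.sum((B @ nodes) ** 2))
        return data + stretch + bend

    def fit(self, X, root: int, tips) -> "ElasticPrincipalTree":
        X = np.asarray(X, dtype=float)
        tips = [int(t) for t in np.atleast_1d(tips)]
        if root in tips or len(set(tips)) != len(tips):
            raise ValueError("root and tips must be distinct cells")
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        nodes, edges, branch, fork = self._init_skeleton(X, root, tips)
        L, B = self._penalty_matrices(len(nodes), edges)
        N = X.shape[0]

        energies = []
        labels, _ = pairwise_distances_argmin_min(X, nodes)
        for _ in range(self.max_iter):
            e_before = self._energy(X, nodes, labels, L, B)
            if energies and e_before > energies[-1] * (1 + 1e-9) + 1e-12:
                raise AssertionError("elastic tree energy increased")
            energies.append(e_before)

            # exact node update: (K/N + lam L + mu B'B) nodes = S/N
            counts = np.bincount(labels, minlength=len(nodes))
            S = np.zeros_like(nodes)
            np.add.at(S, labels, X)
            A = np.diag(counts / N) + self.lambda_stretch * L + self.mu_bend * (B.T @ B)
            A += 1e-12 * np.eye(len(nodes))
            nodes = np.linalg.solve(A, S / N)

            labels, _ = pairwise_distances_argmin_min(X, nodes)
            e_after = self._energy(X, nodes, labels, L, B)
            if abs(energies[-1] - e_after) <= self.tol * max(abs(energies[-1]), 1e-30):
                energies.append(e_after)
                break
        else:
            energies.append(self._energy(X, nodes, labels, L, B))

        self.nodes_ = nodes
        self.edges_ = edges
        self.node_branch_ = np.asarray(branch, dtype=object)
        self.bifurcation_node_ = fork
        self.cell_node_ = labels
        self.energies_ = np.asarray(energies)
        degrees = np.bincount(np.array(edges).ravel(), minlength=len(nodes))
        self.node_degrees_ = degrees
        if fork is not None:
            assert degrees[fork] == 3 and (degrees > 3).sum() == 0
        return self


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime, branch, and biological branch tags."""

    table: pd.DataFrame  # columns: t, branch, branch_tag
    tags: dict[str, str]  # branch1/branch2 -> biological tag


def assign_branches(
    tree: ElasticPrincipalTree,
    dpt_t: np.ndarray,
    primary_score: np.ndarray,
    tag_high: str,
    tag_low: str,
) -> PseudotimeAssignment:
    """Attach branch labels and biological tags to cells of one condition.

    Cells inherit the branch of their support node; the bifurcation node
    belongs to the trunk.  The post-bifurcation branch whose terminal
    segment (outer half of its node chain) has the larger mean
    ``primary_score`` gets ``tag_high`` (e.g. the adipogenic signature on
    soft matrix tags the AD branch), the other gets ``tag_low``.
    """
    check_is_fitted(tree, "nodes_")
    if tree.bifurcation_node_ is None:
        raise ValueError("tree has no bifurcation node (path topology)")
    dpt_t = np.asarray(dpt_t, dtype=float)
    primary_score = np.asarray(primary_score, dtype=float)
    cell_branch = tree.node_branch_[tree.cell_node_]

    means = {}
    for br in ("branch1", "branch2"):
        chain = np.flatnonzero(tree.node_branch_ == br)
        terminal = chain[len(chain) // 2:]
        cells = np.isin(tree.cell_node_, terminal)
        means[br] = primary_score[cells].mean() if cells.any() else -np.inf
    if means["branch1"] == means["branch2"]:
        raise ValueError(
            "tie in branch signature tagging; pass explicit tags per branch"
        )
    high = "branch1" if means["branch1"] > means["branch2"] else "branch2"
    low = "branch2" if high == "branch1" else "branch1"
    tags = {high: tag_high, low: tag_low, "trunk": "trunk"}

    table = pd.DataFrame(
        {
            "t": dpt_t,
            "branch": cell_branch,
            "branch_tag": [tags[b] for b in cell_branch],
        }
    )
    return PseudotimeAssignment(table=table, tags={k: tags[k] for k in ("branch1", "branch2")})


@dataclass
class TrajectoryProfile:
    """Kernel-smoothed per-gene intensities on a uniform pseudotime grid."""

    grid: np.ndarray          # T points on [0, 1], uniform
    values: np.ndarray        # genes x T, non-negative
    bandwidth: float
    tag: str
    extrapolated: np.ndarray  # grid points >3h away from every cell

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0])


def rescale_unit(t: np.ndarray) -> np.ndarray:
    """Affinely map pseudotimes onto [0, 1] (constant input maps to 0)."""
    t = np.asarray(t, dtype=float)
    lo, hi = t.min(), t.max()
    if hi == lo:
        return np.zeros_like(t)
    return (t - lo) / (hi - lo)


def rescale_rank(t: np.ndarray) -> np.ndarray:
    """Map pseudotimes onto [0, 1] by their empirical CDF (rank order).

    The grid then allocates its points uniformly over cells instead of
    over raw diffusion distance, which otherwise over-weights the late,
    fast-moving part of a trajectory; equivalent to an adaptive kernel
    bandwidth in raw pseudotime units.  Monotone, hence order-preserving.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 1 or np.ptp(t) == 0:
        return np.zeros_like(t)
    order = np.argsort(np.argsort(t, kind="stable"), kind="stable")
    return order / (t.size - 1)


def smooth_profiles(
    intensities, t, T: int = 50, h: float = 0.1, tag: str = ""
) -> TrajectoryProfile:
    """Nadaraya-Watson Gaussian-kernel profiles of projection cells.

    ``intensities`` is cells x genes for the cells of one root-to-tip
    projection, ``t`` their pseudotimes (rescaled internally to [0, 1]).
    Grid points farther than ``3 h`` from every cell take the nearest
    cell's value and are flagged in ``extrapolated``.
    """
    Y = np.asarray(intensities, dtype=float)
    t = np.asarray(t, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != t.size:
        raise ValueError("intensities and pseudotimes disagree on cell count")
    if Y.shape[0] < 5:
        raise ValueError("projection needs at least 5 cells")
    if h <= 0 or T < 2:
        raise ValueError("need bandwidth h > 0 and grid size T >= 2")
    ts = rescale_unit(t)
    grid = np.linspace(0.0, 1.0, T)
    diff = grid[:, None] - ts[None, :]
    W = np.exp(-(diff**2) / (2.0 * h * h))
    out = (W @ Y) / W.sum(axis=1)[:, None]
    far = np.abs(diff).min(axis=1) > 3.0 * h
    if far.any():
        nearest = np.abs(diff).argmin(axis=1)
        out[far] = Y[nearest[far]]
    return TrajectoryProfile(
        grid=grid, values=out.T, bandwidth=float(h), tag=tag, extrapolated=far
    )
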