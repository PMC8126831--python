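import numpy as np
import pytest
from scipy.stats import spearmanr

from mscfate import (
    DiffusionMap,
    ElasticPrincipalTree,
    assign_branches,
    diffusion_pseudotime,
    select_root,
    select_tips,
    smooth_profiles,
)
from mscfate.trajectory import GraphConnectivityError


def dense_diffusion_oracle(X, knn, n_comps):
    """Independent dense construction of the locally-scaled transition
    operator and its spectrum (no code shared with DiffusionMap)."""
    n = X.shape[0]
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    order = np.argsort(D, axis=1)
    sigma = np.array([D[i, order[i, int(np.ceil(knn / 2))]] for i in range(n)])
    W = np.zeros((n, n))
    for i in range(n):
        for j in order[i, 1:knn + 1]:
            W[i, j] = np.exp(-D[i, j] ** 2 / (sigma[i] * sigma[j]))
    W = np.maximum(W, W.T)
    q = W.sum(axis=1)
    W = W / np.outer(q, q)
    d = W.sum(axis=1)
    S = W / np.sqrt(np.outer(d, d))
    evals, evecs = np.linalg.eigh(S)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    psi = evecs / np.sqrt(d)[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    return evals[1:n_comps + 1], psi[:, 1:n_comps + 1]


class TestDiffusionMap:
    def test_matches_dense_bruteforce_on_dense_graph(self):
        """50-cell toy with knn = 49 (complete graph): eigenpairs agree with
        an independently coded dense operator construction to 1e-8."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        dmap = DiffusionMap(knn=49, n_comps=6).fit(X)
        evals, psi = dense_diffusion_oracle(X, 49, 6)
        np.testing.assert_allclose(dmap.eigenvalues_, evals, atol=1e-8)
        # eigenvectors agree up to sign
        dots = np.abs(np.sum(dmap.eigenvectors_ * psi, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_eigenvalues_lie_in_open_unit_interval(self):
        X = np.random.default_rng(1).normal(size=(120, 5))
        dmap = DiffusionMap(knn=15, n_comps=8).fit(X)
        assert np.all(dmap.eigenvalues_ > 0) and np.all(dmap.eigenvalues_ < 1)

    def test_disconnected_graph_reports_component_sizes(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, size=(30, 3)),
                       rng.normal(500, 1, size=(20, 3))])
        with pytest.raises(GraphConnectivityError, match="2 components"):
            DiffusionMap(knn=5, n_comps=3).fit(X)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            DiffusionMap(knn=30).fit(np.ones((10, 2)))


class TestDiffusionPseudotime:
    def test_root_has_zero_pseudotime(self):
        X = np.random.default_rng(3).normal(size=(80, 4))
        dmap = DiffusionMap(knn=10, n_comps=5).fit(X)
        t = diffusion_pseudotime(dmap, root=17)
        assert t[17] == 0.0 and np.all(t >= 0) and np.all(np.isfinite(t))

    def test_distance_is_symmetric(self):
        X = np.random.default_rng(4).normal(size=(60, 3))
        dmap = DiffusionMap(knn=10, n_comps=5).fit(X)
        ta = diffusion_pseudotime(dmap, root=5)
        tb = diffusion_pseudotime(dmap, root=40)
        assert ta[40] == pytest.approx(tb[5], rel=1e-12)

    def test_noise_free_chain_is_ordered_perfectly(self):
        """100 cells on a 1-D line: dpt from one end reproduces the chain
        order exactly (Spearman correlation 1)."""
        x = np.linspace(0, 1, 100)
        X = np.column_stack([x, np.zeros(100)])
        dmap = DiffusionMap(knn=8, n_comps=5).fit(X)
        t = diffusion_pseudotime(dmap, root=0)
        assert spearmanr(t, x).statistic == pytest.approx(1.0)


def make_planar_y(n_per=250):
    """Noise-free planar Y: trunk (0,0)->(1,0), arms to (2, +-0.8)."""
    s = np.linspace(0, 1, n_per)
    trunk = np.column_stack([s, np.zeros(n_per)])
    arm1 = np.column_stack([1 + s, 0.8 * s])
    arm2 = np.column_stack([1 + s, -0.8 * s])
    X = np.vstack([trunk, arm1, arm2])
    segments = [((0, 0), (1, 0)), ((1, 0), (2, 0.8)), ((1, 0), (2, -0.8))]
    return X, 0, [2 * n_per - 1, 3 * n_per - 1], segments


def dist_to_segment(p, a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
    return np.linalg.norm(p - (a + u * (b - a)))


class TestElasticPrincipalTree:
    def test_recovers_noise_free_y_skeleton(self):
        X, root, tips, segments = make_planar_y()
        tree = ElasticPrincipalTree(n_nodes=30, seed=0).fit(X, root, tips)
        d = [min(dist_to_segment(p, *seg) for seg in segments) for p in tree.nodes_]
        rms = float(np.sqrt(np.mean(np.square(d))))
        assert rms < 0.05
        assert tree.bifurcation_node_ is not None
        assert tree.node_degrees_[tree.bifurcation_node_] == 3
        assert tree.node_degrees_.max() == 3

    def test_energy_is_non_increasing(self):
        X, root, tips, _ = make_planar_y(120)
        X = X + np.random.default_rng(5).normal(0, 0.05, size=X.shape)
        tree = ElasticPrincipalTree(n_nodes=20, seed=5).fit(X, root, tips)
        assert np.all(np.diff(tree.energies_) <= 1e-9 * np.abs(tree.energies_[:-1]) + 1e-12)

    def test_extreme_bending_penalty_straightens_a_path(self):
        rng = np.random.default_rng(6)
        s = np.linspace(0, np.pi, 200)
        X = np.column_stack([s, 0.3 * np.sin(s)]) + rng.normal(0, 0.01, size=(200, 2))
        tree = ElasticPrincipalTree(n_nodes=12, mu_bend=1e6, seed=6).fit(X, 0, [199])
        centered = tree.nodes_ - tree.nodes_.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        assert sv[1] < 1e-3 * sv[0]  # nodes collinear

    def test_scale_equivariance(self):
        X, root, tips, _ = make_planar_y(100)
        t1 = ElasticPrincipalTree(n_nodes=16, seed=7).fit(X, root, tips)
        t2 = ElasticPrincipalTree(n_nodes=16, seed=7).fit(2 * X, root, tips)
        np.testing.assert_allclose(t2.nodes_, 2 * t1.nodes_, atol=1e-8)

    def test_invalid_arguments_rejected(self):
        X, root, tips, _ = make_planar_y(50)
        with pytest.raises(ValueError, match="distinct"):
            ElasticPrincipalTree().fit(X, root, [root])
        with pytest.raises(ValueError, match="n_nodes"):
            ElasticPrincipalTree(n_nodes=3).fit(X, root, tips)


class TestAssignBranches:
    def fitted_tree(self):
        X, root, tips, _ = make_planar_y(150)
        tree = ElasticPrincipalTree(n_nodes=24, seed=8).fit(X, root, tips)
        dmapless_t = np.linalg.norm(X - X[root], axis=1)
        return X, tree, dmapless_t

    def test_cells_inherit_support_node_branch_and_fork_is_trunk(self):
        X, tree, t = self.fitted_tree()
        score = X[:, 1]  # arm1 has positive y
        out = assign_branches(tree, t, score, "UP", "DOWN")
        fork_cells = tree.cell_node_ == tree.bifurcation_node_
        assert (out.table.loc[fork_cells, "branch"] == "trunk").all()
        up = out.table["branch_tag"] == "UP"
        assert X[up.to_numpy(), 1].mean() > 0.2

    def test_higher_signature_branch_gets_the_high_tag(self):
        X, tree, t = self.fitted_tree()
        out = assign_branches(tree, t, -X[:, 1], "HI", "LO")
        hi = out.table["branch_tag"] == "HI"
        assert X[hi.to_numpy(), 1].mean() < 0  # negative-y arm scores higher now

    def test_path_topology_rejected(self):
        X, root, tips, _ = make_planar_y(60)
        tree = ElasticPrincipalTree(n_nodes=10, seed=9).fit(X, root, [tips[0]])
        with pytest.raises(ValueError, match="bifurcation"):
            assign_branches(tree, np.zeros(len(X)), np.zeros(len(X)), "A", "B")

    def test_signature_tie_raises(self):
        X, tree, t = self.fitted_tree()
        with pytest.raises(ValueError, match="tie"):
            assign_branches(tree, t, np.zeros(len(X)), "A", "B")


class TestSmoothProfiles:
    def test_constant_gene_gives_constant_profile(self):
        t = np.linspace(0, 1, 40)
        y = np.full((40, 1), 3.3)
        prof = smooth_profiles(y, t, T=25, h=0.1)
        np.testing.assert_allclose(prof.values, 3.3)

    def test_five_identical_cells(self):
        prof = smooth_profiles(np.full((5, 2), 1.7), np.zeros(5), T=10, h=0.1)
        np.testing.assert_allclose(prof.values, 1.7)
        assert prof.extrapolated.any()  # grid far from the single time point

    def test_linear_gene_recovered_within_bandwidth(self):
        """Intensity equal to pseudotime on a dense noise-free projection:
        kernel-regression bias is bounded by the bandwidth."""
        t = np.linspace(0, 1, 600)
        prof = smooth_profiles(t[:, None], t, T=50, h=0.08)
        err = np.abs(prof.values[0] - prof.grid)
        assert err.max() < 0.08

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(10)
        t = rng.random(80)
        y = rng.gamma(2.0, 1.0, size=(80, 3))
        perm = rng.permutation(80)
        a = smooth_profiles(y, t, T=20, h=0.1)
        b = smooth_profiles(y[perm], t[perm], T=20, h=0.1)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_grid_is_uniform_and_values_finite(self):
        rng = np.random.default_rng(11)
        prof = smooth_profiles(rng.gamma(1.0, 1.0, (30, 4)), rng.random(30), T=15, h=0.2)
        steps = np.diff(prof.grid)
        np.testing.assert_allclose(steps, steps[0])
        assert np.all(np.isfinite(prof.values)) and np.all(prof.values >= 0)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 5"):
            smooth_profiles(np.ones((3, 1)), np.zeros(3))
        with pytest.raises(ValueError, match="bandwidth"):
            smooth_profiles(np.ones((6, 1)), np.zeros(6), h=0.0)
        with pytest.raises(ValueError, match="cell count"):
            smooth_profiles(np.ones((6, 1)), np.zeros(5))


class TestRootAndTips:
    def test_root_is_the_d0_medoid(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 2))
        d0 = np.arange(10)
        root = select_root(X, d0)
        D = np.linalg.norm(X[d0][:, None] - X[d0][None, :], axis=2)
        assert root == d0[np.argmin(D.sum(axis=1))]

    def test_tips_land_on_opposite_arms_of_a_y(self):
        X, root, true_tips, _ = make_planar_y(200)
        dmap = DiffusionMap(knn=12, n_comps=6).fit(X)
        cand = np.arange(len(X))[X[:, 0] > 1.5]  # outer halves of both arms
        tip1, tip2 = select_tips(dmap, root, cand)
        assert (X[tip1, 1] > 0) != (X[tip2, 1] > 0)
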