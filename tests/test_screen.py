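import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mscfate import MatrixResponsivenessScreen, mr_permutation_p, mr_score, screen_genes


def bruteforce_mr(sa, so, dt):
    """Term-by-term re-evaluation, deliberately sharing no code with mr_score."""
    total = 0.0
    for a, b in zip(sa, so):
        s = a + b
        if s > 0:
            total += abs(a - b) / s * dt
    return total


class TestMrScore:
    def test_identical_profiles_score_zero(self):
        v = np.array([0.0, 1.0, 2.5, 7.0])
        assert mr_score(v, v, 0.1) == 0.0

    def test_one_sided_saturation(self):
        # each term saturates at 1 when one profile is zero
        assert mr_score([2.0, 2.0], [0.0, 0.0], 0.1) == pytest.approx(0.2)

    def test_hand_computed_example(self):
        # terms (0.5, 0, 0.5), dt = 0.5 -> 0.5
        assert mr_score([1, 2, 3], [3, 2, 1], 0.5) == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            T = rng.integers(2, 30)
            sa = rng.gamma(1.0, 2.0, T) * rng.integers(0, 2, T)
            so = rng.gamma(1.0, 2.0, T) * rng.integers(0, 2, T)
            dt = float(rng.uniform(0.01, 1.0))
            assert mr_score(sa, so, dt) == pytest.approx(bruteforce_mr(sa, so, dt), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mr_score([1, 2], [1, 2, 3], 0.1)
        with pytest.raises(ValueError):
            mr_score([-1, 2], [1, 2], 0.1)
        with pytest.raises(ValueError):
            mr_score([1, 2], [1, 2], 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        sa=hnp.arrays(np.float64, 12,
                      elements=st.one_of(st.just(0.0), st.floats(1e-6, 50.0))),
        so=hnp.arrays(np.float64, 12,
                      elements=st.one_of(st.just(0.0), st.floats(1e-6, 50.0))),
        c=st.floats(1e-3, 1e3),
    )
    def test_bounds_symmetry_and_scale_invariance(self, sa, so, c):
        dt = 1 / 11
        mr = mr_score(sa, so, dt)
        assert 0.0 <= mr <= 12 * dt + 1e-12
        assert mr == pytest.approx(mr_score(so, sa, dt), abs=1e-12)
        assert mr == pytest.approx(mr_score(c * sa, c * so, dt), rel=1e-9, abs=1e-9)


class TestPermutationP:
    def test_constant_gene_is_degenerate_with_p_one(self):
        res = mr_permutation_p(np.full(10, 2.0), np.linspace(0, 1, 10),
                               np.full(12, 2.0), np.linspace(0, 1, 12), n_perm=19)
        assert res.p == 1.0 and res.degenerate and res.mr_observed == 0.0

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 40)
        res = mr_permutation_p(
            rng.gamma(1, 0.2, 40), t, 10.0 + rng.gamma(1, 0.2, 40), t,
            n_perm=19, seed=2,
        )
        assert res.p == pytest.approx(1 / 20)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        args = (rng.gamma(1, 1, 20), rng.random(20), rng.gamma(1, 1, 25), rng.random(25))
        a = mr_permutation_p(*args, n_perm=49, seed=11)
        b = mr_permutation_p(*args, n_perm=49, seed=11)
        assert a.p == b.p and a.mr_observed == b.mr_observed

    def test_tiny_projection_rejected(self):
        with pytest.raises(ValueError):
            mr_permutation_p(np.ones(3), np.ones(3), np.ones(10), np.ones(10))


class TestScreenGenes:
    def make_data(self, seed=4, n_genes=30):
        rng = np.random.default_rng(seed)
        t_a, t_b = rng.random(60), rng.random(70)
        Y_a = rng.gamma(1.0, 1.0, size=(60, n_genes))
        Y_b = rng.gamma(1.0, 1.0, size=(70, n_genes))
        Y_b[:, :5] += 5.0  # five strongly divergent genes
        return Y_a, t_a, Y_b, t_b

    def test_rank_structure(self):
        Y_a, t_a, Y_b, t_b = self.make_data()
        table = screen_genes(Y_a, t_a, Y_b, t_b, n_perm=99, seed=5, top_n=10)
        ranked = table.dropna(subset=["rank"]).sort_values("rank")
        assert list(ranked["rank"]) == list(range(1, len(ranked) + 1))
        assert np.all(np.diff(ranked["mr"].to_numpy()) <= 1e-12)
        assert table.loc[~table["retained"], "rank"].isna().all()
        assert set(ranked["gene_id"][:5]) >= {f"g{i:05d}" for i in range(5)} - set()

    def test_divergent_genes_pass_the_gate(self):
        Y_a, t_a, Y_b, t_b = self.make_data()
        table = screen_genes(Y_a, t_a, Y_b, t_b, n_perm=99, seed=6, p_threshold=0.05)
        assert table.loc[:4, "retained"].all()

    def test_zero_threshold_retains_nothing(self):
        Y_a, t_a, Y_b, t_b = self.make_data()
        with pytest.warns(UserWarning, match="truncated"):
            table = screen_genes(Y_a, t_a, Y_b, t_b, n_perm=19, seed=7, p_threshold=0.0)
        assert not table["retained"].any()
        assert table["rank"].isna().all()

    def test_deterministic_given_seed(self):
        Y_a, t_a, Y_b, t_b = self.make_data()
        t1 = screen_genes(Y_a, t_a, Y_b, t_b, n_perm=49, seed=8)
        t2 = screen_genes(Y_a, t_a, Y_b, t_b, n_perm=49, seed=8)
        assert t1.equals(t2)

    def test_ties_broken_lexicographically(self):
        # two exactly identical divergent genes -> equal MR, id order decides
        rng = np.random.default_rng(9)
        t_a, t_b = rng.random(30), rng.random(30)
        col_a, col_b = rng.gamma(1, 1, 30), 8.0 + rng.gamma(1, 1, 30)
        Y_a = np.column_stack([col_a, col_a])
        Y_b = np.column_stack([col_b, col_b])
        table = screen_genes(Y_a, t_a, Y_b, t_b, gene_ids=["zz", "aa"],
                             n_perm=39, seed=10, p_threshold=1.0)
        ranked = table.sort_values("rank")
        assert list(ranked["gene_id"]) == ["aa", "zz"]

    def test_estimator_exposes_profiles_and_params(self):
        Y_a, t_a, Y_b, t_b = self.make_data()
        est = MatrixResponsivenessScreen(n_perm=19, seed=11).fit(Y_a, t_a, Y_b, t_b)
        assert est.profiles_sa_.values.shape == (30, est.T)
        assert est.params_["n_perm"] == 19
        assert len(est.top_table_) <= est.top_n
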