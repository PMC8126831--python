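import numpy as np
import pytest

from mscfate import SimSpec, build_mean_profiles, generate_study
from mscfate.simulate import SimSpecError


def test_spec_validation_rejects_bad_values():
    for kwargs in (
        dict(n_genes=0),
        dict(t_branch=0.0),
        dict(t_branch=1.0),
        dict(effect_size=0.5),
        dict(dispersion=0.0),
        dict(gene_class_counts={"nonsense": 5}),
        dict(gene_class_counts={"housekeeping": 10**6}),
        dict(n_cells_per_state={"D0": 10}),
    ):
        with pytest.raises(SimSpecError):
            SimSpec(**kwargs).validate()


def test_housekeeping_mean_is_constant_everywhere(small_spec):
    mu = build_mean_profiles(small_spec)
    hk = np.flatnonzero(mu.gene_classes == "housekeeping")
    t = np.array([0.0, 0.2, 0.5, 0.9, 1.0])
    out = [
        mu(t, [cond] * 5, [branch] * 5)[:, hk]
        for cond in ("PS", "soft", "stiff")
        for branch in ("trunk", "differentiated", "nondifferentiated")
    ]
    for block in out[1:]:
        np.testing.assert_allclose(block, out[0])
    np.testing.assert_allclose(out[0], np.broadcast_to(mu.baselines[hk], (5, hk.size)))


def test_neutral_effect_size_gives_identical_soft_stiff_profiles():
    spec = SimSpec(seed=3).with_panel_size(300).with_(
        effect_size=1.0, marker_effect_size=1.0, program_effect_size=1.0)
    mu = build_mean_profiles(spec)
    t = np.linspace(0, 1, 7)
    for branch in ("trunk", "differentiated", "nondifferentiated"):
        soft = mu(t, ["soft"] * 7, [branch] * 7)
        stiff = mu(t, ["stiff"] * 7, [branch] * 7)
        np.testing.assert_allclose(soft, stiff)


def test_mr_gene_endpoint_ratio_matches_effect_size(small_spec):
    """At t = 1 a stiff-responsive gene's differentiated-branch mean is
    effect_size x baseline on stiff and exactly baseline on soft
    (e.g. baseline 2, effect 3 -> means 6 vs 2)."""
    mu = build_mean_profiles(small_spec)
    mrs = np.flatnonzero(mu.gene_classes == "mr_stiff_up")
    stiff = mu([1.0], ["stiff"], ["differentiated"])[0, mrs]
    soft = mu([1.0], ["soft"], ["differentiated"])[0, mrs]
    np.testing.assert_allclose(soft, mu.baselines[mrs])
    np.testing.assert_allclose(stiff, small_spec.effect_size * mu.baselines[mrs])
    np.testing.assert_allclose(stiff, small_spec.effect_size * soft)


def test_soft_stiff_class_symmetry(small_spec):
    """Swapping soft<->stiff labels and the two responsive classes gives the
    same multiplier programs (the design has no built-in matrix bias)."""
    mu = build_mean_profiles(small_spec)
    mrs = np.flatnonzero(mu.gene_classes == "mr_stiff_up")
    mrf = np.flatnonzero(mu.gene_classes == "mr_soft_up")
    t = np.linspace(0, 1, 9)
    for branch in ("trunk", "differentiated", "nondifferentiated"):
        m_stiff = mu(t, ["stiff"] * 9, [branch] * 9) / mu.baselines
        m_soft = mu(t, ["soft"] * 9, [branch] * 9) / mu.baselines
        np.testing.assert_allclose(m_stiff[:, mrs], m_soft[:, mrf])
        np.testing.assert_allclose(m_stiff[:, mrf], m_soft[:, mrs])


def test_generate_study_is_deterministic(small_spec):
    m1, c1, t1 = generate_study(small_spec)
    m2, c2, t2 = generate_study(small_spec)
    assert (m1.values != m2.values).nnz == 0
    assert c1.equals(c2)
    assert t1.cells.equals(t2.cells) and t1.genes.equals(t2.genes)


def test_ground_truth_is_complete_and_consistent(small_spec, small_study):
    matrix, cell_table, truth = small_study
    assert list(truth.cells["cell_id"]) == matrix.cell_ids
    assert list(truth.genes["gene_id"]) == matrix.gene_ids
    pre_branch = truth.cells["true_t"] < small_spec.t_branch
    assert (truth.cells.loc[pre_branch, "true_branch"] == "trunk").all()
    assert set(truth.cells["subpopulation"]) == {
        "D0PS", "D3Soft", "D3Stiff", "D3Cyc", "D6Cyc",
        "D6SoftAD", "D6SoftNA", "D6StiffOS", "D6StiffNO",
    }
    counts = truth.genes["gene_class"].value_counts().to_dict()
    for cls, n in small_spec.gene_class_counts.items():
        assert counts.get(cls, 0) == n


def test_extreme_dropout_parameters_add_no_zeros(small_spec):
    """With the dropout midpoint far below every log-mean and a steep slope,
    the thinning probability vanishes and counts equal the pure NB draw."""
    spec = small_spec.with_(dropout_midpoint=-60.0, dropout_slope=40.0)
    with_do, _, _ = generate_study(spec, dropout=True)
    without, _, _ = generate_study(spec, dropout=False)
    assert (with_do.values != without.values).nnz == 0


def test_detected_genes_per_cell_near_scaled_target():
    """Mean detected genes per cell lands within +-30% of the panel-scaled
    detection target (19% of genes, from ~3,800 expressed of ~20,000)."""
    spec = SimSpec(n_cells_per_state={"D0": 100, "D3soft": 100, "D3stiff": 100,
                                      "D6soft": 100, "D6stiff": 100}, seed=5)
    matrix, _, _ = generate_study(spec)
    det = np.asarray((matrix.to_cells_by_genes() > 0).sum(axis=1)).ravel()
    target = 0.19 * spec.n_genes
    assert 0.7 * target <= det.mean() <= 1.3 * target


def test_counts_match_negative_binomial_moments():
    """Pre-dropout counts at a fixed cell state follow NB moments
    (var = mu + dispersion * mu^2) within sampling error."""
    spec = SimSpec(
        n_genes=120,
        gene_class_counts={},  # all housekeeping: mean independent of t
        n_cells_per_state={"D0": 600, "D3soft": 600, "D3stiff": 600,
                           "D6soft": 600, "D6stiff": 600},
        libsize_log_params=(0.0, 0.0),
        seed=9,
    )
    matrix, _, _ = generate_study(spec, dropout=False)
    mu_fn = build_mean_profiles(spec)
    X = np.asarray(matrix.to_cells_by_genes().todense(), dtype=float)
    n = X.shape[0]
    mean, var = X.mean(axis=0), X.var(axis=0)
    mu = mu_fn.baselines
    expected_var = mu + spec.dispersion * mu**2
    # standard errors: SE(mean) = sd/sqrt(n); SE(var) ~ sqrt((m4 - var^2)/n)
    se_mean = np.sqrt(expected_var / n)
    m4 = ((X - mean) ** 4).mean(axis=0)
    se_var = np.sqrt(np.maximum(m4 - var**2, 0) / n)
    ok_mean = np.abs(mean - mu) <= 3 * se_mean
    ok_var = np.abs(var - expected_var) <= 3 * se_var + 1e-9
    # 3-sigma bands: expect ~99.7% coverage, allow a small miss fraction
    assert ok_mean.mean() >= 0.95
    assert ok_var.mean() >= 0.95
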