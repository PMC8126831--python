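import numpy as np
import pandas as pd
import pytest

from mscfate import PipelineConfig, SimSpec, generate_study, normalize_log
from mscfate.pipeline import run_pipeline, simulate_study

SMALL_CELLS = {"D0": 80, "D3soft": 90, "D3stiff": 85, "D6soft": 100, "D6stiff": 150}


SMALL_CLASSES = {
    "mr_stiff_up": 8, "mr_soft_up": 8, "adipo": 25, "osteo": 25,
    "endochon": 25, "oxphos": 25, "progenitor": 25, "cycling": 30,
    "conditioning": 50, "induction": 50,
}


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down study for fast unit tests (same structure, fewer cells/genes)."""
    return SimSpec(n_genes=400, n_cells_per_state=dict(SMALL_CELLS),
                   gene_class_counts=dict(SMALL_CLASSES), seed=11)


@pytest.fixture(scope="session")
def small_study(small_spec):
    matrix, cell_table, truth = generate_study(small_spec)
    return matrix, cell_table, truth


@pytest.fixture(scope="session")
def small_norm(small_study):
    matrix, _, _ = small_study
    return normalize_log(matrix.to_cells_by_genes())


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_spec):
    d = tmp_path_factory.mktemp("small_study")
    simulate_study(d, small_spec)
    return d


@pytest.fixture(scope="session")
def small_config(small_study_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_out")
    return PipelineConfig(
        indir=str(small_study_dir), outdir=str(out),
        n_hvg=250, n_pcs=20, knn=15, tree_nodes=20,
        n_permutations=120, kmeans_n_init=20, seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The study at its default design scale with the full default pipeline.

    Shared by the trajectory-fidelity, branch-recovery and screen-recovery
    checks so the expensive run happens once.
    """
    study = tmp_path_factory.mktemp("default_study")
    out = tmp_path_factory.mktemp("default_out")
    simulate_study(study, SimSpec(seed=0))
    runner = run_pipeline(PipelineConfig(indir=str(study), outdir=str(out), seed=0))
    truth_cells = pd.read_csv(study / "ground_truth_cells.tsv", sep="\t")
    truth_genes = pd.read_csv(study / "ground_truth_genes.tsv", sep="\t")
    return runner, truth_cells, truth_genes


def branch_accuracy(runner, truth_cells, cond, tags):
    """Fraction of the condition's post-bifurcation cells whose branch tag
    matches the ground-truth fate."""
    sub = truth_cells.merge(runner.pseudotime_tables[cond], on="cell_id")
    post = sub[(sub["matrix"] == cond) & (sub["true_branch"] != "trunk")]
    pred = np.where(
        post["branch_tag"] == tags[0], "differentiated",
        np.where(post["branch_tag"] == tags[1], "nondifferentiated", "trunk"),
    )
    return float((pred == post["true_branch"]).mean())
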