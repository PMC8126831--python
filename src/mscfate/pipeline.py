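"""End-to-end pipeline: counts in, cluster/DE/pseudotime/MR tables out.

Stages run in the order of the underlying analysis: normalization and PCA,
k-means subpopulations, differential expression, per-condition diffusion
pseudotime with an elastic principal tree (soft and stiff maps each share
the day-0 cells), trajectory profiles along the SoftAD and StiffOS
projections, and the permutation-gated matrix-responsiveness screen.
A run manifest records the configuration, seed, completed stages and
SHA-256 checksums of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import KMeansSubpopulations, cluster_summary, signature_score
from .config import PipelineConfig
from .de import rank_sum_de
from .io import read_cell_table, read_counts
from .preprocess import normalize_log, standard_embedding
from .screen import MatrixResponsivenessScreen
from .simulate import SimSpec, generate_study, write_study
from .trajectory import (
    DiffusionMap,
    ElasticPrincipalTree,
    assign_branches,
    diffusion_pseudotime,
    rescale_rank,
    select_root,
    select_tips,
    smooth_profiles,
)

logger = logging.getLogger("mscfate")

STAGES = ("preprocess", "cluster", "de", "pseudotime", "profiles", "mr_screen")

# which signature tags each condition's bifurcation (high-score branch first)
_BRANCH_TAGS = {
    "soft": ("adipogenic", "AD", "NA"),
    "stiff": ("osteogenic", "OS", "NO"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("pca", "kmeans", "tree", "screen")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRunner:
    """Runs the analysis stages on one study, holding shared state in memory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = _stage_seeds(config.seed)
        self.outputs: dict[str, Path] = {}
        self.completed: list[str] = []
        self._load()

    # -- input ------------------------------------------------------------
    def _load(self) -> None:
        cfg = self.config
        indir = Path(cfg.indir)
        self.counts = read_counts(indir / "counts", "mtx_dir")
        cells = read_cell_table(indir / "cells.tsv")
        order = {c: i for i, c in enumerate(self.counts.cell_ids)}
        missing = set(self.counts.cell_ids) ^ set(cells["cell_id"])
        if missing:
            raise ValueError(f"cell ids disagree between counts and cell table: {sorted(missing)[:5]}")
        self.cells = cells.sort_values("cell_id", key=lambda s: s.map(order)).reset_index(drop=True)
        self.gene_ids = np.asarray(self.counts.gene_ids, dtype=object)

        sigdir = Path(cfg.signatures_dir) if cfg.signatures_dir else indir / "signatures"
        self.signatures: dict[str, list[str]] = {}
        if sigdir.is_dir():
            for f in sorted(sigdir.glob("*.tsv")):
                genes = [g for g in f.read_text().split() if g]
                if genes:
                    self.signatures[f.stem] = genes

        X = self.counts.to_cells_by_genes()
        if cfg.min_genes or cfg.min_cells:
            detected = np.asarray((X > 0).sum(axis=1)).ravel()
            keep_cells = detected >= cfg.min_genes
            per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
            keep_genes = per_gene >= cfg.min_cells
            X = X[keep_cells][:, keep_genes]
            self.cells = self.cells.loc[keep_cells].reset_index(drop=True)
            self.gene_ids = self.gene_ids[keep_genes]
            logger.info("QC kept %d cells, %d genes", keep_cells.sum(), keep_genes.sum())
        self._raw = X

    def _write(self, name: str, df: pd.DataFrame, subdir: str | None = None) -> None:
        d = self.outdir / subdir if subdir else self.outdir
        d.mkdir(parents=True, exist_ok=True)
        path = d / name
        df.to_csv(path, sep="\t", index=False)
        self.outputs[str(path.relative_to(self.outdir))] = path

    def _timed(self, stage, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            fn()
        except Exception as exc:
            self._write_manifest(partial=True)
            raise PipelineError(stage, exc) from exc
        self.completed.append(stage)
        logger.info("stage %s: done in %.1fs", stage, time.perf_counter() - t0)

    # -- stages -----------------------------------------------------------
    def preprocess(self) -> None:
        cfg = self.config
        self.norm = normalize_log(self._raw, scale=cfg.scale)
        totals = np.asarray(self._raw.sum(axis=1)).ravel()
        self.embedding, self.hvg_idx, pca = standard_embedding(
            self.norm, self.gene_ids, totals=totals,
            n_hvg=cfg.n_hvg, n_pcs=cfg.n_pcs, seed=self.seeds["pca"],
        )
        self.explained_ = pca.explained_variance_ratio_
        self._write("hvg.tsv", pd.DataFrame({"gene_id": self.gene_ids[self.hvg_idx]}))
        emb = pd.DataFrame(self.embedding, columns=[f"PC{i+1}" for i in range(cfg.n_pcs)])
        emb.insert(0, "cell_id", self.cells["cell_id"])
        self._write("embedding.tsv", emb)

    def cluster(self) -> None:
        cfg = self.config
        km = KMeansSubpopulations(k=cfg.k_clusters, n_init=cfg.kmeans_n_init,
                                  seed=self.seeds["kmeans"])
        self.labels = km.fit_predict(self.embedding)
        self.scores = {}
        for name, genes in self.signatures.items():
            try:
                self.scores[name], _ = signature_score(self.norm, self.gene_ids, genes)
            except ValueError:
                logger.warning("signature %s has no genes in the matrix; skipped", name)
        self._write("clusters.tsv", pd.DataFrame(
            {"cell_id": self.cells["cell_id"], "cluster": self.labels}))
        self._write("cluster_summary.tsv",
                    cluster_summary(self.labels, self.cells, self.scores))

    def de(self) -> None:
        for c in sorted(np.unique(self.labels)):
            in_c = np.flatnonzero(self.labels == c)
            rest = np.flatnonzero(self.labels != c)
            table = rank_sum_de(self.norm, self.gene_ids, in_c, rest)
            self._write(f"cluster{c}_vs_rest.tsv", table, subdir="de")

    def pseudotime(self) -> None:
        cfg = self.config
        self.maps: dict[str, dict] = {}
        tables = {}
        for cond in ("soft", "stiff"):
            mask = (self.cells["matrix"] == "PS") | (self.cells["matrix"] == cond)
            idx = np.flatnonzero(mask.to_numpy())
            sub_emb = self.embedding[idx]
            dmap = DiffusionMap(knn=cfg.knn, n_comps=cfg.n_diffusion_comps).fit(sub_emb)
            is_d0 = (self.cells["day"].to_numpy()[idx] == "D0")
            root = select_root(sub_emb, is_d0)
            t = diffusion_pseudotime(dmap, root)
            is_d6 = (self.cells["day"].to_numpy()[idx] == "D6")
            tip1, tip2 = select_tips(dmap, root, is_d6)
            coords = dmap.dpt_coords()
            tree = ElasticPrincipalTree(
                n_nodes=cfg.tree_nodes, lambda_stretch=cfg.lambda_stretch,
                mu_bend=cfg.mu_bend, max_iter=cfg.tree_max_iter,
                seed=self.seeds["tree"],
            ).fit(coords, root, [tip1, tip2])
            signame, tag_high, tag_low = _BRANCH_TAGS[cond]
            if signame not in self.scores:
                raise ValueError(f"missing signature {signame!r} needed to tag {cond} branches")
            assignment = assign_branches(
                tree, t, self.scores[signame][idx], tag_high, tag_low)
            table = assignment.table.copy()
            table.insert(0, "cell_id", self.cells["cell_id"].to_numpy()[idx])
            table.insert(1, "condition", cond)
            tables[cond] = table
            self.maps[cond] = {"idx": idx, "dmap": dmap, "root": root, "tree": tree,
                               "t": t, "assignment": table}
            self._write(f"pseudotime_{cond}.tsv", table)
        self.pseudotime_tables = tables

    def _projection(self, cond: str, tag: str):
        m = self.maps[cond]
        table = m["assignment"]
        sel = table["branch_tag"].isin(["trunk", tag]).to_numpy()
        idx = m["idx"][sel]
        t = rescale_rank(m["t"][sel])
        return idx, t

    def profiles(self) -> None:
        cfg = self.config
        self.projections = {}
        for cond, tag in (("soft", "AD"), ("stiff", "OS")):
            idx, t = self._projection(cond, tag)
            name = f"{cond.capitalize()}{tag}"
            self.projections[name] = (idx, t)
            # profiles and the MR score use linear-scale intensities
            # (counts per `scale` library size): the enclosed-area score is
            # then fold-change-driven, not compressed by the log transform
            prof = smooth_profiles(np.expm1(self.norm[idx]), t,
                                   T=cfg.grid_size, h=cfg.bandwidth, tag=name)
            wide = pd.DataFrame(prof.values,
                                columns=[f"t{v:.4f}" for v in prof.grid])
            wide.insert(0, "gene_id", self.gene_ids)
            self._write(f"profiles_{name}.tsv", wide)

    def mr_screen(self) -> None:
        cfg = self.config
        (idx_sa, t_sa) = self.projections["SoftAD"]
        (idx_so, t_so) = self.projections["StiffOS"]
        screen = MatrixResponsivenessScreen(
            T=cfg.grid_size, h=cfg.bandwidth, n_perm=cfg.n_permutations,
            p_threshold=cfg.p_threshold, top_n=cfg.top_n, seed=self.seeds["screen"],
        ).fit(np.expm1(self.norm[idx_sa]), t_sa,
              np.expm1(self.norm[idx_so]), t_so, gene_ids=self.gene_ids)
        self.mr_table = screen.mr_table_
        self._write("mr_table.tsv", screen.mr_table_)
        self._write(f"mr_top{cfg.top_n}.tsv", screen.top_table_)
        params = self.outdir / "mr_params.json"
        params.write_text(json.dumps(screen.params_, indent=2) + "\n")
        self.outputs["mr_params.json"] = params

    # -- orchestration ----------------------------------------------------
    def run(self, stages=STAGES) -> None:
        for stage in stages:
            self._timed(stage, getattr(self, stage))
        self._write_manifest(partial=False)

    def _write_manifest(self, partial: bool) -> None:
        manifest = {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "stage_seeds": self.seeds,
            "completed_stages": list(self.completed),
            "partial": partial,
            "checksums": {name: _sha256(p) for name, p in sorted(self.outputs.items())},
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineRunner:
    """Run every stage; returns the runner with all results in memory."""
    runner = PipelineRunner(config)
    runner.run()
    return runner


def simulate_study(outdir: str | Path, spec: SimSpec | None = None) -> SimSpec:
    """Generate the default synthetic study under ``outdir`` (counts,
    cell table, ground truth, signature lists)."""
    spec = spec or SimSpec()
    matrix, cell_table, truth = generate_study(spec)
    write_study(outdir, matrix, cell_table, truth)
    return spec
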