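"""Pipeline configuration: defaults, validation, YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their defaults.

    Paths: ``indir`` must contain ``counts/`` (Matrix Market directory) and
    ``cells.tsv``; signature gene lists (one id per line) live in
    ``indir/signatures/`` unless ``signatures_dir`` overrides it.
    """

    indir: str = "study"
    outdir: str = "results"
    signatures_dir: str | None = None

    scale: float = 1e4            # library-size normalization target
    n_hvg: int = 1000
    n_pcs: int = 30
    k_clusters: int = 9
    kmeans_n_init: int = 50
    knn: int = 30                 # diffusion-map neighborhood
    n_diffusion_comps: int = 10
    tree_nodes: int = 30
    lambda_stretch: float = 0.01
    mu_bend: float = 0.1
    tree_max_iter: int = 100
    grid_size: int = 50           # T: pseudotime grid points
    bandwidth: float = 0.1        # h: kernel bandwidth on the unit grid
    n_permutations: int = 1000
    p_threshold: float = 0.01     # permutation gate
    top_n: int = 100              # size of the ranked extract
    min_genes: int = 0            # optional QC: drop cells detecting fewer genes
    min_cells: int = 0            # optional QC: drop genes detected in fewer cells
    seed: int = 0

    _RANGES = {
        "scale": (0.0, None, True),
        "n_hvg": (1, None, False),
        "n_pcs": (1, None, False),
        "k_clusters": (1, None, False),
        "kmeans_n_init": (1, None, False),
        "knn": (1, None, False),
        "n_diffusion_comps": (1, None, False),
        "tree_nodes": (4, None, False),
        "lambda_stretch": (0.0, None, False),
        "mu_bend": (0.0, None, False),
        "tree_max_iter": (1, None, False),
        "grid_size": (2, None, False),
        "bandwidth": (0.0, None, True),
        "n_permutations": (1, None, False),
        "p_threshold": (0.0, 1.0, False),
        "top_n": (1, None, False),
        "min_genes": (0, None, False),
        "min_cells": (0, None, False),
    }

    def __post_init__(self):
        for name, (lo, hi, strict) in self._RANGES.items():
            v = getattr(self, name)
            ok = (v > lo) if strict else (v >= lo)
            if hi is not None:
                ok = ok and v <= hi
            if not ok:
                bound = f"> {lo}" if strict else f">= {lo}"
                if hi is not None:
                    bound += f" and <= {hi}"
                raise ConfigError(f"{name} must be {bound}, got {v!r}")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected, overrides win."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config {path} must be a mapping")
        unknown = set(doc) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
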