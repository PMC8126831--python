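"""Synthetic single-cell study generator.

Emulates a matrix-elasticity fate-decision experiment: mesenchymal stromal
cells (MSCs) are profiled non-conditioned (day 0, polystyrene), after three
days of conditioning on soft (2 kPa) or stiff (25 kPa) hydrogel, and after
three further days in bipotential adipo-/osteogenic induction medium
(day 6).  Each cell carries a latent progression time ``t`` in [0, 1]; past
the bifurcation time ``t_branch`` a cell commits to a differentiated or a
non-differentiated fate.  Gene expression means follow class-specific
multiplier programs on top of a log-normal baseline; counts are negative
binomial with logistic dropout.

Gene classes
------------
housekeeping   constant baseline, no (t, matrix, branch) dependence.
mr_stiff_up    matrix-responsive: on stiff matrix the mean ramps up to
               ``effect_size`` x baseline during conditioning, stays high on
               the differentiated branch and relaxes back to baseline on the
               non-differentiated branch (impaired responsiveness).
mr_soft_up     mirror image on soft matrix.
adipo          late program on the (soft, differentiated) branch.
osteo          late program on the (stiff, differentiated) branch.
endochon       endochondral ossification, (soft, non-differentiated) branch.
oxphos         oxidative-phosphorylation metabolic shift shared by both
               differentiated branches (adipogenic and osteogenic); equal in
               the two cross-matrix projections, so it carries no
               matrix-responsiveness signal.
progenitor     maintenance program retained by cells that do not commit
               (elevated on both matrices' non-differentiated branches);
               like oxphos it never differs between the two projections.
cycling        cell-level program: elevated in randomly chosen cycling cells.
conditioning   culture-adaptation and conditioning response: half the genes
               are matrix-independent (acute shared ramp or staggered
               on/off cascade), the other half respond transiently to one
               matrix (up during conditioning, decaying after the medium
               switch).
induction      response to the differentiation-medium switch: half acute at
               the bifurcation, half staggered across the induction phase;
               matrix- and branch-independent.

All ground truth (true t, branch, subpopulation, gene class) is returned so
downstream inference can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_counts

__all__ = ["SimSpec", "GroundTruth", "build_mean_profiles", "generate_study", "write_study"]

STATES = ("D0", "D3soft", "D3stiff", "D6soft", "D6stiff")
GENE_CLASSES = (
    "housekeeping",
    "mr_stiff_up",
    "mr_soft_up",
    "adipo",
    "osteo",
    "endochon",
    "oxphos",
    "progenitor",
    "cycling",
    "conditioning",
    "induction",
)

# fixed design constants of the emulated protocol (fractions of total t-range)
T_SEED = 0.10        # cells attach to the matrix / conditioning response starts
T_COND_END = 0.20    # conditioning program fully established
T_MR_START = 0.15    # matrix-responsive divergence starts (start of D3 window)
T_MR_FULL = 0.30     # matrix responses are fast: fully established early in D3
D0_WINDOW = (0.0, 0.10)
D3_START = 0.15
D6_MARGIN = 0.10     # day-6 cells have progressed past the bifurcation
INDUCTION_RAMP = 0.15

_CLASS_PREFIX = {
    "housekeeping": "HK",
    "mr_stiff_up": "MRS",
    "mr_soft_up": "MRF",
    "adipo": "ADI",
    "osteo": "OST",
    "endochon": "END",
    "oxphos": "OXP",
    "progenitor": "PRG",
    "cycling": "CYC",
    "conditioning": "CND",
    "induction": "IND",
}


class SimSpecError(ValueError):
    """Raised when a simulation specification violates its invariants."""


def _default_cells() -> dict[str, int]:
    # cell numbers of the emulated study design
    return {"D0": 388, "D3soft": 467, "D3stiff": 450, "D6soft": 534, "D6stiff": 951}


def _default_classes() -> dict[str, int]:
    return {
        "mr_stiff_up": 25,
        "mr_soft_up": 25,
        "adipo": 80,
        "osteo": 80,
        "endochon": 80,
        "oxphos": 80,
        "progenitor": 80,
        "cycling": 80,
        "conditioning": 150,
        "induction": 150,
    }


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study.

    Defaults reproduce the emulated design: ~2,790 cells across five
    harvest states, 2,000 genes of which 50 are planted matrix-responsive,
    three-fold programs, and count noise calibrated so that a cell detects
    roughly 19% of the panel (the study's ~3,800 expressed genes per cell
    on a ~20,000-gene transcriptome, scaled to panel size).
    """

    n_genes: int = 2000
    n_cells_per_state: dict[str, int] = field(default_factory=_default_cells)
    t_branch: float = 0.5
    gene_class_counts: dict[str, int] = field(default_factory=_default_classes)
    effect_size: float = 3.0
    marker_effect_size: float = 3.0
    program_effect_size: float = 5.0
    discrete_states: bool = False
    base_mean_log_params: tuple[float, float] = (float(np.log(0.2)), 1.2)
    dispersion: float = 0.5
    dropout_midpoint: float = -2.0
    dropout_slope: float = 1.0
    libsize_log_params: tuple[float, float] = (0.0, 0.3)
    p_differentiated: float = 0.5
    cycling_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimSpecError("n_genes must be positive")
        if set(self.n_cells_per_state) != set(STATES):
            raise SimSpecError(f"n_cells_per_state must have keys {STATES}")
        if any(n <= 0 for n in self.n_cells_per_state.values()):
            raise SimSpecError("all cell counts must be positive")
        unknown = set(self.gene_class_counts) - set(GENE_CLASSES)
        if unknown:
            raise SimSpecError(f"unknown gene classes: {sorted(unknown)}")
        if any(n < 0 for n in self.gene_class_counts.values()):
            raise SimSpecError("gene class counts must be non-negative")
        if sum(self.gene_class_counts.values()) > self.n_genes:
            raise SimSpecError("gene class counts exceed n_genes")
        if not 0.0 < self.t_branch < 1.0:
            raise SimSpecError("t_branch must lie strictly inside (0, 1)")
        if self.effect_size < 1.0:
            raise SimSpecError("effect_size must be >= 1")
        if self.marker_effect_size < 1.0:
            raise SimSpecError("marker_effect_size must be >= 1")
        if self.program_effect_size < 1.0:
            raise SimSpecError("program_effect_size must be >= 1")
        if self.dispersion <= 0:
            raise SimSpecError("dispersion must be positive")
        if not 0.0 <= self.p_differentiated <= 1.0:
            raise SimSpecError("p_differentiated must lie in [0, 1]")
        if not 0.0 <= self.cycling_fraction < 1.0:
            raise SimSpecError("cycling_fraction must lie in [0, 1)")
        if self.t_branch + D6_MARGIN >= 1.0:
            raise SimSpecError("t_branch too late: no room for the day-6 window")

    def with_(self, **kwargs) -> "SimSpec":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def with_panel_size(self, n_genes: int) -> "SimSpec":
        """Copy with a different gene panel, class counts scaled in
        proportion (at least one gene per originally non-empty class)."""
        if n_genes <= 0:
            raise SimSpecError("n_genes must be positive")
        factor = n_genes / self.n_genes
        counts = {
            cls: max(1, round(n * factor))
            for cls, n in self.gene_class_counts.items()
            if n > 0
        }
        while sum(counts.values()) > n_genes:
            biggest = max(counts, key=counts.get)
            counts[biggest] -= 1
        return replace(self, n_genes=n_genes, gene_class_counts=counts)


@dataclass
class GroundTruth:
    """Latent truth of a simulated study: one record per cell and per gene."""

    cells: pd.DataFrame  # cell_id, condition, true_t, true_branch, is_cycling, subpopulation
    genes: pd.DataFrame  # gene_id, gene_class (the mean-profile identifier)

    def gene_set(self, gene_class: str) -> list[str]:
        m = self.genes["gene_class"] == gene_class
        return self.genes.loc[m, "gene_id"].tolist()


def _ramp(t: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Piecewise-linear ramp from 0 at ``start`` to 1 at ``stop``."""
    return np.clip((t - start) / (stop - start), 0.0, 1.0)


def _gene_classes(spec: SimSpec) -> np.ndarray:
    classes: list[str] = []
    for name in GENE_CLASSES:
        if name == "housekeeping":
            continue
        classes.extend([name] * spec.gene_class_counts.get(name, 0))
    classes.extend(["housekeeping"] * (spec.n_genes - len(classes)))
    return np.asarray(classes, dtype=object)


_MARKER_GATE = {
    "adipo": ("soft", "differentiated"),
    "osteo": ("stiff", "differentiated"),
    "endochon": ("soft", "nondifferentiated"),
    "oxphos": (None, "differentiated"),  # both matrices: shared metabolic shift
    "progenitor": (None, "nondifferentiated"),  # both matrices: uncommitted cells
}


def _gene_windows(spec: SimSpec, classes: np.ndarray, rng: np.random.Generator):
    """Per-gene ramp window [a, b], direction (+1 up, -1 down), and the
    matrix a conditioning gene responds to ("" = matrix-independent).

    Matrix-independent conditioning and induction genes form activation
    cascades: half of each group responds acutely (shared fast window),
    the rest switch on or off in staggered windows across their phase —
    the continuous backdrop a progressing transcriptome shows.  The other
    half of the conditioning class responds transiently to one matrix
    (soft or stiff), decaying after the switch to induction medium.
    Marker genes stagger their onset along the post-bifurcation branch.
    """
    n = classes.size
    tb = spec.t_branch
    a = np.zeros(n)
    b = np.ones(n)
    direction = np.ones(n)
    cond_matrix = np.full(n, "", dtype=object)

    cond = np.flatnonzero(classes == "conditioning")
    shared, soft_sp, stiff_sp = np.array_split(cond, [cond.size // 2,
                                                      cond.size // 2 + cond.size // 4])
    cond_matrix[soft_sp] = "soft"
    cond_matrix[stiff_sp] = "stiff"
    ind = np.flatnonzero(classes == "induction")
    for cols, (acute, phase_lo, phase_hi) in (
        (shared, ((T_SEED, T_COND_END), 0.05, 0.45)),
        (ind, ((tb, tb + INDUCTION_RAMP), tb, 0.75)),
    ):
        half = cols.size // 2
        a[cols[:half]], b[cols[:half]] = acute
        starts = rng.uniform(phase_lo, phase_hi, size=cols.size - half)
        a[cols[half:]] = starts
        b[cols[half:]] = np.minimum(starts + 0.25, 1.0)
        direction[cols[half:]] = rng.choice([1.0, -1.0], size=cols.size - half)
    for cls in _MARKER_GATE:
        cols = np.flatnonzero(classes == cls)
        starts = rng.uniform(tb, 0.7, size=cols.size)
        a[cols] = starts
        b[cols] = np.minimum(starts + 0.3, 1.0)
    return a, b, direction, cond_matrix


def build_mean_profiles(spec: SimSpec) -> Callable:
    """Return the per-gene mean function ``mu(t, condition, branch, cycling)``.

    The returned callable evaluates mean expression for all genes at a set of
    cells: given arrays ``t`` (progression), ``condition`` (``PS``/``soft``/
    ``stiff``), ``branch`` (``trunk``/``differentiated``/``nondifferentiated``)
    and optional boolean ``is_cycling``, it returns a (n_cells, n_genes)
    matrix of non-negative means.  Baselines and cascade windows are drawn
    once from the spec's seed, so the function is deterministic.

    Matrix-responsive genes ramp from baseline to ``effect_size`` x baseline
    on their matrix over the conditioning phase, hold that level on the
    differentiated branch and relax back to baseline on the
    non-differentiated branch, so
    ``mu(t, stiff, differentiated) = effect_size * mu(t, soft, differentiated)``
    for every t past the bifurcation (and symmetrically for mr_soft_up).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 101)))
    loc, scale = spec.base_mean_log_params
    baselines = rng.lognormal(mean=loc, sigma=scale, size=spec.n_genes)
    classes = _gene_classes(spec)
    # responsive genes are drawn from the expressed (upper) half of the
    # baseline distribution: a screen can only rank genes it can detect,
    # and the biology they emulate (cytoskeletal/ECM regulators) is
    # robustly expressed
    mr_cols = np.flatnonzero((classes == "mr_stiff_up") | (classes == "mr_soft_up"))
    from scipy.stats import norm as _norm

    u = rng.uniform(0.5, 1.0, size=mr_cols.size)
    baselines[mr_cols] = np.exp(loc + scale * _norm.ppf(u))
    win_a, win_b, direction, cond_matrix = _gene_windows(spec, classes, rng)
    e = spec.effect_size
    amp = e - 1.0
    tb = spec.t_branch

    def mu(t, condition, branch, is_cycling=None):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        condition = np.atleast_1d(np.asarray(condition, dtype=object))
        branch = np.atleast_1d(np.asarray(branch, dtype=object))
        if is_cycling is None:
            is_cycling = np.zeros(t.shape, dtype=bool)
        is_cycling = np.atleast_1d(np.asarray(is_cycling, dtype=bool))
        out = np.ones((t.size, spec.n_genes))

        # the acute responders to seeding and to the medium switch carry
        # the largest shifts in the experiment (program-level amplitude);
        # the staggered cascade genes are moderate.  Both are matrix- and
        # branch-independent, hence identical in the two projections.
        p_amp = spec.program_effect_size - 1.0
        for cls in ("conditioning", "induction"):
            cols = np.flatnonzero((classes == cls) & (cond_matrix == ""))
            if not cols.size:
                continue
            half = cols.size // 2
            acute, cascade = cols[:half], cols[half:]
            r = _ramp(t[:, None], win_a[acute][None, :], win_b[acute][None, :])
            out[:, acute] = 1.0 + p_amp * r
            r = _ramp(t[:, None], win_a[cascade][None, :], win_b[cascade][None, :])
            up = direction[cascade] > 0
            out[:, cascade[up]] = 1.0 + amp * r[:, up]
            out[:, cascade[~up]] = e - amp * r[:, ~up]

        # transient matrix-specific conditioning response: up on one matrix
        # during conditioning, decaying after the medium switch; moderate
        # amplitude (half the planted responsive genes' effect, the broad
        # tail of the response spectrum); muted in cycling cells like every
        # matrix program
        shape = _ramp(t, T_MR_START, T_MR_FULL) * (1.0 - _ramp(t, tb, tb + 0.2))
        for matrix in ("soft", "stiff"):
            cols = np.flatnonzero((classes == "conditioning") & (cond_matrix == matrix))
            if cols.size:
                gate = (condition == matrix) & ~is_cycling
                out[:, cols] = np.where(gate, 1.0 + 0.5 * amp * shape, 1.0)[:, None]

        # fate markers are induced more strongly than the planted
        # matrix-responsive genes, as terminal differentiation programs are;
        # cycling cells stay progenitor-like and mute fate and matrix
        # programs (they cycle instead of differentiating)
        # adipo/osteo are the cross-matrix fate markers; endochondral and
        # the shared metabolic program are branch-defining but either absent
        # from or equal between the two compared projections
        for cls, (matrix, br) in _MARKER_GATE.items():
            cols = np.flatnonzero(classes == cls)
            if not cols.size:
                continue
            amp_cls = (spec.marker_effect_size if cls in ("adipo", "osteo")
                       else spec.program_effect_size) - 1.0  # non-MR-facing programs
            on = (branch == br) & ~is_cycling
            if matrix is not None:
                on = on & (condition == matrix)
            r = _ramp(t[:, None], win_a[cols][None, :], win_b[cols][None, :])
            out[:, cols] = 1.0 + amp_cls * r * on.astype(float)[:, None]

        for cls, matrix in (("mr_stiff_up", "stiff"), ("mr_soft_up", "soft")):
            cols = np.flatnonzero(classes == cls)
            if not cols.size:
                continue
            up = _ramp(t, T_MR_START, T_MR_FULL)  # fast conditioning response
            decay = 1.0 - _ramp(t, tb, 1.0)  # response lost off-lineage
            level = np.where(branch == "nondifferentiated", up * decay, up)
            m = np.where((condition == matrix) & ~is_cycling, 1.0 + amp * level, 1.0)
            out[:, cols] = m[:, None]

        cyc = np.flatnonzero(classes == "cycling")
        if cyc.size:
            out[:, cyc] = np.where(is_cycling, e, 1.0)[:, None]

        return out * baselines[None, :]

    mu.baselines = baselines
    mu.gene_classes = classes
    mu.windows = (win_a, win_b, direction, cond_matrix)
    return mu


def _sample_cells(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent cell table: state, condition, t, branch, cycling."""
    tb = spec.t_branch
    if spec.discrete_states:
        # subpopulation mode: tight windows at state-characteristic times,
        # so the planted groups are separable blobs rather than a continuum
        d3 = (max(tb - 0.05, D3_START), tb)
        d6 = (0.90, 1.0)
    else:
        d3 = (D3_START, tb)
        d6 = (tb + D6_MARGIN, 1.0)
    windows = {
        "D0": D0_WINDOW if not spec.discrete_states else (0.0, 0.05),
        "D3soft": d3,
        "D3stiff": d3,
        "D6soft": d6,
        "D6stiff": d6,
    }
    rows = []
    for state in STATES:
        n = spec.n_cells_per_state[state]
        lo, hi = windows[state]
        t = rng.uniform(lo, hi, size=n)
        day = {"D0": "D0", "D3soft": "D3", "D3stiff": "D3", "D6soft": "D6", "D6stiff": "D6"}[state]
        if state == "D0":
            condition = "PS"
        else:
            condition = "soft" if "soft" in state else "stiff"
        if day == "D6":
            differentiated = rng.random(n) < spec.p_differentiated
            branch = np.where(differentiated, "differentiated", "nondifferentiated")
        else:
            branch = np.full(n, "trunk", dtype=object)
        cycling = np.zeros(n, dtype=bool)
        if day != "D0":
            cycling = rng.random(n) < spec.cycling_fraction
        for i in range(n):
            rows.append((state, day, condition, t[i], branch[i], bool(cycling[i])))
    df = pd.DataFrame(rows, columns=["state", "day", "matrix", "true_t", "true_branch", "is_cycling"])
    df["cell_id"] = [f"cell{i:05d}" for i in range(len(df))]
    # two technical replicates per harvest state, as in the emulated design
    df["replicate"] = (np.arange(len(df)) % 2) + 1
    return df


def _subpopulation(df: pd.DataFrame) -> pd.Series:
    """Planted subpopulation labels mirroring the nine observed clusters."""
    lab = pd.Series(index=df.index, dtype=object)
    lab[df["day"] == "D0"] = "D0PS"
    d3, d6 = df["day"] == "D3", df["day"] == "D6"
    lab[d3 & (df["matrix"] == "soft")] = "D3Soft"
    lab[d3 & (df["matrix"] == "stiff")] = "D3Stiff"
    lab[d6 & (df["matrix"] == "soft") & (df["true_branch"] == "differentiated")] = "D6SoftAD"
    lab[d6 & (df["matrix"] == "soft") & (df["true_branch"] == "nondifferentiated")] = "D6SoftNA"
    lab[d6 & (df["matrix"] == "stiff") & (df["true_branch"] == "differentiated")] = "D6StiffOS"
    lab[d6 & (df["matrix"] == "stiff") & (df["true_branch"] == "nondifferentiated")] = "D6StiffNO"
    lab[d3 & df["is_cycling"]] = "D3Cyc"
    lab[d6 & df["is_cycling"]] = "D6Cyc"
    return lab


def generate_study(
    spec: SimSpec, *, dropout: bool = True
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one study: counts, cell metadata, and full ground truth.

    Counts are NegativeBinomial(mean = mu * libsize_factor, inverse-size =
    ``dispersion``) thinned by an independent Bernoulli dropout whose
    probability is logistic-decreasing in the log mean.  ``dropout=False``
    skips the thinning (used to check raw NB moments).  Identical specs and
    seeds give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 202)))
    mu_fn = build_mean_profiles(spec)
    cells = _sample_cells(spec, rng)
    cells["subpopulation"] = _subpopulation(cells)

    means = mu_fn(
        cells["true_t"].to_numpy(),
        cells["matrix"].to_numpy(),
        cells["true_branch"].to_numpy(),
        cells["is_cycling"].to_numpy(),
    )
    lib_loc, lib_scale = spec.libsize_log_params
    libsize = rng.lognormal(mean=lib_loc, sigma=lib_scale, size=len(cells))
    means = means * libsize[:, None]

    inv_size = 1.0 / spec.dispersion  # NB "n" parameter
    p = inv_size / (inv_size + means)
    counts = rng.negative_binomial(inv_size, p)
    if dropout:
        logmu = np.log(means)
        with np.errstate(over="ignore"):  # exp overflow saturates to p_drop = 0
            p_drop = 1.0 / (1.0 + np.exp(spec.dropout_slope * (logmu - spec.dropout_midpoint)))
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    gene_ids = _gene_ids(mu_fn.gene_classes)
    matrix = CountMatrix(
        values=sp.csr_matrix(counts.T.astype(np.int64)),  # genes x cells
        gene_ids=gene_ids,
        cell_ids=cells["cell_id"].tolist(),
    )
    cell_table = cells[["cell_id", "day", "matrix", "replicate"]].copy()
    truth = GroundTruth(
        cells=cells[["cell_id", "matrix", "true_t", "true_branch", "is_cycling", "subpopulation"]]
        .rename(columns={"matrix": "condition"})
        .reset_index(drop=True),
        genes=pd.DataFrame({"gene_id": gene_ids, "gene_class": mu_fn.gene_classes}),
    )
    return matrix, cell_table, truth


def _gene_ids(classes: np.ndarray) -> list[str]:
    ids, counters = [], {}
    for c in classes:
        counters[c] = counters.get(c, 0) + 1
        ids.append(f"{_CLASS_PREFIX[str(c)]}{counters[c]:04d}")
    return ids


def write_study(
    outdir: str | Path,
    matrix: CountMatrix,
    cell_table: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    """Write counts (Matrix Market + TSV sidecars), cell table, ground truth
    and per-class signature gene lists under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(outdir / "counts", matrix)
    cell_table.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        merged = cell_table.merge(
            truth.cells[["cell_id", "true_t", "true_branch", "is_cycling", "subpopulation"]],
            on="cell_id",
        )
        merged.to_csv(outdir / "ground_truth_cells.tsv", sep="\t", index=False)
        truth.genes.to_csv(outdir / "ground_truth_genes.tsv", sep="\t", index=False)
        sigdir = outdir / "signatures"
        sigdir.mkdir(exist_ok=True)
        for name, cls in [
            ("adipogenic", "adipo"),
            ("osteogenic", "osteo"),
            ("endochondral", "endochon"),
            ("oxphos", "oxphos"),
            ("cycling", "cycling"),
        ]:
            genes = truth.gene_set(cls)
            (sigdir / f"{name}.tsv").write_text("\n".join(genes) + ("\n" if genes else ""))
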