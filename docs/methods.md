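# Methods

This note documents the models and numerical choices behind `mscfate`: the
synthetic study generator, each analysis stage, and what passing tests on
synthetic data do and do not establish about real data.

## The synthetic study generator

`mscfate.simulate.SimSpec` describes one study. Each cell carries a latent
progression time `t ∈ [0, 1]` sampled uniformly within a day-specific
window (day 0: [0, 0.1]; day 3: [0.15, t_branch]; day 6:
[t_branch + 0.1, 1]); the margin after the bifurcation time
`t_branch = 0.5` reflects that day-6 cells have progressed past
commitment — a cell sampled exactly at the bifurcation has no branch
signal, so its fate label would be unknowable in principle. Day labels
are therefore informative about, but not determined by, `t`. Past
`t_branch`, each day-6 cell commits to a differentiated or a
non-differentiated fate with probability `p_differentiated = 0.5`; 10% of
day-3/6 cells are cycling.

Counts are `NegativeBinomial(mean = μ_g(t, matrix, branch) · libsize,
inverse-size = dispersion)` thinned by an independent Bernoulli dropout
whose probability is logistic-decreasing in the log mean. The baseline
`b_g` is log-normal(ln 0.2, 1.2); library sizes are log-normal(0, 0.3);
dispersion is 0.5 and the dropout midpoint/slope are −2.0/1.0. These noise
parameters were calibrated once, by Monte-Carlo, so that a cell detects
~19% of the gene panel — the study design's ~3,800 expressed genes per
cell on a ~20,000-gene transcriptome, scaled to the 2,000-gene default
panel (~380 detected genes per cell) — and then frozen.

Mean programs are multiplier functions on the baseline, by gene class:

| class | genes | program |
|---|---|---|
| housekeeping | remainder (~1,170) | constant |
| mr_stiff_up / mr_soft_up | 25 + 25 | the planted matrix-responsive genes: on their matrix, ramp from 1× to `effect_size` (3×) early in conditioning (t ∈ [0.15, 0.30]), hold on the differentiated branch, decay back to 1× along the non-differentiated branch (impaired responsiveness off-lineage). Baselines are drawn from the expressed (upper) half of the log-normal: a screen can only rank genes it can detect, and the biology these emulate — cytoskeletal and ECM regulators — is robustly expressed. |
| adipo / osteo | 80 + 80 | fate markers on the (soft, differentiated) and (stiff, differentiated) branches; staggered onsets in [t_branch, 0.7], fold `marker_effect_size` (3×). These are the only branch programs visible to the cross-matrix comparison. |
| endochon | 80 | endochondral-ossification program of the (soft, non-differentiated) branch, fold `program_effect_size` (5×). |
| oxphos | 80 | metabolic (OxPhos) shift shared by both differentiated branches; equal in the two compared projections, hence invisible to the MR score. 5×. |
| progenitor | 80 | maintenance program retained by non-committing cells on both matrices; also MR-invisible. 5×. |
| cycling | 80 | cell-level program of cycling cells (3×). Cycling cells are modeled as progenitor-like: they mute all fate and matrix programs (they cycle instead of differentiating), which is what lets a single day-3 cycling cluster span both matrices. |
| conditioning | 150 | half matrix-independent culture adaptation (an acute cohort at 5× responding to seeding, plus staggered on/off cascade genes at 3×), half *transient* matrix-specific responders at 2× (up during conditioning on one matrix, decaying after the medium switch) — the broad, moderate tail of the matrix-response spectrum. |
| induction | 150 | response to the switch to bipotential induction medium: an acute 5× cohort at the bifurcation plus a staggered 3× on/off cascade; matrix- and branch-independent. |

Two deliberate structural points. First, the backdrop cascades are what
make the data a *trajectory*: without genes switching on and off
throughout `t`, trunk cells would be i.i.d. draws and no pseudotime method
could order them. Second, the class design separates two roles that are
easy to conflate: programs that define branch geometry (endochon, oxphos,
progenitor, the strong state responses) are either absent from or equal
between the SoftAD and StiffOS projections, so the MR ranking is a
competition between the planted persistent responders (3× over most of the
trajectory), the fate markers (3× over the late branch only), and the
transient responders (2×, conditioning only) — with the planted genes on
top by construction, as a screen premised on "matrix-responsive genes
exist" requires.

`discrete_states=True` switches the sampler to tight state-characteristic
windows (day 0 ≈ 0–0.05, day 3 ≈ 0.45–0.5, day 6 ≈ 0.9–1.0) so the nine
labeled groups (D0PS, D3Soft, D3Stiff, D3Cyc, D6SoftAD, D6SoftNA,
D6StiffOS, D6StiffNO, D6Cyc) are separable blobs. This mode defines
"planted subpopulations" for clustering validation; a continuum has no
discrete ground truth to recover.

The generator does not simulate UMI chemistry, ambient RNA, doublets, or
batch effects, and its programs are piecewise-linear in a scalar latent
time. Passing tests on these data show the pipeline recovers structure of
the kind the design assumes — bifurcating lineages, monotone programs,
NB + dropout noise — not that it is robust to artifacts real data add.

## Preprocessing

Normalization is `log(1 + count · scale / cell_total)` (natural log,
`scale` = 10⁴). HVG selection ranks the dispersion (variance/mean) of the
normalized values z-scored within 20 equal-occupancy mean bins; bin
statistics are computed in canonical (mean, gene id) order and the ranking
key is quantized to 9 decimals so the selection is deterministic and
invariant to gene order, with ties broken lexicographically. Zero-variance
genes are never selected while any positive-variance gene remains.

For the embedding, the 1,000 HVGs are scaled to unit variance (clipped at
10 SD) and the per-gene linear component of log library depth is regressed
out before a 30-component full-SVD PCA. Depth regression matters:
detection rate leaks depth into log-normalized sparse data, and without
the correction depth forms a spurious principal axis that splits clusters.
Optional QC (`min_genes`, `min_cells`) is off by default.

## Subpopulations and differential expression

k-means (default k = 9, matching the nine subpopulations of the emulated
design; k stays a configuration parameter) is an explicit Lloyd
loop with k-means++ seeding, best of `n_init = 50` restarts, chosen so the
within-cluster sum of squares can be asserted non-increasing at every
iteration; sklearn's implementation is the independent cross-check in the
tests. Signature scores are means of gene-wise z-scored intensities.
DE uses the two-sided Wilcoxon rank-sum test (exact when both groups have
≤ 8 cells and the gene is tie-free, tie-corrected normal approximation
otherwise), BH adjustment across all tested genes, and the gate
|log2FC| > 1 with adjusted *P* < 10⁻⁵; constant genes get *P* = 1 by
definition. The rank-sum choice is recorded in the run manifest.

## Trajectory inference

Per condition (soft, stiff), the diffusion map is built on that
condition's cells plus the shared day-0 cells: Gaussian kernel
`exp(−d²/(σᵢσⱼ))` on the symmetrized kNN graph (knn = 30) with local
scaling σᵢ = distance to the ⌈knn/2⌉-th neighbor, density normalization by
the row-sum product, row normalization, and eigendecomposition of the
symmetric conjugate; the trivial eigenpair is dropped and the top 10
nontrivial pairs retained. DPT from a root cell is the weighted
eigenvector distance with weights λ/(1−λ). The root is the day-0 medoid;
a disconnected graph is an error naming the component sizes.

The two branch tips are found by partitioning day-6 cells into two arms —
2-means on diffusion coordinates residualized against DPT depth, with
minority clouds (such as cycling cells) iteratively peeled off until the
split is balanced — and taking each arm's deepest cell. Residualization is
essential: raw distances to single extreme cells are dominated by where a
cell sits *along* the trajectory and by that cell's own noise, whereas the
arms separate orthogonally to it.

The elastic principal tree minimizes approximation error plus stretch
(λ = 0.01) and bending (μ = 0.1) penalties over 30 nodes by alternating
nearest-node assignment with the exact linear node update; energy is
asserted non-increasing and convergence is ΔU/U < 10⁻⁶. The Y scaffold is
initialized from anchor geometry — fork at the cell minimizing the summed
distance to root and both tips, trunk = cells no deeper than the fork,
arms from the same residualized 2-means, each segment a depth-binned mean
polyline. Cells inherit the branch of their support node; the fork node
counts as trunk. Each post-fork branch is tagged by the larger
terminal-segment mean of the condition's primary signature (adipogenic on
soft → AD/NA, osteogenic on stiff → OS/NO); an exact tie is an error
prompting explicit tags.

## Profiles and the matrix-responsiveness screen

A projection is the trunk plus one tagged branch, ordered by DPT. Its
pseudotimes are mapped to [0, 1] by their empirical CDF (rank). The
parametrization of the common grid is a genuinely open choice; the rank
map is used because raw DPT distance stretches the fast-moving day-6
segment to most of the axis (expression change per unit time is largest
there), which would weight the enclosed-area score by transcriptional
speed rather than by trajectory coverage. Rank rescaling allocates grid
points uniformly over cells — equivalently, an adaptive kernel bandwidth.

Profiles are Nadaraya–Watson Gaussian-kernel means of the projection
cells' intensities on a uniform grid of T = 50 points with bandwidth
h = 0.1; grid points farther than 3h from every cell copy the nearest
cell's value and are flagged. Profiles and the screen use linear-scale
intensities (counts per 10⁴, i.e. `expm1` of the normalized values): on
the log scale the normalized-difference score is compressed for exactly
the well-expressed genes a screen should find (measured on this
generator, the correlation between log baseline and log-scale MR among
truly responsive genes is −0.9).

The MR score of a gene is `Σₖ |SA_k − SO_k| / (SA_k + SO_k) · Δt` over the
grid (rectangle rule, Δt = 1/(T−1)); grid points where both profiles are
zero contribute 0 ("both absent" is no evidence), making the score
bounded by T·Δt, symmetric, and invariant to common positive rescaling.

The permutation gate shuffles projection labels among the pooled cells —
the cell is the exchangeable unit; grid points are strongly dependent
after smoothing — preserving each cell's (pseudotime, intensity) pair and
the group sizes, and recomputes both profiles and the score per
permutation. `p = (1 + #{MR_perm ≥ MR_obs}) / (n_perm + 1)` with
`n_perm = 1000`; genes with p > 0.01 are discarded, the rest ranked by MR
descending with lexicographic tie-break, and a top-100 extract written.
`screen_genes` shares one permutation set across genes (each permutation's
two kernel-weight matrices score the whole gene matrix at once);
`mr_permutation_p` draws independent permutations per gene. Genes with
all-equal pooled intensities return p = 1 with a degeneracy flag. Note
the gate retains ~1% of null genes by construction, and those survivors
are selected for inflated scores — a few housekeeping or cycling genes
among the retained list is expected behaviour of this published gate, not
a defect.

## Determinism and problem sizes

Every stochastic stage draws its seed from the single run seed via
`numpy.random.SeedSequence`; rerunning a configuration reproduces every
table byte-for-byte, and the manifest records the configuration, stage
seeds and SHA-256 checksums of all outputs. The test suite exercises the
full default design (~2,790 cells × 2,000 genes) once and uses a
~500-cell × 400-gene study for unit and determinism tests; the
acceptance script regenerates the default design from scratch. These
sizes keep a complete run in the low minutes on one CPU while preserving
the study's cell-state proportions.

## Known limitations

- The Y topology is fixed: two tips per condition, no deeper branching
  and no automatic topology search.
- Branch labels near the bifurcation are intrinsically ambiguous; the
  generator leaves a margin after `t_branch` before day-6 sampling, and
  accuracy is evaluated on post-bifurcation cells.
- The permutation scheme and the grid parametrization are documented
  package decisions; both are
  isolated behind small functions (`rescale_rank`, the gate in
  `MatrixResponsivenessScreen`) if a user needs alternatives.
- Pseudotime "rates" across conditions are not compared; the two maps'
  pseudotimes are not commensurate, which is why each projection is
  rescaled before gridding.
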