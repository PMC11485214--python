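# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the known limitations. Everything quantitative
stated here is computed by the test suite or the analysis drivers.

## Synthetic cohorts

The generator (`syndata`) emulates a cohort of individually barcoded embryos
spanning a latent developmental-time axis. Each embryo draws a latent time
uniformly over the cohort window (sorted, so embryo IDs follow time); each
cell draws a discrete state from time-dependent state-frequency curves, a
depth from a mean-preserving lognormal (σ = 0.5) rounded by a Poisson, and
UMI counts from a multinomial over the state's mean-expression vector. A
per-cell, per-gene gamma multiplier (shape 10, i.e. ~32% CV) before the
multinomial produces the negative-binomial-like overdispersion of shallow
UMI data without committing to any package's NB parameterization. The wide
lognormal depth matters: near-constant depths put all cells on a thin
variance shell in embedding space, an artifact real data does not show.

Two builders define the study conditions:

* **EPC cohort** (`epc_cohort_spec`, default 12 embryos × ~250 cells, 500
  genes, 3,000 UMIs/cell): uncommitted progenitors differentiating along two
  graded branches (SpT-Gly-like and TGC-progenitor-like), each modelled as 7
  geometric interpolation steps between progenitor and endpoint — a
  continuum, not isolated blobs, because the estimators assume continuous
  bifurcation and terminal pseudotime bins otherwise degenerate into
  noise-selected tails. A Hand1-like factor (baseline frequency 5×10⁻³) is
  repressed 12-fold towards the SpT-Gly endpoint and an Ascl2-like factor
  7-fold towards the TGC endpoint; 30 program genes per branch ramp 10-fold.
  State vectors are balanced to sum to one before sampling so planted fold
  ratios are realized exactly on the frequency scale.
* **Atlas cohort** (`default_atlas_spec`, default 30 embryos × ~220 cells —
  the per-embryo density of the emulated study — 400 genes): nine states in
  two branching lineages plus a rare precursor held at 1.5%, the S-/M-phase
  marker genes with a planted cycling-cell program (35% of cells, 6× boost),
  and 40 "maturation" genes drifting ±2 log2 across the time window. The
  drift encodes within-cell-type temporal expression change; without it,
  nearest-neighbour rank resampling carries no time signal and embryo
  timing cannot work.

Perturbed cohorts re-use a shared gene design (`design_seed`) so that only
planted effects, not background redraws, separate conditions: target genes
are scaled (0 = ablation) in chosen compartments, state frequencies are
re-weighted then renormalized, and nuisance genes get condition-specific
shifts shared by a KO and its littermate controls. Doublets are sums of two
same-embryo cells (plate barcoding makes cross-embryo doublets impossible)
with parent IDs recorded.

What the generator does **not** emulate: ambient RNA, batch chemistry
beyond planted nuisance genes, read-level noise, gene–gene correlation
within a state beyond the shared gamma draws, and cell-cycle phase
structure (cycling is a binary flag). Passing tests therefore demonstrate
correctness of the estimators under the stated sampling model, not
robustness to those real-data artifacts.

## QC

Cells are retained with total UMIs in [2,000, 30,000] (boundaries inclusive
for retention; the removal rules are strict inequalities) and, when
mitochondrial/ribosomal gene lists are supplied, a mito:ribo count ratio
≤ 1 (configurable; the ratio rule has no published value). The doublet
score is a transparent pANN re-implementation: round(pN·n) artificial
doublets (pN = 0.25) are built by summing random cell pairs, the joint
matrix is embedded by the top 30 PCs of log2(1 + CPM/10), and each cell is
scored by the fraction of artificial cells among its round(pK·(n+n_art))
nearest neighbours. Artificial doublets keep their summed depth on purpose:
the double-depth/half-variance signature is part of what identifies true
doublets. As a consequence the raw mean pANN on structureless data exceeds
the exchangeability expectation pN/(1+pN); that expectation is exposed and
tested through `doublet_scores(..., permute_labels=True)`, which scores
against a random relabelling of the joint cells. Homotypic doublets are out
of scope.

## Metacells

Feature genes pass a variance/mean threshold (T_vm = 0.1) computed on
counts downsampled to the median cell depth (removing depth-driven
variance), coverage thresholds (T_tot = 50 total UMIs, T_top3 = 3 for the
third-largest per-cell count), and survive gene-cluster screening: the
candidates are k-means-clustered (default 120 clusters) on log expression,
and clusters with hypergeometric enrichment (BH-q < 0.05, overlap ≥ 3) for
cell-cycle or stress marker sets are removed — a reproducible stand-in for
manual curation. The cell partition builds a cosine-similarity balanced
kNN graph (Knn = 100) and clusters it with seeded Leiden modularity, with
the resolution bisected so community count tracks n_cells/target_size
(target 60 cells). Communities above twice the target are split by
within-community k-means and groups below the minimal size (20) are merged
into their most similar neighbour, keeping metacells near the conventional
20–100-cell scale. The published metacell packages' exact partition
heuristics are not reproduced; only their stated constraints are honoured.
The expression model (e, le with the fixed 10⁻⁵ pseudocount, lf) is exact
arithmetic and tested to machine precision.

## Embryo staging

Embryo similarity is the Pearson correlation of log add-one-smoothed
metacell-composition vectors (smoothing avoids zero-frequency degeneracy in
small embryos); embryos below 10 cells are excluded. The ordering objective

    G(order) = Σ_{d=1..h} w(d) Σ_i S[o_i, o_{i+d}],  w(d) = (h−d+1)/h,  h = 5

is hill-climbed with random segment reversals and single-embryo relocations
from the nominal-day initial order, accepting only improvements and
stopping after 3,000 consecutive rejections; the final order is oriented
early→late by correlation with nominal days. This objective is a documented
surrogate for a published network-flow-based ordering whose internals are
defined elsewhere; it is validated purely by recovery of planted latent
times (median |Spearman| ≈ 0.95 over five 30-embryo cohorts). Local-window
objectives can prefer globally folded orders on weak similarity matrices —
one seed in five lands near |ρ| ≈ 0.88 — which the median-based validation
absorbs.

E_t calibration sorts nominal days by rank, pre-smooths with an 11-point
rolling median (antisymmetric edge padding so linear trends survive the
boundary), enforces monotonicity by isotonic regression, and interpolates
with a monotone PCHIP spline; E_t is non-decreasing in rank by construction
and calibration is idempotent. Age bins are equal-count rank bins (sizes
within one; 251 embryos in 16 bins gives sizes 15–16). Proliferation rates
interpolate linearly from 0 to 3.5 divisions/day, anchored so the
atlas-wide 90th-percentile S+M cell-cycle score maps to the maximum.

## Lineage kinetics

Variable-gene selection, five-cluster k-means on `lf`, and program assembly
follow the thresholds listed in the README. Cluster labels are canonicalized
by sorting on mean endpoint-A minus endpoint-B relative expression, making
the "clusters 1–2 → A-side program, 4–5 → B-side program" mapping
deterministic and invariant to gene input order.

The principal curve is Hastie–Stuetzle-style: initialized on the first
principal component, alternating lowess smoothing (local linear, span 0.3)
of each coordinate against arc-length with re-projection onto the smoothed
polyline (capped at 200 vertices), converged when mean projection
displacement < 10⁻⁴ (≤ 50 iterations). Collinear input falls back to the
PC1 line with a warning. Positions are normalized arc lengths with robust
endpoints: the span covers the 1st–99th percentile of arc mass and outlying
cells are clamped to the termini, so a few stray cells cannot stretch the
pseudotime axis. Orientation puts the anchor (progenitor) cells near 0.

Kinetics pool counts per 12 equal-arc-length bins; empty bins are reported
missing, never interpolated; the midpoint bin contains arc-length 0.5. The
endpoint fold is the first-bin/last-bin pooled-expression ratio. Because a
terminal bin is the extreme slice of the progenitor cloud, cells there are
mildly selected for high realized counts of any gene that loads on the
score axes; on the default EPC cohort this biases recovered folds upward by
roughly 5–15%, within the ±25% validation band and inherent to this class
of estimator.

ExM-PGC-precursor identification flags non-PGC metacells whose mean PGC
score falls between the 75th percentile of non-PGC metacell scores and the
25th percentile of PGC-annotated metacell scores (band edges: inclusive
below, exclusive above) and whose mean cell E_t is below a configurable
early-time cut-off; the published criteria are qualitative, so the
quantile band and time gate are the package's parameterization and are
always reported with results.

## Perturbation analysis

Query-cell annotation builds a joint query+atlas kNN graph on feature-gene
log expression; each query cell's atlas-neighbour type distribution is
matched to the best-correlated atlas cell's distribution among its
neighbours, and cells with fewer than 10 atlas cells among their K = 100
nearest joint neighbours fall back to the cell–metacell correlation
`cor(log2(u+1), log2(e+1e-5))` over the feature list (Pearson throughout;
ties towards the lower metacell ID).

Embryo timing resamples, for every atlas cell, the rank of its nearest
neighbour from a *different* atlas embryo; query cells inherit the resampled
rank of their nearest atlas cell — rather than that cell's raw embryo rank —
so query and atlas rank distributions live in the same family (with raw
ranks, an exact-copy query degenerates to a point mass and the match becomes
noise). Each query embryo is matched to the WT embryo with the
best-correlated cumulative rank distribution; embryos with fewer than 5
ranked cells are left unmatched. Batch-mode timing is the argmin over
embryos of the L1 distance between the batch's metacell-frequency vector
and window-averaged per-embryo vectors (window w configurable; 20 for
earlier-stage batches, 5 for later ones in the emulated design).

Differential expression on pooled counts uses the df=1 χ² statistic on
(N¹_g, N¹−N¹_g) vs (N²_g, N²−N²_g) without continuity correction (the
convention is also used by the test oracles), BH-corrected; genes absent
from both groups are excluded. Fold changes against projected profiles use
ε = 5×10⁻⁵ and are exactly antisymmetric. The lateral-gene screen takes
candidates with max |lfc| > 0.8 across cell-type×condition columns (plus a
minimal-expression pass), clusters them into 10 k-means groups on their lfc
profiles, and flags groups whose mean |lfc| in any control condition
exceeds 0.4. Per-embryo DE requires a ≥3-fold change in at least one
(embryo, cell type) with ≥10 query cells and expression ≥10⁻⁴, removes
lateral genes, and clusters survivors into three groups. When a knockout
experiment is analysed, query metacells are built **per condition**:
pooling KO and control cells into shared metacells leaks the ablation into
control pseudo-bulk profiles and falsely marks true targets as lateral.

Composition comparisons: per-embryo two-sided Wilcoxon rank-sum per cell
type with BH across types (types skipped below 3 embryos per group);
pooled two-tailed χ² for low-frequency types (default when the pooled
expected count is below 5 per group); pooled log2 frequency ratios against
the 2-fold reference; and an ExE-to-embryonic cell ratio per age bin.
Planted frequency multipliers act before renormalization, so the *realized*
fold is m / (1 + Σᵢ(mᵢ−1)sᵢ) for state shares s — validation always targets
the realized fold.

## Problem sizes and determinism

Default validation sizes: EPC fold recovery uses three ~3,000-cell
replicates; ordering uses five 30-embryo cohorts (~6,600 cells each);
annotation holds out 20% of a 30-embryo atlas; the KO experiment uses
10+10+20 embryos of ~110 cells. All randomness flows from a single root
seed through named CRC-derived substreams, so stages can be re-run
independently yet reproducibly, and every generator output is bit-identical
across runs given its seed.

## Known limitations

* The ordering objective is a surrogate; its optimum can disagree with the
  latent order when the similarity signal is weak (folded tails).
* Terminal pseudotime bins carry a small positive selection bias on
  score-loading genes (quantified above).
* pANN's exchangeability expectation does not hold for raw pair-sum
  artificial doublets (by design, the depth signature is the detector);
  calibration statements should use the permutation null.
* The annotation path assumes query and atlas share a gene universe and
  comparable depth; no batch-effect correction is attempted beyond the
  lateral-gene screen.
* Metacell partitions are Leiden realizations: community structure at a
  given seed can differ in detail, which is why validation criteria are
  medians or tolerance bands rather than exact partitions.
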