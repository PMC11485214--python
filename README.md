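# embryochrono

Tools for temporal modelling of single-embryo, single-cell RNA-seq cohorts of
mouse embryonic and extraembryonic (ExE) development. The package implements a
desk-scale version of the analysis chain used to study trophoblast
differentiation during gastrulation: metacell expression modelling,
transcriptional staging of individual embryos, principal-curve pseudotime of
lineage bifurcations, projection of perturbed (knockout) cells onto a
wild-type atlas, and the associated differential-expression and cell-type
composition statistics. A synthetic-cohort generator with complete ground
truth makes every stage testable end to end without any data download.

## The model in brief

**Metacell expression.** Cells are partitioned into small homogeneous groups
("metacells", ~20–100 cells). For metacell *m* and gene *g*,

    e_gm = Σ_{c∈m} N_gc / Σ_g Σ_{c∈m} N_gc,
    le_gm = log2(e_gm + 1e-5),
    lf_gm = le_gm − mean_m(le_gm)

where `N_gc` are UMI counts. All downstream statistics operate on these
quantities.

**Embryo staging.** Each embryo is summarized by its metacell-composition
vector; embryo–embryo similarity is the Pearson correlation of smoothed log
compositions. Embryos are ordered by improvement-only reshuffling of a
kernel-weighted adjacency objective starting from morphological order, and
ranks are calibrated to developmental time E_t by a monotone spline of
nominal collection day on rank, then grouped into 16 equal-count age bins.

**Lineage kinetics.** For a bifurcating lineage, variable genes are selected
by expression floor (`min_m le > −13`), dynamic range (`max−min le > 2`) and
an endpoint gap (`>1.5` between the branch endpoints' maxima), clustered into
five k-means groups on `lf`, and the extreme clusters define endpoint gene
programs. Per-cell program scores (UMI fractions) span a 2-D score space in
which a principal curve is fitted; cells are binned into 12 equal-arc-length
pseudotime bins and pooled expression kinetics are read off per bin.

**Perturbation statistics.** Query cells are annotated by matching
atlas-neighbour cell-type distributions (with a cell–metacell correlation
fallback), query embryos are timed by matching cumulative rank distributions,
and query metacells are projected onto their best-correlated atlas metacell.
Expression differences use `lfc = log2(mean e_query + ε) − log2(mean e_proj + ε)`
with ε = 5×10⁻⁵; pooled-count comparisons use a χ² test on 2×2 UMI tables
with Benjamini–Hochberg correction; compositions are compared per embryo with
Wilcoxon rank-sum tests (χ² for low-frequency types, pooled log2 ratios
against a 2-fold reference).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_quality_control.py
python analysis/03_build_atlas.py
python analysis/04_stage_embryos.py
python analysis/05_epc_lineage_kinetics.py
python analysis/06_ko_projection_de.py
```

`05_epc_lineage_kinetics.py` generates a ~3,000-cell ectoplacental-cone-like
cohort in which a Hand1-like transcription factor is planted with a 12-fold
repression towards the SpT-Gly endpoint and an Ascl2-like factor with a
7-fold repression towards the TGC-progenitor endpoint, then recovers both
through the full pipeline. Its output on this machine:

```
2957 cells; 62 lineage-variable genes
  program spt_gly_score: 30 genes (clusters [1, 2])
  program tgc_progenitor_score: 31 genes (clusters [4, 5])
Hand1like: recovered endpoint fold 11.81 (planted 12, error -1.6%)
Ascl2like: recovered endpoint fold 7.66 (planted 7, error +9.5%)
```

The fold values are the first-bin over last-bin pooled expression ratios
along each branch's 12-bin pseudotime axis — i.e., how strongly each factor
is shut down between the uncommitted progenitor end and the differentiated
endpoint. `06_ko_projection_de.py` similarly reports full recovery of
planted knockout effects (20 ablated genes, batch-restricted nuisance genes,
and ≥2-fold cell-type frequency shifts at BH-q < 0.001).

A thin CLI wraps the same stages (`embryochrono simulate|qc|atlas|chrono|
kinetics|perturb|run --config cfg.yaml --out dir --seed N`).

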