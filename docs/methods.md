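# Methods

`haemscore` packages the computational core of a single-cell analysis of
haematopoietic stem and progenitor cell (HSPC) aging and p53 pathway
activation: control-referenced gene-set scoring, reference-projection
cell typing, spike-in-calibrated variable-gene selection, derivation of
p53-dependent gene sets from genotype contrasts, lineage-composition
quantification, and score-stratified survival analysis. Because the
original cohorts are animal and patient data, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes, so every stage can be exercised against a known ground
truth.

## Signature scoring

The central statistic is a per-cell signature score: the mean expression
of a gene set minus the mean expression of a control gene set in the same
cell. Controls are chosen one of two ways.

* **Expression-matched bins (default).** All genes are ranked by mean
  expression across cells and cut into `n_bins = 25` equal-size rank
  bins; for each signature gene, `ctrl_per_gene = 50` control genes are
  sampled without replacement (seeded) from that gene's bin, the union is
  de-duplicated, and its mean is subtracted. Matching controls on
  expression level stops the score from tracking library depth or
  detection rate. If every bin-mate of the signature is itself a
  signature gene (possible only on very small gene universes), the
  control set widens to all non-signature genes so the score remains
  defined.
* **Fixed reference pool.** When a curated control list is supplied
  (e.g. a ~694-gene reference set), the control mean is taken over that
  pool; this mode is deterministic and shift-invariant by construction.

Two signatures are packaged: the 20-gene HSC Aging Signature and the
16-gene Haem p53Score set (validated p53 transcriptional targets whose
induction under genotoxic stress is abolished by p53 loss). Scores are
computed on z-scored log expression by default; raw-log scoring is a
flag, since for cross-dataset application either convention is defensible
and the scale choice is not fully determined. Mouse symbols map to human
by uppercasing plus a small override table (e.g. Trp53 → TP53, Mt1 →
MT1A). If fewer than half the signature genes are present the score is
refused (silent renormalization over a small remnant would not be
comparable across datasets); above that floor missing genes are dropped
with a warning.

Cell-cycle phase is assigned from S-phase and G2/M program scores
computed the same way: a cell is G1 when both scores are negative,
otherwise it takes the larger score's label, with exact ties resolved to
G2M (an arbitrary but documented and deterministic choice). Phase can
then be regressed out (below) before downstream scoring.

## Processing chain

Counts are filtered per cell on detected genes, mitochondrial fraction,
spike-in fraction and total counts. `min_*` thresholds are inclusive
(a cell at exactly `min_genes = 1500` is kept, matching the convention of
the standard `filter_cells`-style tools); `max_*` thresholds remove cells
strictly above the cutoff. Biological genes are then scaled to a fixed
per-cell total (10,000 by default; spike-ins are excluded from the
denominator but share the cell's factor), log-transformed as ln(x + 1),
and z-scored per gene (population SD; exactly constant genes map to
zeros — constancy is detected by min == max because accumulated rounding
can leave a "constant" column with a tiny nonzero SD, which would explode
the z-scores). Nuisance covariates (typically phase) are removed by
per-gene ordinary least squares with an intercept; categorical covariates
expand to indicators and a rank-deficient design is rejected with the
collinear columns named. Counts-per-10K is the only supported
normalization; TMM-style normalization used by some plate-based workflows
is deliberately not reimplemented.

## Highly variable genes

For data with ERCC-like spike-ins, the technical noise model
CV²_tech(μ) = a₁/μ + α₀ is fitted to the spike-ins by a Gamma GLM with
identity link (least-squares fallback if the GLM fails). Spike-ins and
biological genes are depth-normalized separately by their own totals.
Each biological gene's observed variance is tested against the fitted
technical variance inflated by a minimum biological dispersion
(`min_biol_disp = 0.25`): the statistic var·(n−1)/denominator is referred
to χ²(n−1), with the denominator (μa₁ + μ²ω)/(1 + ω/n) where
ω = α₀ + min_biol_disp + α₀·min_biol_disp, and selection is at
Benjamini–Hochberg FDR 0.1. These defaults follow the cited method's
convention. The test is conservative by design (the null already grants
each gene 0.25 of biological CV²), so false selections are rare and power
for weakly expressed genes is modest: on the benchmark design (500 cells,
50 planted genes with CV²_biol = 0.5 among 950 null genes, means spanning
0.5–50) about 40 of 50 planted genes are recovered, with recovery
concentrated in the mid-to-high expression range. A mean/dispersion
fallback (mean window 0.02–3, bin-z-scored dispersion > 0.3 over 20 mean
bins) serves datasets without spike-ins.

## Reference-projection cell typing

A reference landscape stores the PCA basis of a labeled reference
restricted to its HVGs: centering means, orthonormal loadings (top 50
components by default) and reference-cell coordinates. Query cells are
centred with the *reference* means (never their own) and multiplied by
the loadings, so they land in the reference frame; HVGs missing from the
query are imputed at the reference mean (zero after centering), with a
hard floor of 80% HVG coverage. No query re-scaling is applied — the
projection is plain PCA. Labels transfer by majority vote over the k = 15
nearest reference cells (Euclidean distance in PC space); vote ties break
to the class with the smaller summed neighbor distance, then
lexicographically — deterministic and locality-respecting.

Typing is two-tier: a broad key landscape labels every cell, and cells
labeled HSC or Immature are re-labeled by a finer stem/progenitor
landscape (LT-HSC / ST-HSC / MPP); committed progenitor labels are final.
On synthetic references with marker-separated clusters, held-out cells
recover their fine labels essentially perfectly; on real atlases the
accuracy is bounded by the biological overlap of neighboring states,
which the synthetic clusters do not model.

## p53-dependent gene derivation

Candidate p53 targets are tested per cell type with one-sided rank-sum
contrasts: *up in mutant vs wild type*, and *higher in mutant than in the
mutant additionally lacking p53* (the rescue criterion that separates
p53-driven induction from p53-independent stress responses).
Benjamini–Hochberg correction is applied within the candidate set per
contrast and cell type; a gene is called dependent in a cell type when
both corrected tests pass at α = 0.05, and enters the signature when
dependent in at least `min_types = 3` of the cell types (a concrete
reading of "multiple subtypes", exposed as a flag). Cell types with fewer
than 5 cells in any genotype are skipped with a warning. This stratified
rank-based formulation replaces a negative-binomial GLM with genotype,
phase and cell-type terms: stratification handles cell type, phase can be
regressed out beforehand, and the two directional contrasts encode the
defining pattern exactly and testably. The Mann–Whitney wrapper uses the
exact null when min(n, m) ≤ 8 without ties, and the tie- and
continuity-corrected normal approximation otherwise.

Gene–score association is plain Pearson correlation of each gene against
a per-cell score, ranked descending with symbol tie-breaks; exactly
constant genes are reported with r = NaN and excluded from ranking
(thresholding is left to the caller, since a correlation cutoff is
analysis-specific).

## Survival stratification

Subjects are split at the (1 − q) score quantile (linear interpolation,
ties-high; default top 25% vs bottom 75%). Three estimators are exposed
and never silently mixed:

* the Kaplan–Meier product-limit curve per group;
* the Mantel–Haenszel log-rank test with the O/E hazard ratio
  (O₁/E₁)/(O₂/E₂) and log-scale CI exp(log HR ± z·√(1/E₁ + 1/E₂)) — the
  form conventionally reported alongside KM figures;
* a Cox proportional-hazards fit maximizing the Breslow partial
  likelihood by Newton–Raphson (gradient tolerance 1e-8, ≤ 100
  iterations) with Wald CIs, for multivariate adjustment (score-high,
  age > 60, prior treatment as 0/1 indicators by default; the dichotomous
  score coding is the default because that is how a top-quantile risk
  group is defined). Breslow ties were chosen for exact testability;
  with continuous times the fit agrees with an Efron-ties reference to
  four decimals. Non-convergence reports the last gradient norm, and
  diverging coefficients (|β| > 50) raise a separation error.

## Synthetic cohorts

`simulate_hspc_cohort` draws negative-binomial counts with variance
μ + μ²/θ (θ = 2 for biological genes — typical biological
overdispersion; θ = 20 for spike-ins, i.e. near-Poisson technical
noise). Structure is planted multiplicatively on the NB mean:

* **cell types** via disjoint marker blocks (20 genes, 8-fold by
  default) — enough separation that typing errors reflect implementation
  faults, not overlapping states;
* **genotype effects** via named fold-changes on gene sets, optionally
  restricted to cell types; effects flagged as p53 activation define the
  per-cell ground-truth `p53_active` label. The default three-genotype
  design plants 4-fold activation of the 16 p53 targets and 3-fold
  upregulation of the 20 aging genes in the stressed double knockout,
  rescued in the triple (p53-null) knockout, and expands the myeloid
  compartment (GMP 2.0×, MEP 1.6×, LMPP 0.5×) in the stressed genotype;
* **depth variation** via lognormal size factors (σ = 0.25) applied to
  biological and spike-in genes alike — the variation normalization must
  remove;
* **cycling subpopulations** optionally boost designated S / G2M program
  genes per cell.

Spike-in means follow a geometric ladder (0.2–2000) mimicking a spike-in
mix; 92 spike-ins by default. All randomness flows through one seeded
generator; (config, seed) fully determines the output, and ground truth
(per-cell labels, per-gene planted folds) is serialized alongside the
matrix so tests never re-derive it.

`simulate_survival_cohort` draws exponential event times with baseline
median 365 days; the top `frac_high` of a continuous score has hazard
multiplied by `hr_high` (2.34 in the packaged demo, mirroring the
adverse-risk group size and effect the analysis is designed to detect),
with independent exponential censoring calibrated so the requested
fraction of baseline subjects is censored. Optional covariate hazards
(age, prior treatment) default to 1.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: gene–gene correlation beyond the
planted blocks, batch effects, ambient RNA, doublets, zero-inflation
beyond NB, overlapping/continuous cell states, and non-proportional
hazards. Recovery results on synthetic cohorts validate the estimators'
correctness and calibration, not their field performance.

## Problem sizes and numerical choices

Tests and the acceptance script run on cohorts of roughly 500–1800 cells
and 400–1300 genes, 500-replicate null calibrations at n = 200 subjects,
and a 5000-subject cohort for hazard-ratio consistency — sizes chosen so
the full suite completes in well under a minute while keeping every
statistical check comfortably powered. Matrices are dense in memory
(the design sizes make sparsity unnecessary); MTX files are 1-based on
disk per the standard and 0-based in memory. Degenerate inputs are
contracts, not accidents: zero-variance genes scale to zeros and are
excluded from correlation ranking, zero-count cells are rejected at
normalization with a pointer to QC, a genotype with zero cells yields
explicit zero-proportion rows, and every all-cells-removed QC outcome
names the binding criterion.

## Known limitations

* The 694-gene fixed control pool for the p53 score is a configuration
  slot, not packaged data; bin-matched controls are the default.
* The rank-based dependence derivation is a deliberate divergence from a
  GLM-based differential-expression formulation; effect-size shrinkage
  and covariate interactions are out of scope.
* The spike-in HVG test is conservative at low expression (see above).
* UMAP layouts, graph clustering, doublet detection and batch
  integration are outside the package; typing rests entirely on
  reference projection.
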