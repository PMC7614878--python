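# haemscore

Signature scoring, reference-projection cell typing and score-stratified
survival analysis for haematopoietic stem/progenitor cell (HSPC)
transcriptomes.

## The problem

Genotoxic stress (for example endogenous aldehyde damage in Fanconi-anemia
pathway mutants) drives HSPCs toward a prematurely aged, myeloid-biased
state via activation of the p53 transcriptional program. Quantifying this
from single-cell RNA-seq requires a small set of interlocking statistics:

* **Signature scores.** For a cell *c* and gene set *G*, the score is

  `score(c) = mean(expr_c over G) − mean(expr_c over controls)`

  with controls drawn from expression-matched bins (rank genes by mean
  expression, cut into 25 equal-size bins, sample 50 controls per
  signature gene, seeded) or from a fixed reference pool. Two signatures
  ship with the package: a 20-gene **Aging Signature** (genes consistently
  upregulated in aged murine LT-HSCs, led by *Selp*) and the 16-gene
  **Haem p53Score** (*Cdkn1a*, *Eda2r*, …, *Pml* — p53 targets whose
  induction under stress is rescued by p53 loss), which quantifies p53
  transcriptional activity in mouse and (via symbol mapping) human
  haematopoietic cells.
* **Cell typing** by projecting query cells into the PCA space of an
  annotated reference landscape (centred with the reference means) and
  voting over the 15 nearest reference cells, with a two-tier scheme that
  refines stem/immature labels against a finer landscape.
* **Variable-gene selection** calibrated on ERCC-like spike-ins: fit
  CV²_tech(μ) = a₁/μ + α₀ on the spike-ins, test each gene's variance
  against the technical expectation (χ² ratio test, BH FDR).
* **p53-dependence calling**: a candidate target is *dependent* in a cell
  type when it is up in the stressed mutant vs wild type **and** restored
  in the mutant additionally lacking p53 (one-sided rank-sum tests, BH
  within the candidate set); genes dependent in ≥ 3 cell types form the
  signature.
* **Survival stratification**: split subjects at the top score quartile,
  compare groups by Kaplan–Meier curves, the Mantel–Haenszel log-rank test
  with the O/E hazard ratio, and a multivariate Cox fit (Breslow ties).

Because the original cohorts are animal/patient data, the package includes
a negative-binomial cohort simulator with planted, recoverable structure
(cell-type markers, genotype effects, spike-ins, library-size variation,
score-dependent hazards) so every stage is testable against ground truth.
See `docs/methods.md` for the full model description.

## Worked example

Run the whole analysis on a simulated three-genotype cohort (wild type,
stressed double knockout "DKO", and DKO with p53 additionally lost,
"TKO"):

```sh
haemscore run-all --outdir demo_run --seed 0 --cells-per-combo 40
```

or equivalently from Python:

```python
from haemscore import PipelineConfig, default_sim_config, run_pipeline

report = run_pipeline(PipelineConfig(
    outdir="demo_run", seed=0,
    sim=default_sim_config(seed=0, cells_per_combo=40),
))
```

which prints (abridged):

```json
{
  "n_cells_qc": 764,
  "cell_typing_accuracy": 1.0,
  "p53_dependent_genes": ["Aen", "Bax", "Bbc3", "Casp1", "Ccng1",
    "Cdkn1a", "Ctsd", "Ier5", "Perp", "Phlda3", "Pml", "Pvt1",
    "Tnfrsf10b", "Zmat3", "Eda2r", "Sulf2"],
  "lineage_by_class": {
    "WT/myeloid": 0.3333, "DKO/myeloid": 0.507, "TKO/myeloid": 0.3333
  },
  "survival_hr": 1.9856338102584883,
  "survival_p": 7.38486271370471e-20
}
```

Reading the numbers: all 764 simulated cells pass QC; two-tier reference
projection recovers every planted cell type; the dependence rule derives
exactly the 16 planted p53 target genes (decoy genes that are up in both
DKO and TKO fail the rescue criterion and are excluded); the DKO cohort
shows the planted myeloid expansion (51% vs 33% myeloid); and on the
simulated survival cohort the top-quartile score group carries a log-rank
hazard ratio near the planted value with overwhelming significance.
Artifacts (count matrix, landscapes, scored cell metadata, KM tables,
Cox fits, a stage-by-stage manifest) land in `demo_run/`.

Individual stages are available as library functions
(`haem_p53_score`, `hierarchical_cell_typing`, `select_hvg_spikein`,
`identify_p53_dependent_genes`, `stratify_top_quantile`, `cox_fit`, …)
and as CLI verbs (`simulate`, `qc`, `score`, `annotate`,
`derive-signature`, `proportions`, `survival`, `make-fixtures`).

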