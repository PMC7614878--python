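"""End-to-end orchestration: simulate/load -> QC -> normalize -> phase ->
project/type -> score -> derive signature -> proportions -> survival.

Each stage writes its artifact into the run directory and appends one
manifest line (stage, parameters, outputs), so any output is traceable to
the parameters that produced it. A rerun with the same configuration and
seed reproduces score columns exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .datatypes import ExpressionMatrix, QCThresholds
from .p53 import (
    identify_p53_dependent_genes,
    lineage_proportions,
    selected_genes,
)
from .projection import (
    ReferenceLandscape,
    fallback_hvg_dispersion,
    fit_reference_pca,
    hierarchical_cell_typing,
    load_landscape,
    save_landscape,
    select_hvg_spikein,
)
from .qc import (
    compute_qc_metrics,
    log_transform,
    normalize_counts,
    qc_filter_cells,
    regress_out_covariates,
    scale_genes,
)
from .scoring import aging_signature_score, assign_cell_cycle_phase, haem_p53_score
from .signatures import HAEM_P53_GENES, haem_p53_signature
from .simulate import (
    GroundTruth,
    SimConfig,
    default_sim_config,
    simulate_hspc_cohort,
    simulate_survival_cohort,
)
from .survival import cox_fit, kaplan_meier, logrank_test_hr, stratify_top_quantile

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_fixtures",
    "build_two_tier_landscapes",
    "COARSE_LABEL_MAP",
    "LINEAGE_MAP",
]

# fine simulated cell types -> coarse key-landscape labels
COARSE_LABEL_MAP = {
    "LT-HSC": "HSC",
    "ST-HSC": "Immature",
    "MPP": "Immature",
    "LMPP": "LMPP",
    "GMP": "GMP",
    "MEP": "MEP",
}

LINEAGE_MAP = {
    "LT-HSC": "stem",
    "ST-HSC": "stem",
    "MPP": "stem",
    "LMPP": "lymphoid",
    "GMP": "myeloid",
    "MEP": "myeloid",
}


@dataclass
class PipelineConfig:
    """Everything one run needs; paths are validated before any compute."""

    outdir: str | Path = "haemscore_run"
    seed: int = 0
    # input: either a simulation design or a matrix path
    sim: SimConfig | None = None
    input_path: str | Path | None = None
    qc: QCThresholds = field(
        default_factory=lambda: QCThresholds(min_genes=200, max_pct_mito=0.1)
    )
    target_sum: float = 10_000.0
    score_layer: str = "scaled"
    regress_phase: bool = True
    # cell typing: load landscapes from disk, or build from the cohort itself
    key_landscape_path: str | Path | None = None
    refinement_landscape_path: str | Path | None = None
    k_neighbors: int = 15
    n_components: int = 50
    # p53-dependence derivation
    candidates: tuple[str, ...] | None = None
    min_types: int = 3
    alpha: float = 0.05
    # survival cohort
    survival_n: int = 1000
    survival_hr_high: float = 2.34
    survival_frac_high: float = 0.25
    survival_censor_rate: float = 0.2
    survival_quantile: float = 0.25
    survival_covariates: tuple[str, ...] = ("group_high", "age_gt60", "prior_treatment")

    def validate(self) -> None:
        for p in (self.key_landscape_path, self.refinement_landscape_path,
                  self.input_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.sim is None and self.input_path is None:
            raise ValueError("config needs either a SimConfig or an input_path")


class _Manifest:
    def __init__(self, outdir: Path) -> None:
        self.path = outdir / "manifest.tsv"
        self.path.write_text("stage\tparams\toutputs\tseconds\n")

    def record(self, stage: str, params: dict, outputs: list[str], t0: float) -> None:
        line = (
            f"{stage}\t{json.dumps(params, default=str)}\t"
            f"{json.dumps(outputs)}\t{time.monotonic() - t0:.2f}\n"
        )
        with self.path.open("a") as fh:
            fh.write(line)
        logger.info("stage=%s outputs=%s", stage, outputs)


def _split_reference(
    m: ExpressionMatrix, truth: GroundTruth, frac_ref: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded split of cells into reference and query halves, stratified by
    true cell type so every type is represented in the reference."""
    rng = np.random.default_rng(seed)
    ref = np.zeros(m.n_cells, dtype=bool)
    types = truth.cells.loc[m.cells, "cell_type"].to_numpy()
    for ct in np.unique(types):
        idx = np.nonzero(types == ct)[0]
        take = max(1, int(round(frac_ref * idx.size)))
        ref[rng.choice(idx, size=take, replace=False)] = True
    return ref, ~ref


def build_two_tier_landscapes(
    m: ExpressionMatrix,
    labels_fine: pd.Series,
    n_components: int = 50,
    coarse_map: dict[str, str] | None = None,
    layer: str = "log",
) -> tuple[ReferenceLandscape, ReferenceLandscape]:
    """Build key (coarse) and refinement (fine) landscapes from a labeled
    reference cohort.

    The key landscape carries coarse labels (fine stem/progenitor states
    collapsed to HSC / Immature); the refinement landscape is fitted on the
    stem/immature compartment only, with the fine labels.
    """
    coarse_map = coarse_map or COARSE_LABEL_MAP
    labels_fine = labels_fine.loc[m.cells]
    labels_coarse = labels_fine.map(coarse_map)
    if labels_coarse.isna().any():
        missing = sorted(set(labels_fine[labels_coarse.isna()]))
        raise ValueError(f"fine labels missing from coarse map: {missing}")

    try:
        hvg = select_hvg_spikein(m)
        hvgs = hvg.selected
    except ValueError:
        hvgs = fallback_hvg_dispersion(m).selected
    if len(hvgs) < n_components:  # keep the space well-posed on small fixtures
        order = np.argsort(-m.layer(layer)[:, ~m.spikein_mask].var(axis=0))
        hvgs = m.bio_genes[order[: max(n_components, 100)]]

    n_comp_key = min(n_components, m.n_cells - 1, len(hvgs))
    key = fit_reference_pca(m, labels_coarse, hvgs, n_components=n_comp_key, layer=layer)

    refine_mask = labels_coarse.isin(["HSC", "Immature"]).to_numpy()
    sub = m.subset_cells(refine_mask)
    n_comp_ref = min(n_components, sub.n_cells - 1, len(hvgs))
    refinement = fit_reference_pca(
        sub, labels_fine[refine_mask], hvgs, n_components=n_comp_ref, layer=layer
    )
    return key, refinement


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a run report dict (also saved as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger("haemscore").addHandler(fh)
    manifest = _Manifest(outdir)
    report: dict = {"seed": config.seed}

    try:
        # -- input ---------------------------------------------------------
        t0 = time.monotonic()
        truth: GroundTruth | None = None
        if config.sim is not None:
            m, meta, truth = simulate_hspc_cohort(config.sim)
            hio.write_matrix(m, meta, outdir / "cohort")
            truth.cells.to_csv(outdir / "cohort" / "groundtruth.tsv", sep="\t")
            truth.fold_changes.to_csv(
                outdir / "cohort" / "groundtruth_folds.tsv", sep="\t", index=False
            )
            manifest.record(
                "simulate", {"seed": config.sim.seed}, ["cohort/"], t0
            )
        else:
            m, meta = hio.read_matrix(config.input_path)
            manifest.record("load", {"path": str(config.input_path)}, [], t0)
        report["n_cells_input"] = m.n_cells

        # -- QC / normalization ---------------------------------------------
        t0 = time.monotonic()
        meta = compute_qc_metrics(m, meta)
        m, meta = qc_filter_cells(m, meta, config.qc)
        if truth is not None:
            truth = GroundTruth(truth.cells.loc[m.cells], truth.fold_changes)
        m = normalize_counts(m, target_sum=config.target_sum)
        m = log_transform(m)
        manifest.record(
            "qc_normalize",
            {"qc": vars(config.qc), "target_sum": config.target_sum},
            [],
            t0,
        )
        report["n_cells_qc"] = m.n_cells

        # -- cell-cycle phase ------------------------------------------------
        t0 = time.monotonic()
        sim = config.sim
        if sim is not None and (sim.frac_s > 0 or sim.frac_g2m > 0):
            names = list(sim.resolved_gene_names())
            s_genes = names[: sim.n_cycle_genes]
            g2m_genes = names[sim.n_cycle_genes: 2 * sim.n_cycle_genes]
            m_sc = scale_genes(m)
            phases = assign_cell_cycle_phase(
                m_sc, s_genes, g2m_genes, seed=config.seed
            )
            meta["phase"] = phases["phase"]
            if config.regress_phase:
                m = regress_out_covariates(m, meta["phase"], source="log")
            manifest.record(
                "cell_cycle",
                {"regressed": config.regress_phase},
                [],
                t0,
            )
        m = scale_genes(m)

        # -- cell typing -------------------------------------------------------
        t0 = time.monotonic()
        if config.key_landscape_path is not None:
            key = load_landscape(config.key_landscape_path)
            refinement = (
                load_landscape(config.refinement_landscape_path)
                if config.refinement_landscape_path is not None
                else None
            )
        elif truth is not None:
            ref_mask, _ = _split_reference(m, truth, 0.5, config.seed + 11)
            ref = m.subset_cells(ref_mask)
            key, refinement = build_two_tier_landscapes(
                ref,
                truth.cells["cell_type"],
                n_components=config.n_components,
            )
            save_landscape(key, outdir / "landscape_key")
            save_landscape(refinement, outdir / "landscape_refinement")
        else:
            raise ValueError(
                "cell typing needs landscape paths when running from a matrix"
            )
        meta["cell_type"] = hierarchical_cell_typing(
            m, key, refinement, k=config.k_neighbors
        )
        manifest.record(
            "annotate",
            {"k": config.k_neighbors},
            ["landscape_key/", "landscape_refinement/"],
            t0,
        )
        if truth is not None:
            agree = (
                meta["cell_type"].to_numpy()
                == truth.cells.loc[m.cells, "cell_type"].to_numpy()
            )
            report["cell_typing_accuracy"] = float(agree.mean())

        # -- signature scores ---------------------------------------------------
        t0 = time.monotonic()
        aging = aging_signature_score(m, layer=config.score_layer, seed=config.seed)
        p53 = haem_p53_score(m, layer=config.score_layer, seed=config.seed)
        meta["aging_signature"] = aging.scores
        meta["haem_p53_score"] = p53.scores
        meta.to_csv(outdir / "cellmeta_scored.tsv", sep="\t")
        manifest.record(
            "score",
            {"layer": config.score_layer, "seed": config.seed},
            ["cellmeta_scored.tsv"],
            t0,
        )

        # -- p53-dependent signature derivation ------------------------------------
        genotypes = set(meta["genotype"])
        if {"WT", "DKO", "TKO"} <= genotypes:
            t0 = time.monotonic()
            candidates = config.candidates or tuple(HAEM_P53_GENES) + tuple(
                g for g in m.bio_genes if g.startswith("g")
            )[:20]
            calls = identify_p53_dependent_genes(
                m,
                meta,
                list(candidates),
                genotypes={"wt": "WT", "mutant": "DKO", "mutant_p53null": "TKO"},
                min_types=config.min_types,
                alpha=config.alpha,
            )
            derived = selected_genes(calls, config.min_types)
            pd.DataFrame(
                [
                    {
                        "gene": c.gene,
                        "n_dependent_types": c.n_dependent_types,
                        "selected": c.gene in derived,
                    }
                    for c in calls
                ]
            ).to_csv(outdir / "p53_dependence.tsv", sep="\t", index=False)
            report["p53_dependent_genes"] = derived
            manifest.record(
                "derive_signature",
                {"min_types": config.min_types, "alpha": config.alpha},
                ["p53_dependence.tsv"],
                t0,
            )

        # -- lineage proportions -----------------------------------------------------
        t0 = time.monotonic()
        lineage = lineage_proportions(meta, LINEAGE_MAP)
        lineage.by_type.to_csv(outdir / "lineage_proportions.csv", index=False)
        report["lineage_by_class"] = {
            f"{r.genotype}/{r.lineage}": round(float(r.proportion), 4)
            for r in lineage.by_class.itertuples()
        }
        manifest.record("proportions", {}, ["lineage_proportions.csv"], t0)

        # -- survival ------------------------------------------------------------------
        t0 = time.monotonic()
        surv = simulate_survival_cohort(
            n=config.survival_n,
            hr_high=config.survival_hr_high,
            frac_high=config.survival_frac_high,
            censor_rate=config.survival_censor_rate,
            seed=config.seed + 101,
        )
        hio.write_survival_table(surv, outdir / "survival_cohort.csv")
        strat = stratify_top_quantile(
            surv.set_index("subject_id")["score"], q=config.survival_quantile
        )
        km = kaplan_meier(surv.set_index("subject_id"), strat.groups)
        pd.concat(km, names=["group"]).to_csv(outdir / "km_table.csv")
        lr = logrank_test_hr(surv.set_index("subject_id"), strat)
        surv_cox = surv.assign(group_high=(surv["group"] == "high").astype(int))
        cox = cox_fit(surv_cox, list(config.survival_covariates))
        stats_out = {
            "hr": lr.hr,
            "ci_low": lr.ci_low,
            "ci_high": lr.ci_high,
            "p": lr.pvalue,
            "cox": cox.to_dict(orient="index"),
        }
        (outdir / "survival_stats.json").write_text(
            json.dumps(stats_out, indent=2, default=float)
        )
        report["survival_hr"] = lr.hr
        report["survival_p"] = lr.pvalue
        manifest.record(
            "survival",
            {"quantile": config.survival_quantile, "n": config.survival_n},
            ["survival_cohort.csv", "km_table.csv", "survival_stats.json"],
            t0,
        )

        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report
    finally:
        logging.getLogger("haemscore").removeHandler(fh)
        fh.close()


def make_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Write a deterministic miniature dataset exercising every stage.

    Contents: a simulated cohort (MTX directory with ground truth, 92
    spike-ins), serialized key/refinement landscapes, a survival CSV and
    the packaged p53 signature file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_sim_config(seed=seed, cells_per_combo=40)
    m, meta, truth = simulate_hspc_cohort(cfg)
    meta = compute_qc_metrics(m, meta)
    hio.write_matrix(m, meta, outdir / "cohort")
    truth.cells.to_csv(outdir / "cohort" / "groundtruth.tsv", sep="\t")
    truth.fold_changes.to_csv(
        outdir / "cohort" / "groundtruth_folds.tsv", sep="\t", index=False
    )

    mn = log_transform(normalize_counts(m))
    key, refinement = build_two_tier_landscapes(
        mn, truth.cells["cell_type"], n_components=30
    )
    save_landscape(key, outdir / "landscape_key")
    save_landscape(refinement, outdir / "landscape_refinement")

    surv = simulate_survival_cohort(n=400, hr_high=2.34, seed=seed + 101)
    hio.write_survival_table(surv, outdir / "survival.csv")
    hio.write_signature(haem_p53_signature(), outdir / "haem_p53_signature.csv")
    return outdir
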