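"""Synthetic HSPC cohorts with planted, recoverable structure.

The generator emulates the statistical features the downstream analysis
assumes: negative-binomial counts with cell-type structure (disjoint
marker-gene blocks), genotype-dependent multiplicative effects on named
gene sets (e.g. p53 target activation, aging-gene upregulation),
myeloid-lineage expansion via per-(genotype, cell type) cell numbers,
ERCC-like technical spike-ins whose counts are independent of biology,
lognormal library-size variation, and survival cohorts whose hazard
depends on a score group.

Counts follow NB(mean mu, dispersion theta) with variance
``mu + mu**2 / theta``. All randomness flows through one
``numpy.random.Generator`` seeded from ``SimConfig.seed``; identical
configuration and seed reproduce the matrices exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, new_cell_meta

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "GroundTruth",
    "default_sim_config",
    "simulate_hspc_cohort",
    "simulate_hvg_dataset",
    "simulate_survival_cohort",
]


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative fold-change on a gene set in one genotype.

    ``cell_types=None`` applies the effect in every cell type.
    ``marks_p53_active=True`` flags affected cells as p53-active in the
    ground truth (used for planted p53-target activation).
    """

    name: str
    genes: tuple[str, ...]
    genotype: str
    fold: float
    cell_types: tuple[str, ...] | None = None
    marks_p53_active: bool = False


@dataclass
class SimConfig:
    """Design of a simulated HSPC cohort.

    Parameters
    ----------
    n_cells_per_type
        Either a single count used for every (genotype, cell type)
        combination, or a dict keyed by ``(genotype, cell_type)``.
    cell_types
        Ordered mapping cell-type label -> lineage class
        (``"stem" | "myeloid" | "lymphoid"``).
    genotypes
        Genotype labels, e.g. ``("WT", "DKO", "TKO")``.
    baseline_means
        Per-gene NB mean (> 0), length ``n_genes``.
    dispersion
        NB dispersion theta (> 0); scalar or per-gene.
    effects
        Planted genotype-dependent fold-changes.
    markers_per_type, marker_fold
        Each cell type gets a disjoint block of ``markers_per_type`` genes
        upregulated ``marker_fold``-fold in all genotypes, creating the
        cell-type structure reference projection must recover.
    n_spikeins, spikein_means, spikein_dispersion
        ERCC-like technical spike-ins: counts depend only on the cell's
        size factor, never on genotype or cell type.
    library_size_spread
        Sigma of the lognormal per-cell size factor (>= 0).
    frac_s, frac_g2m, cycle_fold
        Optional cycling subpopulations: the designated S / G2M program
        genes are upregulated ``cycle_fold``-fold in randomly chosen cells
        regardless of genotype.
    """

    n_cells_per_type: int | dict[tuple[str, str], int]
    cell_types: dict[str, str]
    genotypes: tuple[str, ...]
    baseline_means: np.ndarray
    dispersion: float | np.ndarray = 2.0
    effects: tuple[PlantedEffect, ...] = ()
    gene_names: tuple[str, ...] | None = None
    markers_per_type: int = 20
    marker_fold: float = 8.0
    n_spikeins: int = 92
    spikein_means: np.ndarray | None = None
    spikein_dispersion: float = 20.0
    library_size_spread: float = 0.25
    frac_s: float = 0.0
    frac_g2m: float = 0.0
    cycle_fold: float = 3.0
    n_cycle_genes: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_means = np.asarray(self.baseline_means, dtype=float)
        if len(self.cell_types) == 0:
            raise ValueError("cell_types must be non-empty")
        if len(self.genotypes) == 0:
            raise ValueError("genotypes must be non-empty")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype labels must be unique")
        if self.baseline_means.size == 0 or np.any(self.baseline_means <= 0):
            raise ValueError("baseline_means must be positive")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersion must be positive")
        for eff in self.effects:
            if eff.fold <= 0:
                raise ValueError(f"effect {eff.name!r} fold must be positive")
        if self.library_size_spread < 0:
            raise ValueError("library_size_spread must be >= 0")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must match baseline_means")

    @property
    def n_genes(self) -> int:
        return int(self.baseline_means.size)

    def resolved_gene_names(self) -> pd.Index:
        if self.gene_names is not None:
            return pd.Index(self.gene_names)
        return pd.Index([f"g{i:05d}" for i in range(self.n_genes)])

    def cells_for(self, genotype: str, cell_type: str) -> int:
        if isinstance(self.n_cells_per_type, dict):
            return int(self.n_cells_per_type.get((genotype, cell_type), 0))
        return int(self.n_cells_per_type)


@dataclass
class GroundTruth:
    """Per-cell truth and per-gene planted fold-changes.

    ``cells`` has one row per simulated cell (cell_id, cell_type, genotype,
    p53_active, phase); ``fold_changes`` is a long table
    (genotype, cell_type, gene, fold) listing every planted fold != 1.
    """

    cells: pd.DataFrame
    fold_changes: pd.DataFrame


def default_spikein_means(n_spikeins: int) -> np.ndarray:
    """Geometric concentration ladder spanning ~0.2 to ~2000 mean counts,
    mimicking an ERCC spike-in mix."""
    return np.geomspace(0.2, 2000.0, n_spikeins)


def _marker_assignment(config: SimConfig) -> dict[str, np.ndarray]:
    """Disjoint marker-gene index blocks per cell type, taken from the end
    of the gene list so low-index genes stay available for planted sets."""
    out: dict[str, np.ndarray] = {}
    n = config.n_genes
    k = config.markers_per_type
    needed = k * len(config.cell_types)
    if k > 0 and needed > n:
        raise ValueError("not enough genes for the requested marker blocks")
    for i, ct in enumerate(config.cell_types):
        out[ct] = np.arange(n - needed + i * k, n - needed + (i + 1) * k)
    return out


def simulate_hspc_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw a cohort of NB count profiles under the configured design.

    Returns the count matrix (biological genes then spike-ins), the
    per-cell metadata table, and the :class:`GroundTruth` record.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.resolved_gene_names()
    gene_pos = {g: i for i, g in enumerate(genes)}
    theta = np.broadcast_to(
        np.asarray(config.dispersion, dtype=float), (config.n_genes,)
    ).copy()

    markers = _marker_assignment(config)
    spike_means = (
        default_spikein_means(config.n_spikeins)
        if config.spikein_means is None
        else np.asarray(config.spikein_means, dtype=float)
    )
    if config.n_spikeins and np.any(spike_means <= 0):
        raise ValueError("spikein_means must be positive")
    spike_names = [f"ERCC-{i:05d}" for i in range(config.n_spikeins)]

    # designated cell-cycle program genes (first 2 * n_cycle_genes genes)
    s_idx = np.arange(0, config.n_cycle_genes) if config.frac_s > 0 else np.array([], int)
    g2m_idx = (
        np.arange(config.n_cycle_genes, 2 * config.n_cycle_genes)
        if config.frac_g2m > 0
        else np.array([], int)
    )

    blocks: list[np.ndarray] = []
    spike_blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    truth_rows: list[dict] = []
    fold_rows: list[dict] = []

    for genotype in config.genotypes:
        for cell_type in config.cell_types:
            n = config.cells_for(genotype, cell_type)
            if n == 0:
                continue
            fold = np.ones(config.n_genes)
            fold[markers[cell_type]] *= config.marker_fold
            p53_active = False
            for eff in config.effects:
                if eff.genotype != genotype:
                    continue
                if eff.cell_types is not None and cell_type not in eff.cell_types:
                    continue
                idx = [gene_pos[g] for g in eff.genes if g in gene_pos]
                if len(idx) < len(eff.genes):
                    missing = sorted(set(eff.genes) - set(genes))
                    raise ValueError(
                        f"effect {eff.name!r} names unknown genes: {missing}"
                    )
                fold[idx] *= eff.fold
                p53_active = p53_active or eff.marks_p53_active
            for j in np.nonzero(fold != 1.0)[0]:
                fold_rows.append(
                    {
                        "genotype": genotype,
                        "cell_type": cell_type,
                        "gene": genes[j],
                        "fold": fold[j],
                    }
                )

            sf = rng.lognormal(0.0, config.library_size_spread, size=n)
            mu = sf[:, None] * (config.baseline_means * fold)[None, :]

            # cycling subpopulations: boost the phase program genes per cell
            phase = np.array(["G1"] * n, dtype=object)
            if config.frac_s > 0 or config.frac_g2m > 0:
                u = rng.random(n)
                phase[u < config.frac_s] = "S"
                phase[(u >= config.frac_s) & (u < config.frac_s + config.frac_g2m)] = "G2M"
                mu[np.ix_(phase == "S", s_idx)] *= config.cycle_fold
                mu[np.ix_(phase == "G2M", g2m_idx)] *= config.cycle_fold

            counts = rng.negative_binomial(theta[None, :], theta / (theta + mu))
            blocks.append(counts)
            if config.n_spikeins:
                mu_s = sf[:, None] * spike_means[None, :]
                spike_blocks.append(
                    rng.negative_binomial(
                        config.spikein_dispersion,
                        config.spikein_dispersion / (config.spikein_dispersion + mu_s),
                    )
                )
            ids = [f"{genotype}|{cell_type}|{i:05d}" for i in range(n)]
            cell_ids.extend(ids)
            for cid, ph in zip(ids, phase):
                truth_rows.append(
                    {
                        "cell_id": cid,
                        "cell_type": cell_type,
                        "genotype": genotype,
                        "p53_active": p53_active,
                        "phase": ph,
                    }
                )

    if not blocks:
        raise ValueError("configuration yields zero cells")

    counts = np.vstack(blocks)
    all_genes = pd.Index(list(genes) + spike_names)
    spike_mask = np.zeros(len(all_genes), dtype=bool)
    if config.n_spikeins:
        counts = np.hstack([counts, np.vstack(spike_blocks)])
        spike_mask[config.n_genes:] = True

    truth_cells = pd.DataFrame(truth_rows).set_index("cell_id")
    matrix = ExpressionMatrix(
        pd.Index(cell_ids), all_genes, counts, spikein_mask=spike_mask
    )
    meta = new_cell_meta(matrix.cells)
    meta["genotype"] = truth_cells["genotype"]
    meta["sample"] = truth_cells["genotype"].astype(str) + "_s1"
    fold_changes = pd.DataFrame(
        fold_rows, columns=["genotype", "cell_type", "gene", "fold"]
    )
    logger.info(
        "stage=simulate cells=%d genes=%d spikeins=%d",
        matrix.n_cells, config.n_genes, config.n_spikeins,
    )
    return matrix, meta, GroundTruth(truth_cells, fold_changes)


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A realistic three-genotype LKS-like cohort design.

    Six HSPC cell types, genotypes WT / DKO (double knockout under
    genotoxic stress) / TKO (double knockout with p53 additionally lost);
    the 16 p53 target genes are planted 4-fold up in DKO across all cell
    types (rescued in TKO), the 20 aging genes 3-fold up in DKO, and the
    DKO cohort is myeloid-expanded (GMP/MEP over-represented).
    """
    from .signatures import AGING_SIGNATURE_GENES, HAEM_P53_GENES

    cell_types = {
        "LT-HSC": "stem",
        "ST-HSC": "stem",
        "MPP": "stem",
        "LMPP": "lymphoid",
        "GMP": "myeloid",
        "MEP": "myeloid",
    }
    rng = np.random.default_rng(seed + 1_000_003)
    n_genes = 1200
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    baseline = np.clip(baseline, 0.05, 60.0)
    names = [f"g{i:05d}" for i in range(n_genes)]
    # embed the packaged signature symbols among the simulated genes
    planted = list(HAEM_P53_GENES) + list(AGING_SIGNATURE_GENES)
    for i, sym in enumerate(planted):
        names[100 + i] = sym

    n_cells = {}
    base_n = overrides.pop("cells_per_combo", 60)
    myeloid_boost = {"GMP": 2.0, "MEP": 1.6}
    lymphoid_cut = {"LMPP": 0.5}
    for g in ("WT", "DKO", "TKO"):
        for ct in cell_types:
            n = base_n
            if g == "DKO":
                n = int(round(n * myeloid_boost.get(ct, 1.0) * lymphoid_cut.get(ct, 1.0)))
            n_cells[(g, ct)] = n

    effects = (
        PlantedEffect(
            name="p53_activation",
            genes=HAEM_P53_GENES,
            genotype="DKO",
            fold=4.0,
            marks_p53_active=True,
        ),
        PlantedEffect(
            name="aging_program",
            genes=AGING_SIGNATURE_GENES,
            genotype="DKO",
            fold=3.0,
        ),
    )
    cfg = SimConfig(
        n_cells_per_type=n_cells,
        cell_types=cell_types,
        genotypes=("WT", "DKO", "TKO"),
        baseline_means=baseline,
        dispersion=2.0,
        effects=effects,
        gene_names=tuple(names),
        frac_s=0.15,
        frac_g2m=0.10,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def simulate_hvg_dataset(
    n_cells: int = 500,
    n_genes: int = 1000,
    n_variable: int = 50,
    cv2_biol: float = 0.5,
    n_spikeins: int = 92,
    dispersion_tech: float = 20.0,
    library_size_spread: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Dataset for spike-in-calibrated HVG benchmarking.

    Null genes and spike-ins are pure NB technical noise with a common
    dispersion; ``n_variable`` genes receive an extra per-cell lognormal
    multiplier with squared coefficient of variation ``cv2_biol``.
    Returns the matrix and the boolean truth mask over biological genes.
    """
    rng = np.random.default_rng(seed)
    means = np.geomspace(0.5, 50.0, n_genes)
    rng.shuffle(means)
    sf = rng.lognormal(0.0, library_size_spread, size=n_cells)
    mu = sf[:, None] * means[None, :]
    truth = np.zeros(n_genes, dtype=bool)
    truth[rng.choice(n_genes, size=n_variable, replace=False)] = True
    sigma = np.sqrt(np.log1p(cv2_biol))
    biol = rng.lognormal(-sigma**2 / 2, sigma, size=(n_cells, n_variable))
    mu[:, truth] *= biol
    counts = rng.negative_binomial(
        dispersion_tech, dispersion_tech / (dispersion_tech + mu)
    )
    mu_s = sf[:, None] * default_spikein_means(n_spikeins)[None, :]
    spikes = rng.negative_binomial(
        dispersion_tech, dispersion_tech / (dispersion_tech + mu_s)
    )
    genes = pd.Index(
        [f"g{i:05d}" for i in range(n_genes)]
        + [f"ERCC-{i:05d}" for i in range(n_spikeins)]
    )
    mask = np.zeros(n_genes + n_spikeins, dtype=bool)
    mask[n_genes:] = True
    cells = pd.Index([f"c{i:05d}" for i in range(n_cells)])
    matrix = ExpressionMatrix(
        cells, genes, np.hstack([counts, spikes]), spikein_mask=mask
    )
    return matrix, truth


def simulate_survival_cohort(
    n: int,
    hr_high: float,
    frac_high: float = 0.25,
    censor_rate: float = 0.2,
    baseline_median_days: float = 365.0,
    hr_age: float = 1.0,
    hr_treatment: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival cohort with a score-defined high-risk group.

    Event times are exponential; subjects in the "high" group (the top
    ``frac_high`` of a continuous score) have hazard ``hr_high`` times the
    baseline. Censoring is an independent exponential with rate set so
    that roughly ``censor_rate`` of baseline subjects are censored.
    Optional covariate hazards (``hr_age`` for age > 60, ``hr_treatment``
    for prior treatment) default to no effect.

    Returns a table with columns subject_id, time, event, group,
    age_gt60, prior_treatment, score.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if hr_high <= 0:
        raise ValueError("hr_high must be positive")
    if not 0 < frac_high < 1:
        raise ValueError("frac_high must be in (0, 1)")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    n_high = int(round(n * frac_high))
    order = np.argsort(-score, kind="stable")
    high = np.zeros(n, dtype=bool)
    high[order[:n_high]] = True

    age = rng.random(n) < 0.5
    trt = rng.random(n) < 0.3
    lam0 = np.log(2) / baseline_median_days
    lam = lam0 * np.where(high, hr_high, 1.0)
    lam = lam * np.where(age, hr_age, 1.0) * np.where(trt, hr_treatment, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        lam_c = lam0 * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "subject_id": [f"subj{i:05d}" for i in range(n)],
            "time": time,
            "event": event,
            "group": np.where(high, "high", "low"),
            "age_gt60": age.astype(int),
            "prior_treatment": trt.astype(int),
            "score": score,
        }
    )
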