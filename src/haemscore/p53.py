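"""Deriving p53-dependent gene sets and related cohort summaries.

A candidate p53 target gene is called *dependent* in a cell type when its
expression is (a) higher in the stressed mutant than in wild type and
(b) restored toward wild-type level when p53 is additionally lost —
both assessed by one-sided rank-sum tests with Benjamini-Hochberg
correction within the candidate set. A gene enters the signature when it
is dependent in at least ``min_types`` cell types. This stratified
rank-based formulation replaces a GLM fit with genotype, cell-cycle and
cell-type terms: cell type is handled by stratification and cell-cycle
phase can be regressed out beforehand.

Also here: Pearson ranking of genes against a per-cell score, lineage
(myeloid/lymphoid/stem) proportion tables per genotype, and the paired
HSC-minus-tail telomere-length difference utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DependenceCall",
    "LineageTable",
    "rank_sum_test",
    "identify_p53_dependent_genes",
    "rank_score_correlated_genes",
    "lineage_proportions",
    "telomere_difference",
]


@dataclass
class DependenceCall:
    """Per-gene outcome of the p53-dependence pattern test."""

    gene: str
    up_vs_wt: dict[str, bool] = field(default_factory=dict)
    rescued_by_p53_loss: dict[str, bool] = field(default_factory=dict)
    dependent: dict[str, bool] = field(default_factory=dict)
    q_up: dict[str, float] = field(default_factory=dict)
    q_rescue: dict[str, float] = field(default_factory=dict)

    @property
    def n_dependent_types(self) -> int:
        return sum(self.dependent.values())


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon rank-sum test.

    Uses the exact null distribution when ``min(n, m) <= 8`` and there are
    no ties across the pooled sample; otherwise the normal approximation
    with tie and continuity corrections. Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def identify_p53_dependent_genes(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    candidates: list[str] | tuple[str, ...],
    genotypes: dict[str, str],
    cell_types: list[str] | None = None,
    min_types: int = 3,
    alpha: float = 0.05,
    min_cells: int = 5,
    layer: str = "log",
) -> list[DependenceCall]:
    """Call p53-dependent genes from a genotype-labeled, typed cohort.

    Parameters
    ----------
    genotypes
        Mapping with keys ``wt``, ``mutant``, ``mutant_p53null`` naming the
        genotype labels in ``meta["genotype"]``.
    candidates
        The candidate gene universe (e.g. a validated p53-target list);
        BH correction is applied within this set, per contrast and cell
        type.
    min_types
        A gene is selected when dependent in at least this many cell types.

    Returns calls for all candidates present in the matrix, sorted by
    ``n_dependent_types`` descending then gene symbol.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    for role in ("wt", "mutant", "mutant_p53null"):
        if role not in genotypes:
            raise ValueError(f"genotypes mapping missing role {role!r}")
        if genotypes[role] not in set(meta["genotype"]):
            raise ValueError(
                f"genotype {genotypes[role]!r} ({role}) absent from metadata"
            )
    if cell_types is None:
        cell_types = sorted(meta["cell_type"].dropna().unique())
    x = np.asarray(m.layer(layer), dtype=float)
    pos = {g: i for i, g in enumerate(m.genes)}
    present = [g for g in candidates if g in pos]
    calls = {g: DependenceCall(gene=g) for g in present}

    usable_types = 0
    for ct in cell_types:
        in_ct = (meta["cell_type"] == ct).to_numpy()
        grp = {
            role: in_ct & (meta["genotype"] == genotypes[role]).to_numpy()
            for role in ("wt", "mutant", "mutant_p53null")
        }
        if any(mask.sum() < min_cells for mask in grp.values()):
            logger.warning(
                "stage=dependence cell_type=%s skipped (fewer than %d cells "
                "in a genotype)", ct, min_cells,
            )
            continue
        usable_types += 1
        p_up, p_rescue = [], []
        for g in present:
            col = x[:, pos[g]]
            _, pu = rank_sum_test(col[grp["mutant"]], col[grp["wt"]], "greater")
            _, pr = rank_sum_test(
                col[grp["mutant"]], col[grp["mutant_p53null"]], "greater"
            )
            p_up.append(pu)
            p_rescue.append(pr)
        rej_up, q_up, *_ = multipletests(p_up, alpha=alpha, method="fdr_bh")
        rej_re, q_re, *_ = multipletests(p_rescue, alpha=alpha, method="fdr_bh")
        for g, ru, rr, qu, qr in zip(present, rej_up, rej_re, q_up, q_re):
            call = calls[g]
            call.up_vs_wt[ct] = bool(ru)
            call.rescued_by_p53_loss[ct] = bool(rr)
            call.dependent[ct] = bool(ru and rr)
            call.q_up[ct] = float(qu)
            call.q_rescue[ct] = float(qr)

    if usable_types < 2:
        raise ValueError(
            "need at least 2 cell types with sufficient cells per genotype"
        )
    out = sorted(calls.values(), key=lambda c: (-c.n_dependent_types, c.gene))
    return out


def selected_genes(calls: list[DependenceCall], min_types: int = 3) -> list[str]:
    """Genes dependent in at least ``min_types`` cell types (sorted as given)."""
    return [c.gene for c in calls if c.n_dependent_types >= min_types]


def rank_score_correlated_genes(
    m: ExpressionMatrix,
    scores: pd.Series,
    min_cells: int = 20,
    layer: str = "log",
) -> pd.DataFrame:
    """Rank genes by Pearson correlation with a per-cell score.

    Constant genes get ``r = NaN`` and are excluded from the ranking but
    kept in the output (flagged). Sort is descending r, ties broken by
    gene symbol for stability.
    """
    if m.n_cells < min_cells:
        raise ValueError(f"need at least {min_cells} cells, have {m.n_cells}")
    s = scores.loc[m.cells].to_numpy(dtype=float)
    x = np.asarray(m.layer(layer), dtype=float)[:, ~m.spikein_mask]
    xc = x - x.mean(axis=0)
    sc = s - s.mean()
    sd_x = x.std(axis=0)
    sd_s = s.std()
    is_const = x.max(axis=0) == x.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * sc[:, None]).mean(axis=0) / (sd_x * sd_s)
    r = np.where(is_const, np.nan, r)
    df = pd.DataFrame({"gene": m.bio_genes, "pearson_r": r, "constant": is_const})
    ranked = df[df["pearson_r"].notna()].sort_values(
        ["pearson_r", "gene"], ascending=[False, True], kind="stable"
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    out = ranked.set_index("gene").reindex(df["gene"])
    out["constant"] = df.set_index("gene")["constant"]
    return out.reset_index()


@dataclass
class LineageTable:
    """Cell-type and lineage-class composition per genotype."""

    by_type: pd.DataFrame  # genotype, cell_type, count, proportion
    by_class: pd.DataFrame  # genotype, lineage, count, proportion


def lineage_proportions(
    meta: pd.DataFrame, lineage_map: dict[str, str]
) -> LineageTable:
    """Counts and proportions per (genotype, cell type) with class rollups.

    Every assigned cell type must appear in ``lineage_map``. A genotype
    with zero typed cells yields explicit zero-count rows rather than a
    division by zero.
    """
    typed = meta.dropna(subset=["cell_type"])
    unmapped = sorted(set(typed["cell_type"]) - set(lineage_map))
    if unmapped:
        raise ValueError(f"cell types missing from lineage_map: {unmapped}")
    genotypes = list(pd.unique(meta["genotype"]))
    cell_types = list(lineage_map)
    rows = []
    for g in genotypes:
        sub = typed[typed["genotype"] == g]
        total = len(sub)
        for ct in cell_types:
            n = int((sub["cell_type"] == ct).sum())
            rows.append(
                {
                    "genotype": g,
                    "cell_type": ct,
                    "lineage": lineage_map[ct],
                    "count": n,
                    "proportion": n / total if total else 0.0,
                }
            )
    by_type = pd.DataFrame(rows)
    by_class = (
        by_type.groupby(["genotype", "lineage"], sort=False, as_index=False)[
            ["count", "proportion"]
        ].sum()
    )
    return LineageTable(by_type=by_type, by_class=by_class)


def telomere_difference(
    hsc_lengths: pd.Series, tail_lengths: pd.Series
) -> pd.Series:
    """Per-mouse telomere difference: HSC length minus paired tail length.

    Series are matched by index (mouse id); any unmatched id raises.
    """
    only_hsc = hsc_lengths.index.difference(tail_lengths.index)
    only_tail = tail_lengths.index.difference(hsc_lengths.index)
    if len(only_hsc) or len(only_tail):
        raise ValueError(
            f"unmatched mouse ids: hsc-only={list(only_hsc)}, "
            f"tail-only={list(only_tail)}"
        )
    return (hsc_lengths - tail_lengths.loc[hsc_lengths.index]).rename(
        "telomere_difference"
    )
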