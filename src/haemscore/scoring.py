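"""Control-referenced gene-set scoring and cell-cycle phase assignment.

A signature score for a cell is the mean expression of the signature
genes minus the mean expression of a control gene set in the same cell.
Controls come either from a fixed, user-supplied reference pool, or —
the default — from expression-matched bins: all genes are ranked by mean
expression across cells, cut into ``n_bins`` equal-size bins, and for
each signature gene ``ctrl_per_gene`` control genes are sampled without
replacement from that gene's bin (the union, de-duplicated, forms the
control set). Matching controls on expression level prevents the score
from simply tracking library depth or detection rate.

Scores are computed on the scaled (z-scored) log layer by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSignature
from .signatures import aging_signature, haem_p53_signature

__all__ = [
    "ScoreResult",
    "score_gene_set",
    "aging_signature_score",
    "haem_p53_score",
    "assign_cell_cycle_phase",
]


@dataclass
class ScoreResult:
    """Per-cell scores plus the bookkeeping needed to reproduce them."""

    name: str
    scores: pd.Series
    genes_used: int
    genes_missing: list[str]
    control_genes: list[str]
    seed: int | None


def _bin_matched_controls(
    means: np.ndarray,
    genes: pd.Index,
    sig_idx: np.ndarray,
    n_bins: int,
    ctrl_per_gene: int,
    seed: int,
) -> list[str]:
    """Sample expression-matched control genes for each signature gene."""
    order = np.argsort(means, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(means))
    bin_of = rank * n_bins // len(means)  # equal-size bins by rank
    rng = np.random.default_rng(seed)
    sig_set = set(sig_idx.tolist())
    controls: set[int] = set()
    for gi in sig_idx:
        candidates = np.nonzero(bin_of == bin_of[gi])[0]
        candidates = candidates[[c not in sig_set for c in candidates]]
        if candidates.size == 0:
            continue
        take = min(ctrl_per_gene, candidates.size)
        controls.update(rng.choice(candidates, size=take, replace=False).tolist())
    return [genes[i] for i in sorted(controls)]


def score_gene_set(
    m: ExpressionMatrix,
    sig: GeneSignature,
    layer: str = "scaled",
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: int = 0,
) -> ScoreResult:
    """Score each cell for a gene set against matched or fixed controls.

    With ``sig.reference_pool`` set, the control mean is taken over that
    fixed pool; otherwise controls are sampled from expression-matched
    bins (seeded, deterministic). Spike-in genes never participate.

    At least half of the signature genes must be present in the matrix;
    missing genes are dropped with a warning above that floor and raise
    below it.
    """
    x = np.asarray(m.layer(layer), dtype=float)
    bio = ~m.spikein_mask
    genes = m.genes[bio]
    x = x[:, bio]
    pos = {g: i for i, g in enumerate(genes)}

    present = [g for g in sig.genes if g in pos]
    missing = [g for g in sig.genes if g not in pos]
    if len(present) < 0.5 * len(sig.genes) or not present:
        raise ValueError(
            f"fewer than half of signature {sig.name!r} genes present; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} genes absent, "
            f"scoring on {len(present)}: missing {missing}",
            stacklevel=2,
        )
    sig_idx = np.array([pos[g] for g in present])

    if sig.reference_pool is not None:
        ctrl = [g for g in sig.reference_pool if g in pos]
        if not ctrl:
            raise ValueError("no reference-pool genes present in the matrix")
        ctrl_idx = np.array([pos[g] for g in ctrl])
        used_seed = None
    else:
        means = x.mean(axis=0)
        ctrl = _bin_matched_controls(means, genes, sig_idx, n_bins, ctrl_per_gene, seed)
        if not ctrl:  # every bin-mate is a signature gene; widen to all others
            ctrl = [g for g in genes if g not in set(present)]
        ctrl_idx = np.array([pos[g] for g in ctrl])
        used_seed = seed

    scores = x[:, sig_idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)
    return ScoreResult(
        name=sig.name,
        scores=pd.Series(scores, index=m.cells, name=sig.name),
        genes_used=len(present),
        genes_missing=missing,
        control_genes=list(ctrl),
        seed=used_seed,
    )


def aging_signature_score(
    m: ExpressionMatrix, layer: str = "scaled", seed: int = 0, **kwargs
) -> ScoreResult:
    """Score the packaged 20-gene HSC Aging Signature."""
    return score_gene_set(m, aging_signature(), layer=layer, seed=seed, **kwargs)


def haem_p53_score(
    m: ExpressionMatrix,
    layer: str = "scaled",
    reference_pool: tuple[str, ...] | None = None,
    species: str = "mouse",
    seed: int = 0,
    **kwargs,
) -> ScoreResult:
    """Score the packaged 16-gene Haem p53Score signature.

    Pass ``species="human"`` for matrices with human gene symbols, and
    optionally a fixed ``reference_pool`` (e.g. a curated ~694-gene control
    list) instead of bin-matched sampling.
    """
    sig = haem_p53_signature(reference_pool=reference_pool, species=species)
    return score_gene_set(m, sig, layer=layer, seed=seed, **kwargs)


def assign_cell_cycle_phase(
    m: ExpressionMatrix,
    s_genes: list[str] | tuple[str, ...],
    g2m_genes: list[str] | tuple[str, ...],
    layer: str = "scaled",
    seed: int = 0,
) -> pd.DataFrame:
    """Assign G1 / S / G2M phases from S- and G2M-program scores.

    Each program is scored with :func:`score_gene_set`; a cell is G1 when
    both scores are negative, otherwise it takes the label of the larger
    score (exact ties resolve to G2M — documented, deterministic).

    Returns a DataFrame with columns ``phase``, ``s_score``, ``g2m_score``.
    """
    bio_genes = set(m.bio_genes)
    s_present = [g for g in s_genes if g in bio_genes]
    g2m_present = [g for g in g2m_genes if g in bio_genes]
    if not s_present or not g2m_present:
        raise ValueError("cell-cycle gene lists do not intersect matrix genes")
    s = score_gene_set(
        m, GeneSignature("s_phase", tuple(s_present)), layer=layer, seed=seed
    ).scores
    g2m = score_gene_set(
        m, GeneSignature("g2m_phase", tuple(g2m_present)), layer=layer, seed=seed + 1
    ).scores
    phase = np.where(
        (s < 0) & (g2m < 0), "G1", np.where(s > g2m, "S", "G2M")
    )
    return pd.DataFrame(
        {"phase": phase, "s_score": s, "g2m_score": g2m}, index=m.cells
    )
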