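"""Cell QC, normalization, log transform, scaling and covariate regression.

The processing chain mirrors the standard plate-/droplet-based workflow:
filter low-quality cells on detected genes, mitochondrial fraction,
spike-in fraction and total reads; normalize biological genes to a fixed
total per cell (10K by default); natural-log transform with pseudocount 1;
z-score genes; optionally regress out nuisance covariates (cell-cycle
phase) by per-gene ordinary least squares.

All operations are pure: they return new objects and never mutate inputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, QCThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "compute_qc_metrics",
    "qc_filter_cells",
    "normalize_counts",
    "log_transform",
    "scale_genes",
    "regress_out_covariates",
]


def compute_qc_metrics(
    m: ExpressionMatrix, meta: pd.DataFrame, mito_prefix: str = "mt-"
) -> pd.DataFrame:
    """Fill per-cell QC columns from the counts.

    ``n_genes_detected`` and ``total_counts`` are over biological genes;
    ``pct_mito`` is the fraction of biological counts on genes whose symbol
    starts with ``mito_prefix`` (case-insensitive); ``pct_spikein`` is the
    spike-in fraction of all counts.
    """
    meta = meta.copy()
    bio = ~m.spikein_mask
    bio_counts = m.counts[:, bio]
    total_bio = bio_counts.sum(axis=1)
    total_all = m.counts.sum(axis=1)
    meta["n_genes_detected"] = (bio_counts > 0).sum(axis=1)
    meta["total_counts"] = total_bio
    mito = np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in m.genes]
    ) & bio
    with np.errstate(invalid="ignore", divide="ignore"):
        meta["pct_mito"] = np.where(
            total_bio > 0, m.counts[:, mito].sum(axis=1) / np.maximum(total_bio, 1), 0.0
        )
        meta["pct_spikein"] = np.where(
            total_all > 0,
            m.counts[:, m.spikein_mask].sum(axis=1) / np.maximum(total_all, 1),
            0.0,
        )
    return meta


def qc_filter_cells(
    m: ExpressionMatrix, meta: pd.DataFrame, thresholds: QCThresholds
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain exactly the cells passing every set threshold (order kept).

    ``min_*`` thresholds keep cells at or above the cutoff; ``max_*``
    thresholds remove cells strictly above it. One structured log line is
    emitted per criterion reporting how many cells it removed.

    Raises ``ValueError`` naming the most binding criterion if no cell
    survives.
    """
    if meta[["n_genes_detected", "total_counts"]].isna().any().any():
        meta = compute_qc_metrics(m, meta)
    keep = np.ones(m.n_cells, dtype=bool)
    removed_by: dict[str, int] = {}

    def apply(name: str, mask_fail: np.ndarray) -> None:
        nonlocal keep
        removed_by[name] = int((keep & mask_fail).sum())
        keep &= ~mask_fail
        logger.info("stage=qc removed=%d criterion=%s", removed_by[name], name)

    t = thresholds
    if t.min_genes is not None:
        apply("min_genes", meta["n_genes_detected"].to_numpy() < t.min_genes)
    if t.max_pct_mito is not None:
        apply("max_pct_mito", meta["pct_mito"].to_numpy() > t.max_pct_mito)
    if t.min_total is not None:
        apply("min_total", meta["total_counts"].to_numpy() < t.min_total)
    if t.max_total is not None:
        apply("max_total", meta["total_counts"].to_numpy() > t.max_total)
    if t.max_pct_spikein is not None:
        apply("max_pct_spikein", meta["pct_spikein"].to_numpy() > t.max_pct_spikein)

    if not keep.any():
        binding = max(removed_by, key=removed_by.get)
        raise ValueError(
            f"QC removed all {m.n_cells} cells; most binding criterion: {binding}"
        )
    return m.subset_cells(keep), meta.loc[keep].copy()


def normalize_counts(
    m: ExpressionMatrix, target_sum: float = 10_000.0, source: str = "counts"
) -> ExpressionMatrix:
    """Scale each cell so its biological genes total ``target_sum``.

    Spike-ins are excluded from the denominator but scaled by the same
    per-cell factor, so within-cell ratios are preserved. Result stored as
    layer ``"norm10k"``.
    """
    x = np.asarray(m.layer(source), dtype=float)
    bio_total = x[:, ~m.spikein_mask].sum(axis=1)
    if np.any(bio_total <= 0):
        bad = list(m.cells[bio_total <= 0][:5])
        raise ValueError(
            f"cells with zero biological counts (e.g. {bad}); run QC filtering first"
        )
    norm = x * (target_sum / bio_total)[:, None]
    return m.with_layer("norm10k", norm)


def log_transform(m: ExpressionMatrix, source: str = "norm10k") -> ExpressionMatrix:
    """Natural log of (value + 1), stored as layer ``"log"``."""
    x = np.asarray(m.layer(source), dtype=float)
    if np.any(x < 0):
        raise ValueError("log transform requires non-negative input")
    return m.with_layer("log", np.log1p(x))


def scale_genes(m: ExpressionMatrix, source: str = "log") -> ExpressionMatrix:
    """Z-score each gene across cells (population sd); constant genes map
    to all-zeros. Stored as layer ``"scaled"``."""
    x = np.asarray(m.layer(source), dtype=float)
    if x.shape[0] < 2:
        raise ValueError("scaling requires at least 2 cells")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    # exact constancy check: accumulated rounding can make sd of a constant
    # column slightly nonzero, which would explode the z-scores
    sd = np.where(x.max(axis=0) == x.min(axis=0), 0.0, sd)
    centred = x - mu
    scaled = np.divide(centred, sd, out=np.zeros_like(centred), where=sd > 0)
    return m.with_layer("scaled", scaled)


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names: list[str] = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(dtype=float))
                names.append(str(dcol))
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(str(name))
    return np.column_stack(cols), names


def regress_out_covariates(
    m: ExpressionMatrix,
    covariates: pd.DataFrame | pd.Series,
    source: str = "log",
    target: str | None = None,
) -> ExpressionMatrix:
    """Replace expression by per-gene OLS residuals on the covariates.

    Categorical covariates are expanded to indicator columns; an intercept
    is always included, so residuals are mean-centred and orthogonal to
    every covariate column. Raises on a rank-deficient design, naming the
    collinear columns.
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    covariates = covariates.loc[m.cells]
    X, names = _design_matrix(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    y = np.asarray(m.layer(source), dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ beta
    return m.with_layer(target or source, residuals)
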