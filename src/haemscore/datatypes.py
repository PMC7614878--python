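"""Core in-memory containers for the HSPC expression analysis.

The central object is :class:`ExpressionMatrix`, a cells x genes count
matrix with named derived layers (``norm10k``, ``log``, ``scaled``, ...)
and a boolean partition separating biological genes from ERCC-like
technical spike-ins. Per-cell annotations (genotype, QC statistics,
cell-cycle phase, assigned cell type, signature scores) live in a plain
``pandas.DataFrame`` indexed by cell id, referred to throughout as the
*cell metadata* table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "QCThresholds",
    "new_cell_meta",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes counts plus derived real-valued layers.

    Parameters
    ----------
    cells
        Ordered unique cell identifiers (length ``n_cells``).
    genes
        Ordered unique gene identifiers (length ``n_genes``).
    counts
        Non-negative integer array of shape ``(n_cells, n_genes)``.
    layers
        Named float arrays with the same shape as ``counts``.
    spikein_mask
        Boolean array per gene; True marks a technical spike-in. Spike-ins
        are excluded from biological-gene operations unless explicitly
        requested.
    """

    cells: pd.Index
    genes: pd.Index
    counts: np.ndarray
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    spikein_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells, name="cell_id")
        self.genes = pd.Index(self.genes, name="gene")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.cells.is_unique:
            raise ValueError("cell identifiers must be unique")
        if not self.genes.is_unique:
            raise ValueError("gene identifiers must be unique")
        if self.spikein_mask is None:
            self.spikein_mask = np.zeros(len(self.genes), dtype=bool)
        self.spikein_mask = np.asarray(self.spikein_mask, dtype=bool)
        if self.spikein_mask.shape != (len(self.genes),):
            raise ValueError("spikein_mask length must equal number of genes")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape mismatch")

    # -- convenience -----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def bio_genes(self) -> pd.Index:
        """Biological (non-spike-in) gene identifiers."""
        return self.genes[~self.spikein_mask]

    def layer(self, name: str) -> np.ndarray:
        """Return a named layer; ``"counts"`` returns the raw counts."""
        if name == "counts":
            return self.counts
        if name not in self.layers:
            raise KeyError(
                f"layer {name!r} not present; available: "
                f"{['counts', *self.layers]}"
            )
        return self.layers[name]

    def with_layer(self, name: str, values: np.ndarray) -> "ExpressionMatrix":
        """Return a copy with an added/replaced layer (inputs not mutated)."""
        if values.shape != self.counts.shape:
            raise ValueError(f"layer {name!r} shape mismatch")
        layers = dict(self.layers)
        layers[name] = values
        return ExpressionMatrix(
            self.cells, self.genes, self.counts, layers, self.spikein_mask.copy()
        )

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by boolean mask or positional index, order preserved."""
        return ExpressionMatrix(
            self.cells[keep],
            self.genes,
            self.counts[keep],
            {k: v[keep] for k, v in self.layers.items()},
            self.spikein_mask.copy(),
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named gene list, optionally with a fixed control/reference pool.

    When ``reference_pool`` is set, scoring subtracts the mean expression of
    that fixed pool; otherwise controls are drawn from expression-matched
    bins at scoring time.
    """

    name: str
    genes: tuple[str, ...]
    reference_pool: tuple[str, ...] | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("signature gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.reference_pool is not None:
            overlap = set(self.genes) & set(self.reference_pool)
            if overlap:
                raise ValueError(
                    f"reference pool overlaps signature genes: {sorted(overlap)}"
                )


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs. ``min_*`` are inclusive (>= keeps the cell);
    ``max_*`` remove cells strictly above the cutoff. Unset thresholds are
    not applied."""

    min_genes: int | None = None
    max_pct_mito: float | None = None
    min_total: int | None = None
    max_total: int | None = None
    max_pct_spikein: float | None = None

    def __post_init__(self) -> None:
        if (
            self.min_total is not None
            and self.max_total is not None
            and not self.min_total < self.max_total
        ):
            raise ValueError("min_total must be < max_total when both set")


META_COLUMNS = [
    "genotype",
    "sample",
    "n_genes_detected",
    "total_counts",
    "pct_mito",
    "pct_spikein",
    "phase",
    "cell_type",
]


def new_cell_meta(cells: pd.Index, genotype: str | pd.Series = "unknown",
                  sample: str | pd.Series = "s1") -> pd.DataFrame:
    """Create an empty per-cell metadata table with the canonical columns."""
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["genotype"] = genotype
    meta["sample"] = sample
    for col in META_COLUMNS[2:]:
        meta[col] = np.nan
    return meta
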