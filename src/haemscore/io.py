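"""Reading and writing the package's on-disk formats.

Count matrices travel as a Matrix Market triplet directory
(``matrix.mtx`` genes-agnostic COO counts, 1-based per the MTX standard;
``genes.tsv`` with columns gene / is_spikein; ``barcodes.tsv`` one cell id
per line) plus a ``cellmeta.tsv`` sidecar, or as a dense CSV whose header
row holds gene symbols (``ERCC-`` prefixed genes are treated as
spike-ins). Survival tables and signature files are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionMatrix, GeneSignature, new_cell_meta

__all__ = [
    "write_matrix",
    "read_matrix",
    "read_survival_table",
    "write_survival_table",
    "read_signature",
    "write_signature",
]


def write_matrix(m: ExpressionMatrix, meta: pd.DataFrame, outdir: str | Path) -> Path:
    """Write MTX + genes.tsv + barcodes.tsv + cellmeta.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # MTX stores genes x cells (rows = features), matching common tooling
    spio.mmwrite(
        outdir / "matrix.mtx",
        sparse.coo_matrix(m.counts.T),
        field="integer",
    )
    pd.DataFrame(
        {"gene": m.genes, "is_spikein": m.spikein_mask.astype(int)}
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(m.cells).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta.to_csv(outdir / "cellmeta.tsv", sep="\t")
    return outdir


def _read_mtx_dir(path: Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    mat = spio.mmread(path / "matrix.mtx")
    genes_df = pd.read_csv(path / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    n_genes_declared, n_cells_declared = mat.shape
    if len(genes_df) != n_genes_declared:
        raise ValueError(
            f"matrix.mtx declares {n_genes_declared} genes but genes.tsv has "
            f"{len(genes_df)} lines (line {len(genes_df) + 1} expected)"
        )
    if len(barcodes) != n_cells_declared:
        raise ValueError(
            f"matrix.mtx declares {n_cells_declared} cells but barcodes.tsv has "
            f"{len(barcodes)} lines (line {len(barcodes) + 1} expected)"
        )
    counts = np.asarray(mat.todense()).T.astype(np.int64)
    spike = (
        genes_df["is_spikein"].to_numpy(dtype=bool)
        if "is_spikein" in genes_df
        else genes_df["gene"].str.startswith("ERCC").to_numpy()
    )
    m = ExpressionMatrix(
        pd.Index(barcodes), pd.Index(genes_df["gene"]), counts, spikein_mask=spike
    )
    meta_path = path / "cellmeta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if not meta.index.equals(m.cells):
            meta = meta.reindex(m.cells)
    else:
        meta = new_cell_meta(m.cells)
    return m, meta


def _read_dense_csv(path: Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    df = pd.read_csv(path, index_col=0)
    spike = np.asarray(df.columns.str.startswith("ERCC"))
    m = ExpressionMatrix(
        pd.Index(df.index.astype(str)),
        pd.Index(df.columns),
        df.to_numpy(dtype=np.int64),
        spikein_mask=spike,
    )
    return m, new_cell_meta(m.cells)


def read_matrix(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Load a count matrix from an MTX directory or a dense CSV file.

    Round-trips :func:`write_matrix` exactly for counts and metadata.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix == ".csv":
        return _read_dense_csv(path)
    raise ValueError(f"unrecognised matrix input: {path}")


SURVIVAL_COLUMNS = ["subject_id", "time", "event"]


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Load a survival CSV; requires subject_id, time, event columns."""
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in survival table")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    df["event"] = df["event"].astype(bool)
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Load a signature from a two-column CSV (symbol, role).

    ``role`` is ``gene`` or ``reference``; a headerless one-symbol-per-line
    file is read as all signature genes.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if "," in first:
        df = pd.read_csv(path)
        sym_col, role_col = df.columns[:2]
        genes = tuple(df.loc[df[role_col] == "gene", sym_col])
        pool = tuple(df.loc[df[role_col] == "reference", sym_col]) or None
    else:
        genes = tuple(s.strip() for s in path.read_text().splitlines() if s.strip())
        pool = None
    return GeneSignature(name=name or path.stem, genes=genes, reference_pool=pool)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    rows = [{"symbol": g, "role": "gene"} for g in sig.genes]
    if sig.reference_pool:
        rows += [{"symbol": g, "role": "reference"} for g in sig.reference_pool]
    pd.DataFrame(rows).to_csv(path, index=False)
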