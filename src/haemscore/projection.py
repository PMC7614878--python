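"""Reference-landscape cell typing and highly-variable-gene selection.

Cell types are assigned by projecting query transcriptomes into the PCA
space of an annotated reference landscape and taking a majority vote over
the 15 nearest reference cells (Euclidean distance in PC space). A
two-tier scheme refines coarse stem/immature labels with a second,
finer-grained landscape.

Two HVG selectors are provided for building landscapes: the
spike-in-calibrated method, which fits the technical squared coefficient
of variation CV2_tech(mu) = a1/mu + a0 on ERCC-like spike-ins by Gamma
GLM and tests each biological gene's observed variance against the fitted
technical expectation plus a minimum biological dispersion (chi-squared
ratio test, Benjamini-Hochberg FDR); and a mean/dispersion-threshold
fallback with bin-normalized dispersions for data without spike-ins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

__all__ = [
    "HVGResult",
    "ReferenceLandscape",
    "select_hvg_spikein",
    "fallback_hvg_dispersion",
    "fit_reference_pca",
    "project_onto_reference",
    "knn_label_transfer",
    "hierarchical_cell_typing",
    "save_landscape",
    "load_landscape",
]


@dataclass
class HVGResult:
    """Per-gene variability statistics and the selected set."""

    table: pd.DataFrame  # index gene; columns mean, cv2, cv2_tech, pvalue, qvalue, selected
    method: str

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def _size_normalize(counts: np.ndarray) -> np.ndarray:
    """Divide each cell by its total relative to the mean total."""
    totals = counts.sum(axis=1).astype(float)
    totals = np.where(totals > 0, totals, 1.0)
    return counts / (totals / totals.mean())[:, None]


def select_hvg_spikein(
    m: ExpressionMatrix, fdr: float = 0.1, min_biol_disp: float = 0.25
) -> HVGResult:
    """Spike-in-calibrated HVG selection on raw counts.

    Spike-ins and biological genes are depth-normalized separately (their
    own totals), the technical CV2-vs-mean relation is fitted on the
    spike-ins by Gamma GLM with identity link, and each biological gene's
    variance is tested against the fitted technical variance inflated by
    ``min_biol_disp`` using the chi-squared ratio test; selection is at
    Benjamini-Hochberg FDR ``fdr``.
    """
    spikes = m.counts[:, m.spikein_mask].astype(float)
    usable = (spikes.mean(axis=0) > 0).sum()
    if usable < 10:
        raise ValueError(
            f"only {usable} spike-ins with nonzero mean (need >= 10); "
            "use fallback_hvg_dispersion instead"
        )
    n = m.n_cells
    s_norm = _size_normalize(spikes)
    mu_s = s_norm.mean(axis=0)
    keep = mu_s > 0
    cv2_s = s_norm.var(axis=0, ddof=1)[keep] / mu_s[keep] ** 2
    mu_s = mu_s[keep]

    # fit CV2_tech = a1/mu + a0 on spike-ins (Gamma GLM, identity link)
    import statsmodels.api as sm

    X = np.column_stack([1.0 / mu_s, np.ones_like(mu_s)])
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identity link on Gamma is intended here
            fit = sm.GLM(
                cv2_s, X, family=sm.families.Gamma(sm.families.links.Identity())
            )
            res = fit.fit(start_params=np.array([1.0, 0.05]), maxiter=200)
        a1, a0 = res.params
    except Exception:  # fall back to least squares on the same model
        a1, a0 = np.linalg.lstsq(X, cv2_s, rcond=None)[0]
    a1 = max(float(a1), 1e-12)
    a0 = max(float(a0), 1e-12)

    bio = m.counts[:, ~m.spikein_mask].astype(float)
    b_norm = _size_normalize(bio)
    mu = b_norm.mean(axis=0)
    var = b_norm.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, 0.0)
    cv2_tech = np.where(mu > 0, a1 / np.maximum(mu, 1e-300) + a0, np.inf)

    # chi-squared ratio test of observed variance vs inflated technical variance
    omega = a0 + min_biol_disp + a0 * min_biol_disp
    denom = (mu * a1 + mu**2 * omega) / (1.0 + omega / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        statv = np.where(denom > 0, var * (n - 1) / denom, 0.0)
    pval = stats.chi2.sf(statv, df=n - 1)
    pval = np.where(mu > 0, pval, 1.0)
    reject, qval, *_ = multipletests(pval, alpha=fdr, method="fdr_bh")

    table = pd.DataFrame(
        {
            "mean": mu,
            "cv2": cv2,
            "cv2_tech": cv2_tech,
            "pvalue": pval,
            "qvalue": qval,
            "selected": reject,
        },
        index=m.bio_genes,
    )
    return HVGResult(table=table, method="spikein")


def fallback_hvg_dispersion(
    m: ExpressionMatrix,
    min_mean: float = 0.02,
    max_mean: float = 3.0,
    min_disp: float = 0.3,
    n_mean_bins: int = 20,
    layer: str = "log",
) -> HVGResult:
    """Mean/dispersion-threshold HVG selection on log data (no spike-ins).

    Means and dispersions (variance/mean) are computed on the de-logged
    layer; dispersions are z-scored within 20 equal-width mean bins and
    genes inside the mean window with normalized dispersion above
    ``min_disp`` are selected.
    """
    x = np.expm1(np.asarray(m.layer(layer), dtype=float)[:, ~m.spikein_mask])
    mu = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, var / mu, np.nan)
    in_window = (mu > min_mean) & (mu < max_mean)
    if not in_window.any():
        raise ValueError("all genes fall outside the [min_mean, max_mean] window")

    log_mu = np.log1p(mu)
    bins = pd.cut(pd.Series(log_mu), bins=n_mean_bins, labels=False)
    disp_norm = np.full_like(mu, np.nan)
    for b in range(n_mean_bins):
        idx = np.nonzero((bins == b).to_numpy() & np.isfinite(disp))[0]
        if idx.size == 0:
            continue
        d = disp[idx]
        sd = d.std(ddof=1) if idx.size > 1 else 0.0
        disp_norm[idx] = (d - d.mean()) / sd if sd > 0 else 0.0

    selected = in_window & (np.nan_to_num(disp_norm, nan=-np.inf) > min_disp)
    table = pd.DataFrame(
        {
            "mean": mu,
            "cv2": np.where(mu > 0, var / mu**2, 0.0),
            "cv2_tech": np.nan,
            "pvalue": np.nan,
            "qvalue": np.nan,
            "dispersion_norm": disp_norm,
            "selected": selected,
        },
        index=m.bio_genes,
    )
    return HVGResult(table=table, method="dispersion")


@dataclass
class ReferenceLandscape:
    """An annotated reference PCA space.

    ``loadings`` has orthonormal columns (HVGs x components); query cells
    are centred with ``gene_means`` (the reference means) before
    projection, so the query lands in the same coordinate frame.
    """

    genes: pd.Index  # the HVGs, in loading row order
    gene_means: np.ndarray
    loadings: np.ndarray  # (n_hvgs, n_components)
    ref_coords: np.ndarray  # (n_ref_cells, n_components)
    labels: pd.Series  # per reference cell
    n_components: int

    def __post_init__(self) -> None:
        gtg = self.loadings.T @ self.loadings
        if not np.allclose(gtg, np.eye(self.n_components), atol=1e-6):
            raise ValueError("loadings columns must be orthonormal")
        if len(self.labels) != self.ref_coords.shape[0]:
            raise ValueError("labels must cover all reference cells")


def fit_reference_pca(
    ref: ExpressionMatrix,
    labels: pd.Series,
    hvgs: pd.Index | list[str],
    n_components: int = 50,
    layer: str = "log",
) -> ReferenceLandscape:
    """Build a landscape from reference expression restricted to its HVGs."""
    hvgs = pd.Index(hvgs)
    pos = ref.genes.get_indexer(hvgs)
    if (pos < 0).any():
        raise ValueError("HVGs missing from the reference matrix")
    x = np.asarray(ref.layer(layer), dtype=float)[:, pos]
    max_rank = min(x.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(#cells, #HVGs)={max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    return ReferenceLandscape(
        genes=hvgs,
        gene_means=pca.mean_,
        loadings=pca.components_.T,
        ref_coords=coords,
        labels=pd.Series(labels, index=ref.cells),
        n_components=n_components,
    )


def project_onto_reference(
    query: ExpressionMatrix, landscape: ReferenceLandscape, layer: str = "log"
) -> np.ndarray:
    """Project query cells into the landscape's PC space.

    Query expression is centred with the *reference* gene means and
    multiplied by the stored loadings. HVGs absent from the query are
    imputed at the reference mean (zero after centring); fewer than 80%
    coverage raises.
    """
    pos = query.genes.get_indexer(landscape.genes)
    coverage = float((pos >= 0).mean())
    if coverage < 0.8:
        raise ValueError(
            f"query covers only {coverage:.0%} of landscape HVGs (need >= 80%)"
        )
    x = np.asarray(query.layer(layer), dtype=float)
    centred = np.zeros((query.n_cells, len(landscape.genes)))
    present = pos >= 0
    centred[:, present] = (
        x[:, pos[present]] - landscape.gene_means[present][None, :]
    )
    return centred @ landscape.loadings


def knn_label_transfer(
    query_coords: np.ndarray, landscape: ReferenceLandscape, k: int = 15
) -> pd.DataFrame:
    """Majority-vote label transfer over the k nearest reference cells.

    Ties on vote count break to the class with the smaller summed neighbor
    distance, then lexicographically. Returns a DataFrame with the
    assigned ``label`` and per-class vote counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > landscape.ref_coords.shape[0]:
        raise ValueError("k exceeds the number of reference cells")
    nn = NearestNeighbors(n_neighbors=k).fit(landscape.ref_coords)
    dist, idx = nn.kneighbors(np.asarray(query_coords, dtype=float))
    ref_labels = landscape.labels.to_numpy()

    out_labels: list[str] = []
    tallies: list[dict[str, int]] = []
    for d_row, i_row in zip(dist, idx):
        votes: dict[str, int] = {}
        dsum: dict[str, float] = {}
        for d, i in zip(d_row, i_row):
            lab = ref_labels[i]
            votes[lab] = votes.get(lab, 0) + 1
            dsum[lab] = dsum.get(lab, 0.0) + d
        best = sorted(votes, key=lambda lab: (-votes[lab], dsum[lab], lab))[0]
        out_labels.append(best)
        tallies.append(votes)
    return pd.DataFrame({"label": out_labels, "votes": tallies})


def hierarchical_cell_typing(
    query: ExpressionMatrix,
    key_landscape: ReferenceLandscape,
    refinement_landscape: ReferenceLandscape | None,
    refine_labels: set[str] = frozenset({"HSC", "Immature"}),
    k: int = 15,
    layer: str = "log",
) -> pd.Series:
    """Two-tier cell typing: key landscape first, then refinement.

    Every cell is labeled by the key landscape; cells whose key label is in
    ``refine_labels`` (the stem/immature compartment) are re-labeled by the
    finer-grained refinement landscape. Other labels are final.
    """
    key_coords = project_onto_reference(query, key_landscape, layer=layer)
    labels = pd.Series(
        knn_label_transfer(key_coords, key_landscape, k=k)["label"].to_numpy(),
        index=query.cells,
        name="cell_type",
    )
    if refinement_landscape is None:
        import warnings

        warnings.warn("no refinement landscape; returning key labels", stacklevel=2)
        return labels
    to_refine = labels.isin(refine_labels).to_numpy()
    if to_refine.any():
        sub = query.subset_cells(to_refine)
        sub_coords = project_onto_reference(sub, refinement_landscape, layer=layer)
        fine = knn_label_transfer(sub_coords, refinement_landscape, k=k)
        labels.iloc[np.nonzero(to_refine)[0]] = fine["label"].to_numpy()
    return labels


def save_landscape(landscape: ReferenceLandscape, outdir: str | Path) -> Path:
    """Serialize a landscape: loadings CSV (genes x components), centering
    means CSV, reference coordinates CSV, labels TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp_cols = [f"PC{i+1}" for i in range(landscape.n_components)]
    pd.DataFrame(landscape.loadings, index=landscape.genes, columns=comp_cols).to_csv(
        outdir / "loadings.csv"
    )
    pd.Series(landscape.gene_means, index=landscape.genes, name="mean").to_csv(
        outdir / "means.csv"
    )
    pd.DataFrame(
        landscape.ref_coords, index=landscape.labels.index, columns=comp_cols
    ).to_csv(outdir / "ref_coords.csv")
    landscape.labels.rename("cell_type").to_csv(outdir / "labels.tsv", sep="\t")
    return outdir


def load_landscape(path: str | Path) -> ReferenceLandscape:
    path = Path(path)
    loadings = pd.read_csv(path / "loadings.csv", index_col=0)
    means = pd.read_csv(path / "means.csv", index_col=0)["mean"]
    coords = pd.read_csv(path / "ref_coords.csv", index_col=0)
    labels = pd.read_csv(path / "labels.tsv", sep="\t", index_col=0)["cell_type"]
    return ReferenceLandscape(
        genes=loadings.index,
        gene_means=means.to_numpy(),
        loadings=loadings.to_numpy(),
        ref_coords=coords.to_numpy(),
        labels=labels,
        n_components=loadings.shape[1],
    )
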