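"""PCA landscapes, kNN label transfer, two-tier typing, HVG selection."""

import numpy as np
import pandas as pd
import pytest

from haemscore import (
    ExpressionMatrix,
    SimConfig,
    fallback_hvg_dispersion,
    fit_reference_pca,
    hierarchical_cell_typing,
    knn_label_transfer,
    log_transform,
    normalize_counts,
    project_onto_reference,
    select_hvg_spikein,
    simulate_hspc_cohort,
)
from haemscore.pipeline import build_two_tier_landscapes
from haemscore.projection import ReferenceLandscape, load_landscape, save_landscape
from haemscore.simulate import simulate_hvg_dataset


def _log_matrix(x, gene_names=None):
    n, g = x.shape
    genes = pd.Index(gene_names or [f"g{j:04d}" for j in range(g)])
    return ExpressionMatrix(
        pd.Index([f"c{i:05d}" for i in range(n)]), genes,
        np.zeros((n, g), int), layers={"log": np.asarray(x, float)},
    )


def _clustered_reference(seed=0, n_per=60, n_genes=40, sep=5.0, labels=("A", "B", "C")):
    """Gaussian clusters with inter-centroid distance >= sep x within-sd."""
    rng = np.random.default_rng(seed)
    centroids = rng.normal(scale=sep, size=(len(labels), n_genes))
    x = np.vstack([centroids[i] + rng.normal(size=(n_per, n_genes))
                   for i in range(len(labels))])
    lab = np.repeat(labels, n_per)
    m = _log_matrix(x)
    return m, pd.Series(lab, index=m.cells)


def test_loadings_orthonormal_and_self_projection():
    m, labels = _clustered_reference()
    L = fit_reference_pca(m, labels, m.genes, n_components=10)
    np.testing.assert_allclose(
        L.loadings.T @ L.loadings, np.eye(10), atol=1e-6
    )
    coords = project_onto_reference(m, L)
    np.testing.assert_allclose(coords, L.ref_coords, atol=1e-6)


def test_rank_two_data_has_no_higher_components():
    rng = np.random.default_rng(1)
    basis = rng.normal(size=(2, 30))
    weights = rng.normal(size=(50, 2))
    m = _log_matrix(weights @ basis)
    L = fit_reference_pca(m, pd.Series("x", index=m.cells), m.genes, n_components=10)
    var = L.ref_coords.var(axis=0)
    assert np.all(var[2:] < 1e-10)


def test_n_components_too_large_errors():
    m, labels = _clustered_reference(n_per=5, n_genes=10)
    with pytest.raises(ValueError, match="n_components"):
        fit_reference_pca(m, labels, m.genes, n_components=100)


def test_query_identical_to_reference_cell_matches_coordinates():
    m, labels = _clustered_reference(seed=2)
    L = fit_reference_pca(m, labels, m.genes, n_components=5)
    q = m.subset_cells(np.arange(3))
    coords = project_onto_reference(q, L)
    np.testing.assert_allclose(coords, L.ref_coords[:3], atol=1e-6)


def test_missing_hvgs_imputed_at_reference_mean():
    """Hand-built 5-gene example: a query missing one HVG projects as if
    that gene sat exactly at the reference mean (zero after centring)."""
    rng = np.random.default_rng(3)
    m = _log_matrix(rng.normal(size=(30, 5)), gene_names=list("abcde"))
    L = fit_reference_pca(m, pd.Series("x", index=m.cells), m.genes, n_components=3)
    q_full = rng.normal(size=(4, 5))
    q_missing = _log_matrix(q_full[:, :4], gene_names=list("abcd"))
    coords = project_onto_reference(q_missing, L)
    centred = q_full.copy() - L.gene_means
    centred[:, 4] = 0.0  # brute zero-fill of the missing gene
    np.testing.assert_allclose(coords, centred @ L.loadings, atol=1e-10)


def test_low_hvg_coverage_errors():
    rng = np.random.default_rng(4)
    m = _log_matrix(rng.normal(size=(20, 10)))
    L = fit_reference_pca(m, pd.Series("x", index=m.cells), m.genes, n_components=3)
    q = _log_matrix(rng.normal(size=(2, 5)), gene_names=[f"g{j:04d}" for j in range(5)])
    with pytest.raises(ValueError, match="80%"):
        project_onto_reference(q, L)


def test_knn_k1_returns_nearest_label():
    m, labels = _clustered_reference(seed=5)
    L = fit_reference_pca(m, labels, m.genes, n_components=5)
    out = knn_label_transfer(L.ref_coords[:5], L, k=1)
    assert list(out["label"]) == list(labels.iloc[:5])


def test_knn_unanimous_vote():
    coords = np.vstack([np.zeros((15, 2)), np.full((5, 2), 10.0)])
    L = ReferenceLandscape(
        genes=pd.Index(["a", "b"]),
        gene_means=np.zeros(2),
        loadings=np.eye(2),
        ref_coords=coords,
        labels=pd.Series(["GMP"] * 15 + ["MEP"] * 5),
        n_components=2,
    )
    out = knn_label_transfer(np.array([[0.1, 0.0]]), L, k=15)
    assert out["label"].iloc[0] == "GMP"


def test_knn_tie_breaks_by_summed_distance():
    """7-vs-7-vs-1 among 15 neighbors: tied classes resolve to the one with
    smaller summed neighbor distance (checked by explicit enumeration)."""
    # class X at distances 1..7, class Y at distances 1.5..7.5, Z far
    dx = np.arange(1.0, 8.0)
    dy = np.arange(1.5, 8.5)
    coords = np.concatenate([dx, dy, [9.0]])[:, None]
    labels = ["X"] * 7 + ["Y"] * 7 + ["Z"]
    L = ReferenceLandscape(
        genes=pd.Index(["a"]),
        gene_means=np.zeros(1),
        loadings=np.eye(1),
        ref_coords=coords,
        labels=pd.Series(labels),
        n_components=1,
    )
    out = knn_label_transfer(np.array([[0.0]]), L, k=15)
    # brute enumeration: sum(|coords|) per tied class
    sums = {lab: coords[[i for i, l2 in enumerate(labels) if l2 == lab], 0].sum()
            for lab in ("X", "Y")}
    assert sums["X"] < sums["Y"]
    assert out["label"].iloc[0] == "X"


def test_knn_reference_permutation_invariance():
    m, labels = _clustered_reference(seed=6)
    L = fit_reference_pca(m, labels, m.genes, n_components=5)
    rng = np.random.default_rng(0)
    perm = rng.permutation(L.ref_coords.shape[0])
    L2 = ReferenceLandscape(
        genes=L.genes,
        gene_means=L.gene_means,
        loadings=L.loadings,
        ref_coords=L.ref_coords[perm],
        labels=pd.Series(L.labels.to_numpy()[perm]),
        n_components=L.n_components,
    )
    q = L.ref_coords[::7] + 0.01
    a = knn_label_transfer(q, L, k=15)["label"]
    b = knn_label_transfer(q, L2, k=15)["label"]
    assert list(a) == list(b)


def test_self_projection_label_consistency():
    """Leave-one-out kNN on well-separated clusters recovers >= 95% of the
    reference cells' own labels."""
    m, labels = _clustered_reference(seed=7, n_per=80, sep=5.0)
    L = fit_reference_pca(m, labels, m.genes, n_components=10)
    correct = 0
    for i in range(m.n_cells):
        mask = np.ones(m.n_cells, bool)
        mask[i] = False
        L_i = ReferenceLandscape(
            genes=L.genes, gene_means=L.gene_means, loadings=L.loadings,
            ref_coords=L.ref_coords[mask],
            labels=pd.Series(L.labels.to_numpy()[mask]),
            n_components=L.n_components,
        )
        pred = knn_label_transfer(L.ref_coords[i:i + 1], L_i, k=15)["label"].iloc[0]
        correct += pred == labels.iloc[i]
    assert correct / m.n_cells >= 0.95


def test_hierarchical_typing_rules():
    m, labels = _clustered_reference(seed=8, labels=("GMP", "HSC", "MEP"))
    key = fit_reference_pca(m, labels, m.genes, n_components=5)
    fine_labels = labels.replace({"HSC": "LT-HSC"})
    refinement = fit_reference_pca(m, fine_labels, m.genes, n_components=5)

    out = hierarchical_cell_typing(m, key, refinement)
    # cells keyed GMP/MEP are never relabeled; HSC cells get fine labels
    keyed = knn_label_transfer(project_onto_reference(m, key), key, k=15)["label"]
    assert (out[keyed.to_numpy() == "GMP"] == "GMP").all()
    assert set(out[keyed.to_numpy() == "HSC"]) == {"LT-HSC"}

    # with no cell in the refine set, output equals key labels
    out2 = hierarchical_cell_typing(m, key, refinement, refine_labels={"Absent"})
    assert list(out2) == list(keyed)

    with pytest.warns(UserWarning, match="refinement"):
        out3 = hierarchical_cell_typing(m, key, None)
    assert list(out3) == list(keyed)


def test_two_tier_recovery_on_held_out_cells():
    from haemscore import default_sim_config
    from haemscore.qc import scale_genes

    cfg = default_sim_config(seed=21, cells_per_combo=40)
    m, meta, truth = simulate_hspc_cohort(cfg)
    m = log_transform(normalize_counts(m))
    rng = np.random.default_rng(0)
    ref_mask = rng.random(m.n_cells) < 0.5
    key, refinement = build_two_tier_landscapes(
        m.subset_cells(ref_mask), truth.cells["cell_type"], n_components=30
    )
    held_out = m.subset_cells(~ref_mask)
    pred = hierarchical_cell_typing(held_out, key, refinement)
    true = truth.cells.loc[held_out.cells, "cell_type"]
    assert (pred == true).mean() >= 0.9


def test_landscape_serialization_round_trip(tmp_path):
    m, labels = _clustered_reference(seed=9)
    L = fit_reference_pca(m, labels, m.genes, n_components=4)
    save_landscape(L, tmp_path / "land")
    L2 = load_landscape(tmp_path / "land")
    np.testing.assert_allclose(L.loadings, L2.loadings)
    np.testing.assert_allclose(L.ref_coords, L2.ref_coords)
    assert list(L.labels) == list(L2.labels)
    q = m.subset_cells(np.arange(5))
    np.testing.assert_allclose(
        project_onto_reference(q, L), project_onto_reference(q, L2), atol=1e-9
    )


# ---- HVG selection ---------------------------------------------------------


def test_hvg_spikein_recovers_planted_variable_genes():
    m, truth = simulate_hvg_dataset(n_cells=500, seed=12)
    res = select_hvg_spikein(m)
    sel = res.table["selected"].to_numpy()
    recovered = int((sel & truth).sum())
    false_sel = int((sel & ~truth).sum())
    assert recovered >= 40
    assert false_sel <= 0.10 * max(sel.sum(), 1)


def test_hvg_zero_variance_gene_never_selected():
    m, _ = simulate_hvg_dataset(n_cells=200, n_genes=100, n_variable=10, seed=1)
    counts = m.counts.copy()
    counts[:, 0] = 5  # constant gene
    m2 = ExpressionMatrix(m.cells, m.genes, counts, spikein_mask=m.spikein_mask)
    res = select_hvg_spikein(m2)
    assert not res.table["selected"].iloc[0]


def test_hvg_scale_equivariance_under_count_doubling():
    m, _ = simulate_hvg_dataset(n_cells=300, seed=13)
    res1 = select_hvg_spikein(m)
    m2 = ExpressionMatrix(m.cells, m.genes, m.counts * 2, spikein_mask=m.spikein_mask)
    res2 = select_hvg_spikein(m2)
    a = set(res1.selected)
    b = set(res2.selected)
    # identical up to FDR-boundary genes
    assert len(a ^ b) <= 0.15 * max(len(a), 1) + 3


def test_hvg_spikein_requires_enough_spikeins():
    m, _ = simulate_hvg_dataset(n_cells=100, n_spikeins=5, seed=2)
    with pytest.raises(ValueError, match="fallback"):
        select_hvg_spikein(m)


def test_fallback_hvg_mean_window_and_bins():
    rng = np.random.default_rng(14)
    n, g = 300, 200
    x = rng.poisson(1.0, size=(n, g)).astype(float)
    x[:, 0] = rng.poisson(50.0, size=n)  # mean far above max_mean
    m = ExpressionMatrix(
        pd.Index([f"c{i}" for i in range(n)]),
        pd.Index([f"g{j}" for j in range(g)]),
        x.astype(int),
    )
    m = log_transform(normalize_counts(m, target_sum=float(x.sum(1).mean())))
    res = fallback_hvg_dispersion(m, min_mean=0.02, max_mean=3.0, min_disp=0.3)
    assert not res.table["selected"].iloc[0]  # outside the mean window
    # identical-dispersion genes in a bin all get ~0 z-scores: none selected
    m_flat = _log_matrix(np.log1p(rng.poisson(1.0, size=(n, 50)).astype(float)))
    res_flat = fallback_hvg_dispersion(m_flat, min_disp=3.0)
    assert res_flat.table["selected"].sum() == 0
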