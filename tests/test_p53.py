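"""p53-dependence calling, rank tests, score correlation, proportions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haemscore import (
    ExpressionMatrix,
    PlantedEffect,
    SimConfig,
    identify_p53_dependent_genes,
    lineage_proportions,
    log_transform,
    normalize_counts,
    rank_score_correlated_genes,
    rank_sum_test,
    selected_genes,
    simulate_hspc_cohort,
    telomere_difference,
)
from haemscore.signatures import HAEM_P53_GENES


# ---- rank-sum test ----------------------------------------------------------


def test_rank_sum_exact_small_sample_matches_enumeration():
    """U = 0 for fully separated 3-vs-3; the exact two-sided p equals the
    enumeration over all C(6,3) = 20 equally likely rank assignments."""
    x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    u, p = rank_sum_test(x, y, "two-sided")
    assert u == 0.0

    # brute enumeration of the null distribution of U
    pooled = np.arange(1, 7)
    us = []
    for combo in itertools.combinations(range(6), 3):
        xs = pooled[list(combo)]
        ys = pooled[[i for i in range(6) if i not in combo]]
        us.append(sum((xi > ys).sum() for xi in xs))
    us = np.array(us)
    p_exact = (us <= 0).mean() + (us >= 9).mean()  # two-sided, max U = 9
    assert p == pytest.approx(p_exact) == pytest.approx(0.1)


def test_rank_sum_identical_samples_p_one():
    x = np.array([3.0, 1.0, 7.0, 5.0])
    _, p = rank_sum_test(x, x.copy(), "two-sided")
    assert p == pytest.approx(1.0)


def test_rank_sum_large_sample_close_to_reference_implementation():
    rng = np.random.default_rng(0)
    x = rng.normal(0.0, 1.0, 60)
    y = rng.normal(0.4, 1.0, 70)
    _, p = rank_sum_test(x, y, "two-sided")
    ref = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    assert p == pytest.approx(ref, rel=0.05)


def test_rank_sum_empty_sample_errors():
    with pytest.raises(ValueError):
        rank_sum_test(np.array([]), np.array([1.0]))


# ---- dependence calling ------------------------------------------------------


def _dependence_cohort(n_per=100, seed=17, n_types=6):
    """16 genes planted up 4x in mutant and rescued in the p53-null (in 4 of
    6 cell types); 20 decoys up 4x in BOTH mutant and p53-null."""
    types = {f"T{i}": "stem" for i in range(n_types)}
    dependent_types = tuple(f"T{i}" for i in range(4))
    n_genes = 400
    names = [f"g{i:05d}" for i in range(n_genes)]
    names[100:116] = list(HAEM_P53_GENES)
    decoys = tuple(f"g{i:05d}" for i in range(200, 220))
    effects = (
        PlantedEffect("p53", HAEM_P53_GENES, "DKO", 4.0,
                      cell_types=dependent_types, marks_p53_active=True),
        PlantedEffect("decoy_mut", decoys, "DKO", 4.0),
        PlantedEffect("decoy_tko", decoys, "TKO", 4.0),
    )
    cfg = SimConfig(
        n_cells_per_type=n_per,
        cell_types=types,
        genotypes=("WT", "DKO", "TKO"),
        baseline_means=np.full(n_genes, 2.0),
        effects=effects,
        gene_names=tuple(names),
        markers_per_type=0,
        n_spikeins=0,
        seed=seed,
    )
    m, meta, truth = simulate_hspc_cohort(cfg)
    m = log_transform(normalize_counts(m))
    meta["cell_type"] = truth.cells.loc[m.cells, "cell_type"]
    return m, meta, decoys


GENOTYPE_ROLES = {"wt": "WT", "mutant": "DKO", "mutant_p53null": "TKO"}


def test_dependence_recovers_planted_pattern_and_rejects_decoys():
    m, meta, decoys = _dependence_cohort()
    candidates = list(HAEM_P53_GENES) + list(decoys)
    calls = identify_p53_dependent_genes(m, meta, candidates, GENOTYPE_ROLES)
    assert set(selected_genes(calls, min_types=3)) == set(HAEM_P53_GENES)
    # sort order: dependent-type count descending, then symbol
    counts = [c.n_dependent_types for c in calls]
    assert counts == sorted(counts, reverse=True)
    for c in calls:
        for ct in c.dependent:
            assert c.dependent[ct] == (c.up_vs_wt[ct] and c.rescued_by_p53_loss[ct])


def test_dependence_null_data_selects_nothing():
    rng = np.random.default_rng(3)
    n = 180
    x = rng.normal(size=(n, 30))
    m = ExpressionMatrix(
        pd.Index([f"c{i}" for i in range(n)]),
        pd.Index([f"g{j}" for j in range(30)]),
        np.zeros((n, 30), int), layers={"log": x},
    )
    meta = pd.DataFrame(
        {
            "genotype": np.tile(["WT", "DKO", "TKO"], n // 3),
            "cell_type": np.repeat(["T0", "T1", "T2"], n // 3),
        },
        index=m.cells,
    )
    calls = identify_p53_dependent_genes(
        m, meta, [f"g{j}" for j in range(30)], GENOTYPE_ROLES, min_types=1
    )
    assert selected_genes(calls, min_types=1) == []


def test_dependence_monotone_in_min_types():
    m, meta, decoys = _dependence_cohort(n_per=60, seed=5)
    candidates = list(HAEM_P53_GENES) + list(decoys)
    calls = identify_p53_dependent_genes(m, meta, candidates, GENOTYPE_ROLES)
    previous = None
    for k in (1, 2, 3, 4, 5):
        sel = set(selected_genes(calls, min_types=k))
        if previous is not None:
            assert sel <= previous
        previous = sel


def test_dependence_missing_genotype_errors():
    m, meta, _ = _dependence_cohort(n_per=20, seed=1, n_types=2)
    with pytest.raises(ValueError, match="absent"):
        identify_p53_dependent_genes(
            m, meta, list(HAEM_P53_GENES),
            {"wt": "WT", "mutant": "DKO", "mutant_p53null": "NOPE"},
        )


# ---- score correlation -------------------------------------------------------


def test_rank_score_correlated_genes_contracts():
    rng = np.random.default_rng(8)
    n = 50
    score = pd.Series(rng.normal(size=n), index=[f"c{i}" for i in range(n)])
    x = rng.normal(size=(n, 10))
    x[:, 3] = 2.0 + 1.5 * score.to_numpy()  # exactly linear in the score
    x[:, 7] = 4.2  # constant
    m = ExpressionMatrix(
        pd.Index(score.index), pd.Index([f"g{j}" for j in range(10)]),
        np.zeros((n, 10), int), layers={"log": x},
    )
    out = rank_score_correlated_genes(m, score)
    row = out.set_index("gene").loc["g3"]
    assert row["pearson_r"] == pytest.approx(1.0, abs=1e-9)
    assert row["rank"] == 1
    const = out.set_index("gene").loc["g7"]
    assert bool(const["constant"]) and np.isnan(const["pearson_r"])

    # affine score transform leaves r unchanged
    out2 = rank_score_correlated_genes(m, 10.0 - 0.0 * score + 2.0 * score)
    np.testing.assert_allclose(
        out["pearson_r"].to_numpy(), out2["pearson_r"].to_numpy(), atol=1e-9
    )

    # ordering matches a brute-force covariance-formula recomputation
    s = score.to_numpy()
    brute = {}
    for j in range(10):
        v = x[:, j]
        if v.max() == v.min():
            continue
        brute[f"g{j}"] = ((v - v.mean()) * (s - s.mean())).mean() / (v.std() * s.std())
    brute_order = sorted(brute, key=lambda g: (-brute[g], g))
    impl_order = list(out.dropna(subset=["pearson_r"])
                      .sort_values("rank")["gene"])
    assert impl_order == brute_order

    with pytest.raises(ValueError, match="cells"):
        rank_score_correlated_genes(m, score, min_cells=1000)


# ---- lineage proportions -----------------------------------------------------


def test_lineage_proportions_contracts():
    meta = pd.DataFrame(
        {
            "genotype": ["WT"] * 4 + ["DKO"] * 0,
            "cell_type": ["GMP", "GMP", "LT-HSC", "LMPP"],
        },
        index=[f"c{i}" for i in range(4)],
    )
    lm = {"GMP": "myeloid", "LT-HSC": "stem", "LMPP": "lymphoid"}
    table = lineage_proportions(meta, lm)
    per_g = table.by_type.groupby("genotype")["proportion"].sum()
    np.testing.assert_allclose(per_g.to_numpy(), 1.0, atol=1e-9)
    gmp = table.by_type.query("cell_type == 'GMP'")["proportion"].iloc[0]
    assert gmp == pytest.approx(0.5)

    single = lineage_proportions(
        meta.assign(cell_type="GMP"), {"GMP": "myeloid"}
    )
    assert (single.by_type["proportion"] == 1.0).all()

    with pytest.raises(ValueError, match="Unknown"):
        lineage_proportions(meta.assign(cell_type="Unknown"), lm)


def test_lineage_proportions_zero_cell_genotype_no_division_error():
    meta = pd.DataFrame(
        {"genotype": ["WT", "WT", "DKO"], "cell_type": ["GMP", "GMP", None]},
        index=["c0", "c1", "c2"],
    )
    table = lineage_proportions(meta, {"GMP": "myeloid"})
    dko = table.by_type.query("genotype == 'DKO'")
    assert (dko["count"] == 0).all() and (dko["proportion"] == 0.0).all()


def test_planted_myeloid_expansion_recovered():
    """60% vs 30% myeloid composition recovered within the binomial 99% CI
    at 500 cells per genotype."""
    n = 500
    n_cells = {}
    for g, myeloid_frac in (("WT", 0.3), ("DKO", 0.6)):
        n_cells[(g, "GMP")] = int(n * myeloid_frac)
        n_cells[(g, "LT-HSC")] = n - int(n * myeloid_frac)
    cfg = SimConfig(
        n_cells_per_type=n_cells,
        cell_types={"GMP": "myeloid", "LT-HSC": "stem"},
        genotypes=("WT", "DKO"),
        baseline_means=np.full(50, 2.0),
        markers_per_type=5,
        n_spikeins=0,
        seed=4,
    )
    m, meta, truth = simulate_hspc_cohort(cfg)
    meta["cell_type"] = truth.cells.loc[m.cells, "cell_type"]
    table = lineage_proportions(meta, {"GMP": "myeloid", "LT-HSC": "stem"})
    for g, frac in (("WT", 0.3), ("DKO", 0.6)):
        est = table.by_class.query(
            "genotype == @g and lineage == 'myeloid'"
        )["proportion"].iloc[0]
        half_width = 2.576 * np.sqrt(frac * (1 - frac) / n)
        assert abs(est - frac) <= half_width


# ---- telomere utility -------------------------------------------------------


def test_telomere_difference_pairing():
    hsc = pd.Series({"m1": 5000.0, "m2": 4800.0})
    tail = pd.Series({"m2": 5000.0, "m1": 5000.0})  # permuted order
    diff = telomere_difference(hsc, tail)
    assert diff["m1"] == 0.0
    assert diff["m2"] == -200.0
    with pytest.raises(ValueError, match="unmatched"):
        telomere_difference(hsc, tail.drop("m1"))
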