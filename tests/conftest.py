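import numpy as np
import pandas as pd
import pytest

from haemscore import (
    ExpressionMatrix,
    compute_qc_metrics,
    default_sim_config,
    log_transform,
    normalize_counts,
    scale_genes,
    simulate_hspc_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-genotype, 6-cell-type cohort with planted p53/aging effects."""
    cfg = default_sim_config(seed=3, cells_per_combo=30)
    m, meta, truth = simulate_hspc_cohort(cfg)
    meta = compute_qc_metrics(m, meta)
    return m, meta, truth


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    """Same cohort with norm10k / log / scaled layers attached."""
    m, meta, truth = small_cohort
    m = scale_genes(log_transform(normalize_counts(m)))
    return m, meta, truth


@pytest.fixture()
def tiny_matrix():
    """A 4-cell x 5-gene matrix with one spike-in, hand-checkable."""
    counts = np.array(
        [
            [10, 0, 5, 3, 2],
            [0, 8, 1, 1, 0],
            [4, 4, 4, 4, 4],
            [1, 2, 3, 4, 5],
        ]
    )
    return ExpressionMatrix(
        cells=pd.Index([f"c{i}" for i in range(4)]),
        genes=pd.Index(["gA", "gB", "gC", "mt-gD", "ERCC-1"]),
        counts=counts,
        spikein_mask=np.array([False, False, False, False, True]),
    )
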