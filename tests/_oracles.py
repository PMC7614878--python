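"""Independent brute-force oracles used by the test suite.

These are deliberately slow, straight-line reimplementations of documented
procedures; they share no code with the package implementation.
"""

import numpy as np


def brute_force_bin_score(x, gene_names, sig_genes, n_bins, ctrl_per_gene, seed):
    """Straight-line reimplementation of bin-matched control scoring.

    Ranks genes by mean expression, forms ``n_bins`` equal-size rank bins,
    samples ``ctrl_per_gene`` non-signature controls from each signature
    gene's bin with a fresh ``default_rng(seed)``, de-duplicates, and
    returns mean(signature) - mean(controls) per cell.
    """
    x = np.asarray(x, dtype=float)
    gene_names = list(gene_names)
    n_genes = len(gene_names)
    means = [float(np.mean(x[:, j])) for j in range(n_genes)]

    # stable rank, ties kept in gene order
    order = np.argsort(np.asarray(means), kind="stable")
    rank = {int(j): int(r) for r, j in enumerate(order)}
    bin_of = {j: rank[j] * n_bins // n_genes for j in range(n_genes)}

    sig_idx = [gene_names.index(g) for g in sig_genes]
    sig_set = set(sig_idx)
    rng = np.random.default_rng(seed)
    controls = set()
    for gi in sig_idx:
        candidates = [j for j in range(n_genes) if bin_of[j] == bin_of[gi]]
        candidates = [j for j in candidates if j not in sig_set]
        if not candidates:
            continue
        take = min(ctrl_per_gene, len(candidates))
        picked = rng.choice(np.asarray(candidates), size=take, replace=False)
        controls.update(int(p) for p in picked)
    controls = sorted(controls)

    scores = []
    for c in range(x.shape[0]):
        sig_mean = sum(x[c, j] for j in sig_idx) / len(sig_idx)
        ctrl_mean = sum(x[c, j] for j in controls) / len(controls)
        scores.append(sig_mean - ctrl_mean)
    return np.asarray(scores)


def auroc(scores, flags):
    """Rank-based AUROC (Mann-Whitney statistic / (n1*n0))."""
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    pos = scores[flags]
    neg = scores[~flags]
    wins = 0.0
    for p in pos:
        wins += (p > neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))
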