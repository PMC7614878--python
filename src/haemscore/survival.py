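"""Score-stratified survival analysis.

Subjects are split into a high-score group (top quantile, default top
25%) and the rest; survival differences are quantified by the
Kaplan-Meier product-limit estimator, the Mantel-Haenszel log-rank test
with the O/E hazard-ratio estimate, and a multivariate Cox
proportional-hazards fit (Breslow tie handling, Newton-Raphson on the
partial likelihood) so the score group can be assessed alongside
clinical covariates such as age > 60 and prior treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratifiedGroups",
    "LogrankResult",
    "stratify_top_quantile",
    "kaplan_meier",
    "logrank_test_hr",
    "cox_fit",
]


@dataclass
class StratifiedGroups:
    """High/low group assignment by score quantile."""

    groups: pd.Series  # per subject: "high" | "low"
    threshold: float
    rule: str


def stratify_top_quantile(scores: pd.Series, q: float = 0.25) -> StratifiedGroups:
    """Label the top ``q`` fraction of scores "high", the rest "low".

    The threshold is the (1 - q) quantile with linear interpolation; ties
    at the threshold go to the high group. Raises if all scores are equal
    (no stratification possible).
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 subjects to stratify")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    vals = scores.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("all scores identical; cannot stratify")
    threshold = float(np.quantile(vals, 1.0 - q))
    groups = pd.Series(
        np.where(vals >= threshold, "high", "low"), index=scores.index, name="group"
    )
    return StratifiedGroups(
        groups=groups,
        threshold=threshold,
        rule=f"score >= {1 - q:.0%} quantile ({threshold:.6g}) -> high",
    )


def kaplan_meier(
    table: pd.DataFrame, group: pd.Series | str | None = None
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    ``table`` needs ``time`` and ``event`` columns; ``group`` is a column
    name, an aligned Series, or None (single group "all"). Returns, per
    group, a DataFrame with one row per distinct event time: ``time``,
    ``at_risk``, ``events``, ``survival``. Censored subjects leave the
    risk set after their censoring time.
    """
    if (table["time"] < 0).any():
        raise ValueError("negative survival times")
    if isinstance(group, str):
        labels = table[group]
    elif group is None:
        labels = pd.Series("all", index=table.index)
    else:
        labels = group
    out: dict[str, pd.DataFrame] = {}
    for lab in pd.unique(labels):
        sub = table.loc[labels == lab]
        t = sub["time"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=bool)
        event_times = np.unique(t[e])
        rows = []
        surv = 1.0
        for et in event_times:
            at_risk = int((t >= et).sum())
            d = int(((t == et) & e).sum())
            surv *= 1.0 - d / at_risk
            rows.append(
                {"time": et, "at_risk": at_risk, "events": d, "survival": surv}
            )
        out[lab] = pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])
    return out


@dataclass
class LogrankResult:
    chi2: float
    pvalue: float
    hr: float  # (O1/E1) / (O2/E2), group order as given
    ci_low: float
    ci_high: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_test_hr(
    table: pd.DataFrame, groups: StratifiedGroups | pd.Series, alpha: float = 0.05
) -> LogrankResult:
    """Mantel-Haenszel log-rank test with the O/E hazard-ratio estimate.

    The HR is reported for the first group ("high" when stratified) versus
    the second, as ``(O1/E1)/(O2/E2)`` with a log-scale confidence
    interval ``exp(log HR ± z * sqrt(1/E1 + 1/E2))``.
    """
    labels = groups.groups if isinstance(groups, StratifiedGroups) else groups
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    if "high" in uniq:  # report HR for high vs low
        uniq = ["high", *[u for u in uniq if u != "high"]]
    masks = [(labels == u).to_numpy() for u in uniq]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("a group has zero subjects")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=bool)
    if not e.any():
        raise ValueError("no events in the table")

    event_times = np.unique(t[e])
    O1 = E1 = O2 = E2 = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n1 = float((at_risk & masks[0]).sum())
        n2 = float((at_risk & masks[1]).sum())
        nj = n1 + n2
        dj = float(((t == et) & e).sum())
        d1 = float(((t == et) & e & masks[0]).sum())
        d2 = dj - d1
        O1 += d1
        O2 += d2
        E1 += dj * n1 / nj
        E2 += dj * n2 / nj
        if nj > 1:
            V += dj * (n1 / nj) * (n2 / nj) * (nj - dj) / (nj - 1)
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    hr = (O1 / E1) / (O2 / E2) if E1 > 0 and E2 > 0 and O2 > 0 else np.inf
    z = stats.norm.ppf(1 - alpha / 2)
    se_log = np.sqrt(1.0 / E1 + 1.0 / E2)
    return LogrankResult(
        chi2=float(chi2),
        pvalue=p,
        hr=float(hr),
        ci_low=float(hr * np.exp(-z * se_log)),
        ci_high=float(hr * np.exp(z * se_log)),
        observed=(O1, O2),
        expected=(E1, E2),
    )


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Cox proportional-hazards fit with Breslow tie handling.

    Maximizes the partial likelihood by Newton-Raphson (gradient tolerance
    ``tol``, at most ``max_iter`` iterations); Wald confidence intervals
    and p-values per covariate. Raises on non-convergence (reporting the
    last gradient norm) and on apparent separation (diverging
    coefficients).

    Returns a DataFrame indexed by covariate with columns ``coef``, ``hr``,
    ``se``, ``ci_low``, ``ci_high``, ``pvalue``.
    """
    if int(table["event"].sum()) < 10:
        raise ValueError("need at least 10 events for a stable Cox fit")
    X = table[covariates].to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    if rank < p + 1:
        raise ValueError("collinear covariates in Cox design")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=bool)

    # sort descending by time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    event_times = np.unique(ts[es])

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()  # guard overflow; cancels in the ratios
        w = np.exp(eta)
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * Xs, axis=0)
        cwxx = np.cumsum(w[:, None, None] * Xs[:, :, None] * Xs[:, None, :], axis=0)

        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for et in event_times:
            in_risk = np.searchsorted(-ts, -et, side="right") - 1
            d_mask = (ts == et) & es
            d = int(d_mask.sum())
            s0 = cw[in_risk]
            s1 = cwx[in_risk]
            s2 = cwxx[in_risk]
            grad += Xs[d_mask].sum(axis=0) - d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            break
        step = np.linalg.solve(hess, -grad)
        beta = beta + step
        if np.any(np.abs(beta) > 50):
            raise ValueError(
                "coefficients diverging; a covariate may perfectly separate "
                "the event order (monotone likelihood)"
            )
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last gradient norm {gnorm:.3g})"
        )

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    zcrit = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "pvalue": 2 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(covariates, name="covariate"),
    )
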