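"""Edge-wise group inference and covariate regressions with FDR control.

Each directed edge's coefficient is compared between groups with a
Welch two-sample t test; p values are adjusted across the family of
N(N-1) edges within one (condition, phase) cell by the
Benjamini-Hochberg step-up procedure (a global family across cells is
available via the caller).  Covariate analyses regress each edge's
coefficient on a subject covariate, equivalent to testing the Pearson
correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .mvar import EdgeCoefficientPanel


def _split_edge(edge: str) -> tuple[str, str]:
    parts = edge.split("->")
    return (parts[0], parts[1]) if len(parts) == 2 else (edge, edge)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q values and rejection mask.

    Sorts the m p values ascending, finds the largest rank i with
    p_(i) <= (i/m) q and rejects all ranks up to i.  The returned q
    values are the monotone-adjusted p*m/rank, capped at 1; tied p
    values share the most favorable rank's outcome by construction.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("pvals must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw_q = ranked * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(raw_q[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    passing = np.nonzero(ranked <= np.arange(1, m + 1) / m * q)[0]
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[: passing[-1] + 1] = True
    qvals = np.empty(m)
    reject = np.empty(m, dtype=bool)
    qvals[order] = qvals_sorted
    reject[order] = reject_sorted
    return qvals, reject


def compare_groups(
    panel: EdgeCoefficientPanel,
    group_a: str = "HC",
    group_b: str = "SCZ",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise Welch t comparison of the two groups with BH-FDR.

    Returns one row per directed edge with group means, the mean
    difference (group_a - group_b), the absolute difference, a
    direction label ("reduced in <group_b>" when group_a's mean is
    larger), Welch t/df/p, BH-adjusted q, and the significance flag at
    ``q_threshold``.  Edges with zero variance in both groups get p = 1
    and are flagged degenerate.
    """
    values = panel.coefficients
    groups = panel.groups
    a = values[groups == group_a]
    b = values[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise DataError(
            f"need >= 2 subjects per group, got {len(a)} {group_a} / {len(b)} {group_b}"
        )
    xa, xb = a.to_numpy(), b.to_numpy()
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    var_a, var_b = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance edges are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
        tvals = np.array(res.statistic, dtype=float)
        pvals = np.array(res.pvalue, dtype=float)
        dfs = np.array(res.df, dtype=float)
    tvals[degenerate] = 0.0
    pvals[degenerate] = 1.0
    dfs[degenerate] = len(a) + len(b) - 2
    qvals, reject = bh_fdr(pvals, q=q_threshold)

    diff = mean_a - mean_b
    edges = panel.edge_names
    sources = [_split_edge(e)[0] for e in edges]
    targets = [_split_edge(e)[1] for e in edges]
    table = pd.DataFrame(
        {
            "condition": panel.condition,
            "phase": panel.phase,
            "edge": edges,
            "source": sources,
            "target": targets,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "difference": diff,
            "abs_difference": np.abs(diff),
            "direction": [
                f"reduced in {group_b}" if d > 0 else f"increased in {group_b}"
                for d in diff
            ],
            "t": tvals,
            "df": dfs,
            "p": pvals,
            "q": qvals,
            "significant": reject,
            "degenerate_edge": degenerate,
        }
    )
    table.attrs.update(
        {
            "group_a": group_a,
            "group_b": group_b,
            "q_threshold": q_threshold,
            "mode": panel.mode,
            "p_order": panel.p,
        }
    )
    return table


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def covariate_regression(
    panel: EdgeCoefficientPanel,
    covariate: pd.Series,
    q_threshold: float = 0.05,
    covariate_name: str | None = None,
) -> pd.DataFrame:
    """Per-edge Pearson correlation with a subject covariate, BH-adjusted.

    The simple-regression slope test is equivalent to testing r via its
    t distribution, which is what this computes.  Subjects with a
    missing covariate are excluded listwise; the retained count is
    recorded per edge.
    """
    name = covariate_name or (covariate.name or "covariate")
    cov = covariate.reindex(panel.coefficients.index)
    keep = cov.notna()
    n = int(keep.sum())
    if n < 3:
        raise DataError(f"need >= 3 subjects with non-missing {name!r}, got {n}")
    x = cov[keep].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DataError(f"covariate {name!r} is constant")
    values = panel.coefficients.loc[keep]

    rows = []
    for edge in panel.edge_names:
        y = values[edge].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = _pearson_with_p(x, y)
        src, tgt = _split_edge(edge)
        rows.append(
            {
                "condition": panel.condition,
                "phase": panel.phase,
                "covariate": name,
                "edge": edge,
                "source": src,
                "target": tgt,
                "r": r,
                "p": p,
                "n": n,
                "n_missing": int((~keep).sum()),
            }
        )
    table = pd.DataFrame(rows)
    qvals, reject = bh_fdr(table["p"].to_numpy(), q=q_threshold)
    table["q"] = qvals
    table["significant"] = reject
    table["sign"] = np.where(table["r"] >= 0, "positive", "negative")
    table.attrs.update({"q_threshold": q_threshold, "covariate": name})
    return table


def behavior_covariate_tests(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r between subject covariates and behavioral metrics.

    ``metrics`` holds per-subject behavioral outcomes (e.g. Early/Late
    mean fraction correct, learning-curve parameters), ``covariates``
    per-subject covariate columns; both indexed by subject.  Missing
    values are excluded listwise per (metric, covariate) pair.
    """
    rows = []
    for cov_name in covariates.columns:
        for metric in metrics.columns:
            joined = pd.concat(
                [covariates[cov_name], metrics[metric]], axis=1
            ).dropna()
            if len(joined) < 3:
                raise DataError(
                    f"need >= 3 complete pairs for ({metric}, {cov_name})"
                )
            x = joined.iloc[:, 0].to_numpy(dtype=float)
            y = joined.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise DataError(f"covariate {cov_name!r} is constant")
            if np.ptp(y) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = _pearson_with_p(x, y)
            rows.append(
                {
                    "parameter": metric,
                    "covariate": cov_name,
                    "r": r,
                    "p": p,
                    "n": len(joined),
                }
            )
    return pd.DataFrame(rows)


def behavioral_metrics(
    behavior: pd.DataFrame,
    fits: pd.DataFrame,
    n_blocks: int | None = None,
) -> pd.DataFrame:
    """Per-subject behavioral outcome table for covariate tests.

    Early/Late mean fraction correct (first vs last half of blocks)
    plus the fitted curve parameters and derived inflection time.
    """
    if n_blocks is None:
        n_blocks = int(behavior["block"].max())
    half = n_blocks // 2
    early = (
        behavior[behavior["block"] <= half]
        .groupby("subject", observed=True)["fraction"]
        .mean()
        .rename("early_fraction")
    )
    late = (
        behavior[behavior["block"] > half]
        .groupby("subject", observed=True)["fraction"]
        .mean()
        .rename("late_fraction")
    )
    params = fits.set_index("subject")[["a", "b", "c", "inflection_time"]]
    return pd.concat([early, late, params], axis=1)
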