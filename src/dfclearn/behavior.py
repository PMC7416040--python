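"""Learning-curve modeling and group-level behavioral inference.

Recall performance across retrieval blocks is modeled with the Gompertz
function

    fraction correct = a * exp(-exp(b - c * t))

where a is the asymptote (learning capacity), c the rate parameter and
b the shape offset; the curve's inflection — the transition from the
linear to the asymptotic learning regime — falls at t = b / c.  Note the
field sometimes labels b the "learning rate time constant" and c the
"inflection point"; this module reports the raw (a, b, c) of the
formula above together with the derived inflection time b/c so both
conventions can be read off.

Group x block performance is analyzed with a classical mixed
(split-plot) ANOVA computed from sums of squares, and group contrasts
on fitted parameters use Welch t tests with Cohen's d effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError
from .synth import BehavioralRecord

DEFAULT_BOUNDS = ((0.0, 1.05), (-10.0, 10.0), (0.0, 10.0))  # a, b, c


def gompertz_value(a, b, c, t):
    """Evaluate the Gompertz learning curve a*exp(-exp(b - c*t))."""
    return a * np.exp(-np.exp(np.asarray(b, dtype=float) - np.asarray(c, dtype=float) * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class GompertzFit:
    """Least-squares Gompertz parameters for one subject.

    ``inflection_time`` is the derived b/c (blocks); ``degenerate``
    marks all-zero data fits that bypass the solver.
    """

    a: float
    b: float
    c: float
    inflection_time: float
    sse: float
    converged: bool
    n_blocks: int
    degenerate: bool = False


def _initial_points(
    y: np.ndarray,
    t: np.ndarray,
    bounds: tuple[tuple[float, float], ...],
    n_starts: int,
) -> list[np.ndarray]:
    (a_lo, a_hi), (b_lo, b_hi), (c_lo, c_hi) = bounds
    a0 = float(np.clip(max(y.max(), 1e-3), a_lo + 1e-6, a_hi - 1e-6))
    # log-log linearization: for 0 < y < a_eff, log(-log(y/a_eff)) = b - c*t
    a_eff = min(a0 * 1.02 + 1e-6, a_hi)
    mask = (y > 1e-9) & (y < a_eff * (1 - 1e-9))
    b0, c0 = 1.0, 0.5
    if mask.sum() >= 2:
        u = np.log(-np.log(y[mask] / a_eff))
        slope, intercept = np.polyfit(t[mask], u, 1)
        c0 = float(np.clip(-slope, c_lo + 1e-6, c_hi - 1e-6))
        b0 = float(np.clip(intercept, b_lo + 1e-6, b_hi - 1e-6))
    base = np.array([a0, b0, c0])
    starts = [base, _coarse_grid_start(y, t, bounds)]
    # deterministic jitter; start points depend only on the data
    jrng = np.random.default_rng(12345)
    lo = np.array([a_lo, b_lo, c_lo]) + 1e-6
    hi = np.array([a_hi, b_hi, c_hi]) - 1e-6
    scale = np.array([0.2, 1.5, 0.7])
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.clip(base + jrng.normal(0, scale), lo, hi))
    return starts


def _coarse_grid_start(
    y: np.ndarray, t: np.ndarray, bounds: tuple[tuple[float, float], ...]
) -> np.ndarray:
    """Best point of a coarse SSE scan over the bound box (basin locator)."""
    (a_lo, a_hi), (b_lo, b_hi), (c_lo, c_hi) = bounds
    a_grid = np.linspace(a_lo + 1e-6, a_hi, 22)
    b_grid = np.linspace(b_lo, b_hi, 41)
    c_grid = np.linspace(c_lo, c_hi, 41)
    curves = a_grid[:, None, None, None] * np.exp(
        -np.exp(b_grid[None, :, None, None] - c_grid[None, None, :, None] * t)
    )
    sse = ((curves - y) ** 2).sum(axis=-1)
    i, j, k = np.unravel_index(np.argmin(sse), sse.shape)
    return np.array([a_grid[i], b_grid[j], c_grid[k]])


def fit_gompertz(
    fractions: np.ndarray,
    blocks: np.ndarray | None = None,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
    n_starts: int = 5,
    tol: float = 1e-12,
) -> GompertzFit:
    """Fit (a, b, c) to per-block fractions by bounded least squares.

    Uses multi-start trust-region least squares: one data-driven start
    (a0 = max fraction, b0/c0 from a log-log linearization) plus
    jittered starts; the best converged solution is kept.

    Raises
    ------
    DataError
        For fewer than 3 blocks (the model has 3 parameters) or
        fractions outside [0, 1].
    """
    y = np.asarray(fractions, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise DataError("need at least 3 blocks to fit a 3-parameter curve")
    if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y > 1):
        raise DataError("fractions must be finite and in [0, 1]")
    t = (
        np.arange(1, y.size + 1, dtype=float)
        if blocks is None
        else np.asarray(blocks, dtype=float)
    )
    if t.shape != y.shape:
        raise DataError("blocks and fractions must align")

    if np.all(y == 0):
        return GompertzFit(
            a=0.0, b=0.0, c=0.0, inflection_time=math.nan,
            sse=0.0, converged=False, n_blocks=y.size, degenerate=True,
        )

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def resid(theta: np.ndarray) -> np.ndarray:
        return gompertz_value(*theta, t) - y

    best = None
    for x0 in _initial_points(y, t, bounds, n_starts):
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=tol, ftol=tol, gtol=tol
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if sol.success and (best is None or sse < best[0]):
            best = (sse, sol.x)
    if best is None:
        return GompertzFit(
            a=math.nan, b=math.nan, c=math.nan, inflection_time=math.nan,
            sse=math.nan, converged=False, n_blocks=y.size,
        )
    sse, (a, b, c) = best
    return GompertzFit(
        a=float(a), b=float(b), c=float(c),
        inflection_time=float(b / c) if c != 0 else math.nan,
        sse=sse, converged=True, n_blocks=y.size,
    )


def fit_cohort_gompertz(records: list[BehavioralRecord]) -> pd.DataFrame:
    """Fit every subject; returns a tidy per-subject fit table."""
    rows = []
    for rec in records:
        fit = fit_gompertz(rec.fractions)
        rows.append(
            {
                "subject": rec.subject.subject_id,
                "group": rec.subject.group,
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
                "inflection_time": fit.inflection_time,
                "sse": fit.sse,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
            }
        )
    return pd.DataFrame(rows)


def behavior_table(records: list[BehavioralRecord]) -> pd.DataFrame:
    """Long-format (subject, group, block, fraction) table."""
    rows = []
    for rec in records:
        for k, fr in enumerate(rec.fractions, start=1):
            rows.append(
                {
                    "subject": rec.subject.subject_id,
                    "group": rec.subject.group,
                    "block": k,
                    "fraction": float(fr),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """Split-plot ANOVA summary: one row per effect.

    ``table`` columns: effect, ss, df1, df2, ms, mse, F, p,
    partial_eta_sq.  The group effect is tested against the
    subjects-within-group mean square; time and group x time against
    the within-subject residual.
    """

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        row = self.table.loc[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def mixed_anova(
    data: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    block: str = "block",
    value: str = "fraction",
) -> AnovaResult:
    """Two-way mixed ANOVA: between factor `group`, within factor `block`.

    Requires a complete within-subject design (every subject measured in
    every block, no imputation) with >= 2 subjects per group.  Sums of
    squares are observation-weighted, so unequal group sizes are
    handled; with one between factor this coincides with the classical
    split-plot decomposition.
    """
    df = data[[subject, group, block, value]].copy()
    if df[value].isna().any():
        raise DataError("missing values are not allowed (no imputation)")
    counts = df.groupby([subject, block], observed=True).size()
    if (counts != 1).any():
        raise DataError("duplicate subject/block measurements")
    blocks = sorted(df[block].unique())
    per_subject = df.groupby(subject, observed=True)[block].nunique()
    if (per_subject != len(blocks)).any():
        raise DataError("incomplete design: every subject needs every block")
    gmap = df.groupby(subject, observed=True)[group].nunique()
    if (gmap != 1).any():
        raise DataError("each subject must belong to exactly one group")
    group_sizes = df.drop_duplicates(subject).groupby(group, observed=True).size()
    if len(group_sizes) < 2 or (group_sizes < 2).any():
        raise DataError("need >= 2 groups with >= 2 subjects each")

    K = len(blocks)
    n_subj = df[subject].nunique()
    grand = df[value].mean()

    subj_means = df.groupby(subject, observed=True)[value].mean()
    subj_group = df.drop_duplicates(subject).set_index(subject)[group]
    group_means = df.groupby(group, observed=True)[value].mean()
    block_means = df.groupby(block, observed=True)[value].mean()
    cell_means = df.groupby([group, block], observed=True)[value].mean()

    n_per_group = group_sizes.to_dict()
    g_levels = list(group_sizes.index)

    ss_between_subj = K * float(((subj_means - grand) ** 2).sum())
    ss_group = K * sum(
        n_per_group[g] * (group_means[g] - grand) ** 2 for g in g_levels
    )
    ss_subj_within = ss_between_subj - ss_group

    ss_total = float(((df[value] - grand) ** 2).sum())
    ss_within_subj = ss_total - ss_between_subj
    ss_time = n_subj * float(((block_means - grand) ** 2).sum())
    ss_cells = sum(
        n_per_group[g] * (cell_means[(g, k)] - grand) ** 2
        for g in g_levels
        for k in blocks
    )
    ss_inter = float(ss_cells - ss_group - ss_time)
    ss_error = ss_within_subj - ss_time - ss_inter

    n_groups = len(g_levels)
    df_group, df_subj = n_groups - 1, n_subj - n_groups
    df_time = K - 1
    df_inter = df_group * df_time
    df_error = df_subj * df_time

    ms_subj = ss_subj_within / df_subj
    ms_error = ss_error / df_error

    def row(effect, ss, df1, df2, ss_err, ms_err):
        ms = ss / df1
        F = ms / ms_err if ms_err > 0 else math.inf if ms > 0 else 0.0
        p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
        return {
            "effect": effect,
            "ss": float(ss),
            "df1": int(df1),
            "df2": int(df2),
            "ms": float(ms),
            "mse": float(ms_err),
            "F": float(F),
            "p": p,
            "partial_eta_sq": float(ss / (ss + ss_err)) if (ss + ss_err) > 0 else 0.0,
        }

    table = pd.DataFrame(
        [
            row("group", ss_group, df_group, df_subj, ss_subj_within, ms_subj),
            row("time", ss_time, df_time, df_error, ss_error, ms_error),
            row("group x time", ss_inter, df_inter, df_error, ss_error, ms_error),
        ]
    )
    return AnovaResult(table=table)


def parameter_group_contrasts(
    fits: pd.DataFrame,
    parameters: tuple[str, ...] = ("a", "b", "c", "inflection_time"),
    group_a: str = "HC",
    group_b: str = "SCZ",
) -> pd.DataFrame:
    """Welch t and Cohen's d (pooled SD) per fitted parameter.

    Subjects whose fit failed or is degenerate are excluded; exclusion
    counts are reported per parameter.
    """
    degenerate = (
        fits["degenerate"] if "degenerate" in fits else pd.Series(False, index=fits.index)
    )
    usable = fits[fits["converged"].astype(bool) & ~degenerate.astype(bool)]
    rows = []
    for param in parameters:
        x = usable.loc[usable["group"] == group_a, param].dropna().to_numpy()
        y = usable.loc[usable["group"] == group_b, param].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise DataError(f"need >= 2 usable subjects per group for {param!r}")
        res = stats.ttest_ind(x, y, equal_var=False)
        na, nb = len(x), len(y)
        pooled_sd = math.sqrt(
            ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
        )
        d = (x.mean() - y.mean()) / pooled_sd if pooled_sd > 0 else math.nan
        rows.append(
            {
                "parameter": param,
                f"mean_{group_a}": float(x.mean()),
                f"mean_{group_b}": float(y.mean()),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "cohens_d": float(d),
                "n_excluded": int(len(fits) - len(usable)),
            }
        )
    return pd.DataFrame(rows)
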