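"""Directed functional connectivity via multivariate autoregressive models.

The lag-p MVAR model Z_t = c + sum_k B_k Z_{t-k} + E_t is fitted by
ordinary least squares per target node; the off-diagonal lag-1
coefficients b_ij (prediction of node i by node j) are Granger-style
directed-influence estimates.  Lagged predictor/response pairs are
formed strictly within epoch segments — the first p volumes of each
segment serve as predictors only, and no lag pair crosses an epoch
boundary.

The default estimation mode is bivariate: for each ordered node pair a
two-node MVAR is fitted and the cross coefficient recorded, giving
N(N-1) directed-edge coefficients per subject and condition/phase cell
(30 for the default six-node network).  A full multivariate mode (one
N-node fit per subject) is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSchedule, NodeSet
from .exceptions import ConfigError, DataError
from .synth import NodeTimeSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentedSeries:
    """Contiguous volume runs for one (condition, phase) of one subject."""

    segments: tuple[np.ndarray, ...]
    node_labels: tuple[str, ...]
    condition: str
    phase: str
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        segs = tuple(np.asarray(s, dtype=float) for s in self.segments)
        for s in segs:
            if s.ndim != 2 or s.shape[1] != len(self.node_labels):
                raise DataError("each segment must be (volumes x nodes)")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def n_obs(self, p: int) -> int:
        """Effective observations after lag loss: sum over segments of len - p."""
        return int(sum(max(s.shape[0] - p, 0) for s in self.segments))


def segment_series(
    ts: NodeTimeSeries,
    condition: str,
    phase: str,
    hemodynamic_offset_volumes: int = 0,
    p: int = 1,
) -> SegmentedSeries:
    """Extract all epoch segments labeled (condition, phase).

    Each contiguous run is shifted forward by the hemodynamic offset
    (its first ``offset`` volumes are dropped; the window still ends at
    the epoch boundary).  Segments shorter than p + 2 after shifting
    are dropped with a warning.

    Raises
    ------
    DataError
        If no epoch in the schedule carries the requested labels, or no
        usable segment survives.
    """
    if hemodynamic_offset_volumes < 0:
        raise ConfigError("hemodynamic offset must be >= 0")
    labels = ts.schedule.volume_labels
    match = labels[(labels["epoch"] == condition) & (labels["phase"] == phase)]
    if match.empty:
        raise DataError(
            f"no epochs labeled ({condition!r}, {phase!r}) in the schedule"
        )
    segments = []
    for _, block in match.groupby("epoch_index", sort=True):
        idx = block["volume"].to_numpy()[hemodynamic_offset_volumes:]
        if len(idx) < p + 2:
            logger.warning(
                "dropping segment of %d volumes (< p + 2 = %d) for (%s, %s)",
                len(idx), p + 2, condition, phase,
            )
            continue
        segments.append(ts.data[idx])
    if not segments:
        raise DataError(
            f"no usable segments for ({condition!r}, {phase!r}) after offset"
        )
    return SegmentedSeries(
        segments=tuple(segments),
        node_labels=ts.node_labels,
        condition=condition,
        phase=phase,
        subject_id=ts.subject.subject_id,
        group=ts.subject.group,
    )


@dataclass(frozen=True)
class MVARFit:
    """OLS estimates of a lag-p MVAR on a node subset.

    ``B[k-1, i, j]`` is the lag-k coefficient predicting node i from
    node j; ``se`` and ``t`` are aligned elementwise.  ``n_obs`` counts
    lagged response rows pooled over segments.
    """

    node_labels: tuple[str, ...]
    p: int
    B: np.ndarray
    intercept: np.ndarray | None
    resid_var: np.ndarray
    se: np.ndarray
    t: np.ndarray
    n_obs: int
    n_segments: int
    dof: int


def _lagged_design(
    segments: tuple[np.ndarray, ...],
    cols: np.ndarray,
    p: int,
    include_intercept: bool,
    demean: bool,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for seg in segments:
        z = seg[:, cols]
        if z.shape[0] <= p:
            continue
        if demean:
            z = z - z.mean(axis=0)
        ys.append(z[p:])
        xs.append(np.hstack([z[p - k : z.shape[0] - k] for k in range(1, p + 1)]))
    if not xs:
        raise DataError("no segment long enough for the requested lag order")
    Y = np.vstack(ys)
    X = np.vstack(xs)
    if include_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    return X, Y


def fit_mvar(
    seg: SegmentedSeries,
    node_subset: tuple[str, ...] | None = None,
    p: int = 1,
    include_intercept: bool = True,
    demean: bool = False,
) -> MVARFit:
    """Fit the MVAR by per-target OLS pooled over segments.

    Standard errors come from the usual OLS covariance
    sigma_i^2 (X'X)^{-1} with sigma_i^2 = RSS_i / (n_obs - k), and
    t = estimate / se.

    Raises
    ------
    DataError
        On rank-deficient designs or when the effective observation
        count does not exceed the regressor count.
    """
    if p < 1:
        raise ConfigError("model order p must be >= 1")
    labels = seg.node_labels if node_subset is None else tuple(node_subset)
    if len(labels) < 2:
        raise ConfigError("need at least 2 nodes")
    try:
        cols = np.array([seg.node_labels.index(lab) for lab in labels])
    except ValueError as e:
        raise ConfigError(f"unknown node in subset: {e}") from e

    X, Y = _lagged_design(seg.segments, cols, p, include_intercept, demean)
    n_obs, k = X.shape
    n_nodes = len(labels)
    if n_obs <= k:
        raise DataError(
            f"insufficient observations: {n_obs} rows for {k} regressors"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise DataError(f"rank-deficient design (rank {rank} < {k} regressors)")

    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ Y)  # (k, n_nodes)
    resid = Y - X @ beta
    dof = n_obs - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_diag = np.diag(np.linalg.inv(xtx))
    se_all = np.sqrt(np.outer(xtx_inv_diag, sigma2))  # (k, n_nodes)

    off = 1 if include_intercept else 0
    B = np.empty((p, n_nodes, n_nodes))
    se = np.empty_like(B)
    for lag in range(p):
        # design columns for lag are ordered by source node
        blk = slice(off + lag * n_nodes, off + (lag + 1) * n_nodes)
        B[lag] = beta[blk, :].T  # (target, source)
        se[lag] = se_all[blk, :].T
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    intercept = beta[0, :].copy() if include_intercept else None
    return MVARFit(
        node_labels=labels,
        p=p,
        B=B,
        intercept=intercept,
        resid_var=sigma2,
        se=se,
        t=t,
        n_obs=n_obs,
        n_segments=seg.n_segments,
        dof=dof,
    )


@dataclass(frozen=True)
class EdgeCoefficientPanel:
    """Subjects x directed-edges matrix of lag-1 coefficients.

    Columns follow :meth:`NodeSet.edges` order (row-major by target,
    then source, named ``source->target``); one row per analyzed
    subject.  ``tstats`` is aligned with ``coefficients``.
    """

    condition: str
    phase: str
    mode: str
    p: int
    node_labels: tuple[str, ...]
    coefficients: pd.DataFrame = field(repr=False)
    tstats: pd.DataFrame = field(repr=False)
    groups: pd.Series = field(repr=False)

    @property
    def edge_names(self) -> list[str]:
        return list(self.coefficients.columns)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy (subject, group, condition, phase, source, target, coefficient, t)."""
        rows = []
        for subj in self.coefficients.index:
            for edge in self.coefficients.columns:
                src, tgt = edge.split("->")
                rows.append(
                    {
                        "subject": subj,
                        "group": self.groups[subj],
                        "condition": self.condition,
                        "phase": self.phase,
                        "source": src,
                        "target": tgt,
                        "coefficient": self.coefficients.at[subj, edge],
                        "t": self.tstats.at[subj, edge],
                    }
                )
        return pd.DataFrame(rows)


def build_edge_panel(
    cohort: list[NodeTimeSeries],
    condition: str,
    phase: str,
    mode: str = "bivariate",
    p: int = 1,
    hemodynamic_offset_volumes: int = 0,
    include_intercept: bool = True,
    demean: bool = False,
) -> EdgeCoefficientPanel:
    """Estimate the directed-edge coefficient panel for one analysis cell.

    In bivariate mode (default, one two-node fit per unordered pair)
    each fit yields both directions' lag-1 cross coefficients; in
    multivariate mode a single full-network fit per subject provides
    all off-diagonal coefficients.  Subjects whose fit fails are
    excluded with a logged warning.
    """
    if mode not in ("bivariate", "multivariate"):
        raise ConfigError("mode must be 'bivariate' or 'multivariate'")
    if not cohort:
        raise DataError("empty cohort")
    node_labels = cohort[0].node_labels
    if any(ts.node_labels != node_labels for ts in cohort):
        raise DataError("all subjects must share one node set")
    edge_names = NodeSet(node_labels).edge_names()
    lab_index = {lab: i for i, lab in enumerate(node_labels)}

    coef_rows, t_rows, groups, index = [], [], [], []
    for ts in cohort:
        try:
            seg = segment_series(
                ts, condition, phase, hemodynamic_offset_volumes, p=p
            )
            coefs: dict[str, float] = {}
            tvals: dict[str, float] = {}
            if mode == "multivariate":
                fit = fit_mvar(
                    seg, p=p, include_intercept=include_intercept, demean=demean
                )
                for edge in edge_names:
                    src, tgt = edge.split("->")
                    i, j = lab_index[tgt], lab_index[src]
                    coefs[edge] = fit.B[0, i, j]
                    tvals[edge] = fit.t[0, i, j]
            else:
                n = len(node_labels)
                for a in range(n):
                    for b in range(a + 1, n):
                        pair = (node_labels[a], node_labels[b])
                        fit = fit_mvar(
                            seg,
                            node_subset=pair,
                            p=p,
                            include_intercept=include_intercept,
                            demean=demean,
                        )
                        # within the 2-node fit: index 0 = a, 1 = b
                        coefs[f"{pair[0]}->{pair[1]}"] = fit.B[0, 1, 0]
                        tvals[f"{pair[0]}->{pair[1]}"] = fit.t[0, 1, 0]
                        coefs[f"{pair[1]}->{pair[0]}"] = fit.B[0, 0, 1]
                        tvals[f"{pair[1]}->{pair[0]}"] = fit.t[0, 0, 1]
        except DataError as e:
            logger.warning(
                "excluding subject %s from (%s, %s) panel: %s",
                ts.subject.subject_id, condition, phase, e,
            )
            continue
        coef_rows.append([coefs[e] for e in edge_names])
        t_rows.append([tvals[e] for e in edge_names])
        groups.append(ts.subject.group)
        index.append(ts.subject.subject_id)

    if not index:
        raise DataError(f"no subject could be fitted for ({condition}, {phase})")
    coefficients = pd.DataFrame(coef_rows, index=index, columns=edge_names)
    tstats = pd.DataFrame(t_rows, index=index, columns=edge_names)
    return EdgeCoefficientPanel(
        condition=condition,
        phase=phase,
        mode=mode,
        p=p,
        node_labels=node_labels,
        coefficients=coefficients,
        tstats=tstats,
        groups=pd.Series(groups, index=index, name="group"),
    )
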