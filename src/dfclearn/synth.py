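"""Synthetic cohort generator with known ground truth.

Simulates (i) BOLD-like node time series from condition- and
phase-specific stable lag-1 vector-autoregressive coupling, for two
groups (healthy controls, HC, and patients, SCZ) with group differences
on chosen directed edges; and (ii) negatively accelerated recall
governed by a Gompertz learning curve with binomial trial noise.

Within an epoch the signal follows Z_t = intercept + B Z_{t-1} + eps_t
with Gaussian innovations; at every epoch boundary the recursion
restarts from a fresh draw of the process's stationary distribution, so
no dependence crosses epoch boundaries (the analysis never forms lag
pairs across boundaries either).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .design import (
    BOTH,
    DEFAULT_NODE_LABELS,
    EARLY,
    ENCODING,
    LATE,
    REST,
    RETRIEVAL,
    DesignSchedule,
    NodeSet,
    make_design_schedule,
)
from .exceptions import ConfigError, DataError

GROUPS = ("HC", "SCZ")


@dataclass(frozen=True)
class SubjectRecord:
    """Identity, group membership and covariates of one subject.

    Missing covariates are explicit ``None``; ``dosage_ratio`` is the
    standardized antipsychotic dose PDD/DDD and only meaningful for the
    patient group.
    """

    subject_id: str
    group: str
    age: float | None = None
    fsiq: float | None = None
    dosage_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.dosage_ratio is not None and self.dosage_ratio < 0:
            raise ConfigError("dosage_ratio must be >= 0 when present")


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(B, dtype=float)))))


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth lag-1 coupling for one condition (and phase).

    ``B[i, j]`` is the influence of node j on node i at lag 1.  The
    matrix must be stable (spectral radius < 1) so the within-epoch
    process is stationary.
    """

    condition: str
    phase: str  # Early, Late or Both
    B: np.ndarray
    intercept: np.ndarray | None = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ConfigError(f"B must be square, got shape {B.shape}")
        object.__setattr__(self, "B", B)
        if self.phase not in (EARLY, LATE, BOTH):
            raise ConfigError(f"phase must be Early/Late/Both, got {self.phase!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        rho = spectral_radius(B)
        if rho >= 1.0:
            raise ConfigError(
                f"unstable coupling for ({self.condition}, {self.phase}): "
                f"spectral radius {rho:.3f} >= 1"
            )
        icpt = self.intercept
        icpt = np.zeros(B.shape[0]) if icpt is None else np.asarray(icpt, dtype=float)
        if icpt.shape != (B.shape[0],):
            raise ConfigError("intercept length must match B dimension")
        object.__setattr__(self, "intercept", icpt)

    @property
    def n_nodes(self) -> int:
        return self.B.shape[0]

    def stationary_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and covariance of the stationary VAR(1) distribution.

        mu = (I - B)^-1 intercept; Sigma solves the discrete Lyapunov
        equation Sigma = B Sigma B' + noise_sd^2 I.
        """
        n = self.n_nodes
        mu = np.linalg.solve(np.eye(n) - self.B, self.intercept)
        if self.noise_sd == 0:
            return mu, np.zeros((n, n))
        sigma = solve_discrete_lyapunov(self.B, self.noise_sd**2 * np.eye(n))
        return mu, (sigma + sigma.T) / 2.0


@dataclass(frozen=True)
class NodeTimeSeries:
    """A (volumes x nodes) signal matrix tied to a subject and schedule."""

    subject: SubjectRecord
    schedule: DesignSchedule
    node_labels: tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape != (self.schedule.n_volumes, len(self.node_labels)):
            raise DataError(
                f"data shape {data.shape} does not match schedule volumes "
                f"({self.schedule.n_volumes}) x nodes ({len(self.node_labels)})"
            )
        if not np.all(np.isfinite(data)):
            raise DataError("time series contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-retrieval-block fraction of correctly recalled items."""

    subject: SubjectRecord
    n_items: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if not np.all(np.isfinite(fr)) or np.any(fr < 0) or np.any(fr > 1):
            raise DataError("fractions must be finite and in [0, 1]")
        object.__setattr__(self, "fractions", fr)


def _match_spec(
    specs: list[CouplingSpec], condition: str, phase: str
) -> CouplingSpec:
    hits = [
        s
        for s in specs
        if s.condition == condition and s.phase in (phase, BOTH)
    ]
    if len(hits) != 1:
        raise ConfigError(
            f"({condition}, {phase}) must be covered by exactly one CouplingSpec, "
            f"found {len(hits)}"
        )
    return hits[0]


def simulate_network_timeseries(
    spec_set: list[CouplingSpec],
    schedule: DesignSchedule,
    subject: SubjectRecord,
    seed: int | np.random.Generator | np.random.SeedSequence,
    node_labels: tuple[str, ...] | None = None,
    smoothing_tau_s: float | None = None,
) -> NodeTimeSeries:
    """Simulate one subject's node time series epoch by epoch.

    Each epoch instance is generated from the CouplingSpec matching its
    (condition, phase); the first volume is drawn from the stationary
    distribution and the VAR(1) recursion runs within the epoch only.
    Identical seeds yield bit-identical output.

    ``smoothing_tau_s`` (off by default) applies a first-order
    exponential low-pass with the given time constant (seconds) within
    each epoch after generation — a deliberately crude stand-in for
    hemodynamic sluggishness used to stress-test estimator robustness,
    not a hemodynamic response model.
    """
    if smoothing_tau_s is not None and not smoothing_tau_s > 0:
        raise ConfigError("smoothing_tau_s must be > 0 when given")
    rng = np.random.default_rng(seed)
    n_nodes = spec_set[0].n_nodes
    if node_labels is None:
        node_labels = (
            DEFAULT_NODE_LABELS
            if n_nodes == len(DEFAULT_NODE_LABELS)
            else tuple(f"node{i}" for i in range(n_nodes))
        )
    if any(s.n_nodes != n_nodes for s in spec_set):
        raise ConfigError("all coupling specs must share one node dimension")

    labels = schedule.volume_labels
    # pre-resolve one spec per (condition, phase) occurring in the schedule
    cells = labels[["epoch", "phase"]].drop_duplicates()
    resolved = {
        (row.epoch, row.phase): _match_spec(spec_set, row.epoch, row.phase)
        for row in cells.itertuples()
    }
    moments = {key: spec.stationary_moments() for key, spec in resolved.items()}

    out = np.empty((schedule.n_volumes, n_nodes))
    for _, block in labels.groupby("epoch_index", sort=True):
        key = (block["epoch"].iloc[0], block["phase"].iloc[0])
        spec = resolved[key]
        mu, sigma = moments[key]
        idx = block["volume"].to_numpy()
        t_len = len(idx)
        eps = (
            rng.normal(0.0, spec.noise_sd, size=(t_len, n_nodes))
            if spec.noise_sd > 0
            else np.zeros((t_len, n_nodes))
        )
        z = (
            rng.multivariate_normal(mu, sigma, method="cholesky")
            if spec.noise_sd > 0
            else mu.copy()
        )
        out[idx[0]] = z
        for t in range(1, t_len):
            z = spec.intercept + spec.B @ z + eps[t]
            out[idx[t]] = z
        if smoothing_tau_s is not None:
            alpha = 1.0 - np.exp(-schedule.tr_s / smoothing_tau_s)
            for t in range(1, t_len):
                out[idx[t]] = (1 - alpha) * out[idx[t - 1]] + alpha * out[idx[t]]
    return NodeTimeSeries(
        subject=subject, schedule=schedule, node_labels=node_labels, data=out
    )


# ---------------------------------------------------------------------------
# covariate model


@dataclass(frozen=True)
class EdgeLink:
    """Linear generative link from a covariate to one directed edge.

    The subject's coupling on (source -> target) in the matching
    condition/phase cells becomes b + slope * z, where z is the
    subject's covariate standardized by the model's location/scale and
    clipped to +/-3 (keeps per-subject matrices stable for moderate
    slopes).
    """

    covariate: str  # "age" | "fsiq" | "dosage_ratio"
    source: str
    target: str
    slope: float
    condition: str | None = None  # None = all conditions
    phase: str | None = None  # None = all phases


@dataclass(frozen=True)
class CovariateModel:
    """Distributions for subject covariates, per group.

    Age and FSIQ are Gaussian; defaults follow the cohort the generator
    emulates (HC: age 28 +/- 7, FSIQ 101.29 +/- 10.55; SCZ: age 29 +/- 8,
    FSIQ 87.74 +/- 6.06).  The PDD/DDD dosage ratio is log-normal and
    drawn for the patient group only.
    """

    age_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 28.0, "SCZ": 29.0}
    )
    age_sd: dict[str, float] = field(default_factory=lambda: {"HC": 7.0, "SCZ": 8.0})
    fsiq_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 101.29, "SCZ": 87.74}
    )
    fsiq_sd: dict[str, float] = field(
        default_factory=lambda: {"HC": 10.55, "SCZ": 6.06}
    )
    dosage_log_mean: float = 0.0
    dosage_log_sd: float = 0.5
    edge_links: tuple[EdgeLink, ...] = ()

    def draw(self, group: str, rng: np.random.Generator) -> dict[str, float | None]:
        age = rng.normal(self.age_mean[group], self.age_sd[group])
        fsiq = rng.normal(self.fsiq_mean[group], self.fsiq_sd[group])
        dosage = (
            float(rng.lognormal(self.dosage_log_mean, self.dosage_log_sd))
            if group == "SCZ"
            else None
        )
        return {"age": float(age), "fsiq": float(fsiq), "dosage_ratio": dosage}

    def standardize(self, covariate: str, group: str, value: float) -> float:
        if covariate == "age":
            z = (value - self.age_mean[group]) / self.age_sd[group]
        elif covariate == "fsiq":
            z = (value - self.fsiq_mean[group]) / self.fsiq_sd[group]
        elif covariate == "dosage_ratio":
            z = (math.log(value) - self.dosage_log_mean) / self.dosage_log_sd
        else:
            raise ConfigError(f"unknown covariate {covariate!r}")
        return float(np.clip(z, -3.0, 3.0))


def _apply_edge_links(
    specs: list[CouplingSpec],
    links: tuple[EdgeLink, ...],
    subject: SubjectRecord,
    model: CovariateModel,
    node_labels: tuple[str, ...],
) -> list[CouplingSpec]:
    if not links:
        return specs
    index = {lab: i for i, lab in enumerate(node_labels)}
    out = []
    for spec in specs:
        B = spec.B.copy()
        touched = False
        for link in links:
            if link.condition is not None and link.condition != spec.condition:
                continue
            if link.phase is not None and link.phase not in (spec.phase, BOTH):
                continue
            value = getattr(subject, link.covariate)
            if value is None:
                continue
            z = model.standardize(link.covariate, subject.group, value)
            B[index[link.target], index[link.source]] += link.slope * z
            touched = True
        out.append(replace(spec, B=B) if touched else spec)
    return out


# ---------------------------------------------------------------------------
# default ground-truth coupling


def _edges_matrix(
    edges: dict[tuple[str, str], float],
    labels: tuple[str, ...] = DEFAULT_NODE_LABELS,
    diag: float = 0.3,
) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(labels)}
    B = np.eye(len(labels)) * diag
    for (src, tgt), w in edges.items():
        B[idx[tgt], idx[src]] = w
    return B


#: Edges that differ between groups in each condition x phase cell.
#: Early Encoding: a frontal-hippocampal-fusiform set, reduced in SCZ.
#: Late Encoding: pathways toward the dlPFC, reduced in SCZ.
#: Early Retrieval: pathways to/from the dACC, increased in SCZ.
#: Late Retrieval: toward dlPFC increased, from dlPFC decreased in SCZ.
DEFAULT_EFFECT_EDGES: dict[tuple[str, str], list[tuple[str, str, str]]] = {
    (ENCODING, EARLY): [
        ("dlPFC", "HPC", "reduced"),
        ("dlPFC", "FG", "reduced"),
        ("HPC", "FG", "reduced"),
        ("dACC", "dlPFC", "reduced"),
        ("HPC", "dlPFC", "reduced"),
        ("FG", "ITG", "reduced"),
    ],
    (ENCODING, LATE): [
        ("dACC", "dlPFC", "reduced"),
        ("HPC", "dlPFC", "reduced"),
        ("FG", "dlPFC", "reduced"),
    ],
    (RETRIEVAL, EARLY): [
        ("dlPFC", "dACC", "increased"),
        ("dACC", "HPC", "increased"),
        ("SP", "dACC", "increased"),
    ],
    (RETRIEVAL, LATE): [
        ("dACC", "dlPFC", "increased"),
        ("dlPFC", "HPC", "reduced"),
        ("dlPFC", "FG", "reduced"),
    ],
}

STRONG_COUPLING = 0.35
WEAK_COUPLING = 0.05


def default_group_specs(
    noise_sd: float = 1.0,
    strong: float = STRONG_COUPLING,
    weak: float = WEAK_COUPLING,
) -> dict[str, list[CouplingSpec]]:
    """Ground-truth coupling for both groups over all schedule cells.

    Group differences follow :data:`DEFAULT_EFFECT_EDGES`: on each
    listed edge one group carries ``strong`` coupling and the other
    ``weak``, with 'reduced' meaning SCZ < HC.  Rest epochs get weak
    diagonal-only coupling and are excluded from the dFC analysis by
    default.
    """
    specs: dict[str, list[CouplingSpec]] = {g: [] for g in GROUPS}
    for (condition, phase), effects in DEFAULT_EFFECT_EDGES.items():
        for group in GROUPS:
            edges = {}
            for src, tgt, direction in effects:
                if group == "HC":
                    edges[(src, tgt)] = strong if direction == "reduced" else weak
                else:
                    edges[(src, tgt)] = weak if direction == "reduced" else strong
            specs[group].append(
                CouplingSpec(
                    condition=condition,
                    phase=phase,
                    B=_edges_matrix(edges),
                    noise_sd=noise_sd,
                )
            )
    for group in GROUPS:
        specs[group].append(
            CouplingSpec(
                condition=REST,
                phase=BOTH,
                B=np.eye(len(DEFAULT_NODE_LABELS)) * 0.2,
                noise_sd=noise_sd,
            )
        )
    return specs


def null_group_specs(noise_sd: float = 1.0) -> dict[str, list[CouplingSpec]]:
    """Identical coupling in both groups (for null-calibration studies)."""
    base = default_group_specs(noise_sd=noise_sd)
    return {"HC": base["HC"], "SCZ": base["HC"]}


# ---------------------------------------------------------------------------
# cohort


def subject_seed_sequences(
    seed: int, n: int
) -> list[np.random.SeedSequence]:
    """Deterministic per-subject seed streams spawned from one master seed."""
    return list(np.random.SeedSequence(seed).spawn(n))


def simulate_cohort(
    group_specs: dict[str, list[CouplingSpec]] | None = None,
    n_hc: int = 24,
    n_scz: int = 31,
    schedule: DesignSchedule | None = None,
    covariate_model: CovariateModel | None = None,
    seed: int = 0,
    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS,
    smoothing_tau_s: float | None = None,
) -> list[NodeTimeSeries]:
    """Simulate a two-group cohort with group-specific coupling.

    Defaults emulate the study cohort: 24 HC and 31 SCZ subjects on the
    default 288-volume schedule.  Per-subject randomness comes from seed
    streams spawned deterministically from the master seed, so the whole
    cohort is reproducible from (specs, seed).
    """
    if n_hc < 1 or n_scz < 1:
        raise ConfigError("group sizes must be >= 1")
    if group_specs is None:
        group_specs = default_group_specs()
    if schedule is None:
        schedule = make_design_schedule()
    model = covariate_model if covariate_model is not None else CovariateModel()

    memberships = [("HC", i + 1) for i in range(n_hc)] + [
        ("SCZ", i + 1) for i in range(n_scz)
    ]
    seqs = subject_seed_sequences(seed, len(memberships))
    cohort: list[NodeTimeSeries] = []
    for (group, k), seq in zip(memberships, seqs):
        rng = np.random.default_rng(seq)
        cov = model.draw(group, rng)
        subject = SubjectRecord(
            subject_id=f"{group}{k:02d}",
            group=group,
            age=cov["age"],
            fsiq=cov["fsiq"],
            dosage_ratio=cov["dosage_ratio"],
        )
        specs = _apply_edge_links(
            group_specs[group], model.edge_links, subject, model, node_labels
        )
        cohort.append(
            simulate_network_timeseries(
                specs, schedule, subject, rng, node_labels=node_labels,
                smoothing_tau_s=smoothing_tau_s,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class GompertzGroupParams:
    """Group-level Gompertz parameter means and between-subject SDs."""

    a: float
    b: float
    c: float
    a_sd: float = 0.0
    b_sd: float = 0.0
    c_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.a <= 1:
            raise ConfigError("asymptote a must be in (0, 1]")
        if min(self.a_sd, self.b_sd, self.c_sd) < 0:
            raise ConfigError("between-subject SDs must be >= 0")


#: Defaults: patients reach a lower asymptote and transition to the
#: asymptotic regime later than controls.
DEFAULT_GOMPERTZ_PARAMS: dict[str, GompertzGroupParams] = {
    "HC": GompertzGroupParams(a=0.90, b=1.0, c=0.9, a_sd=0.08, b_sd=0.3, c_sd=0.15),
    "SCZ": GompertzGroupParams(a=0.75, b=1.2, c=0.6, a_sd=0.08, b_sd=0.3, c_sd=0.15),
}


def _gompertz(a: float, b: float, c: float, t: np.ndarray) -> np.ndarray:
    return a * np.exp(-np.exp(b - c * t))


def simulate_learning_curves(
    subjects: list[SubjectRecord],
    group_params: dict[str, GompertzGroupParams] | None = None,
    n_items: int = 9,
    n_blocks: int = 8,
    seed: int = 0,
    noise: str = "binomial",
) -> list[BehavioralRecord]:
    """Simulate per-block recall fractions from Gompertz learning curves.

    Per subject, (a, b, c) are drawn around the group means; the block-t
    success probability is a*exp(-exp(b - c*t)) and the observed count
    is Binomial(n_items, p) (or round(p * n_items) in noise-free mode,
    ``noise="none"``).
    """
    if n_items < 1:
        raise ConfigError("n_items must be >= 1")
    if n_blocks < 2:
        raise ConfigError("n_blocks must be >= 2")
    if noise not in ("binomial", "none"):
        raise ConfigError("noise must be 'binomial' or 'none'")
    params = group_params if group_params is not None else DEFAULT_GOMPERTZ_PARAMS
    t = np.arange(1, n_blocks + 1, dtype=float)
    for g, p in params.items():
        mean_curve = _gompertz(p.a, p.b, p.c, t)
        if np.any(mean_curve < 0) or np.any(mean_curve > 1):
            raise ConfigError(f"mean curve for group {g!r} leaves [0, 1]")

    seqs = subject_seed_sequences(seed, len(subjects))
    records = []
    for subject, seq in zip(subjects, seqs):
        rng = np.random.default_rng(seq)
        p = params[subject.group]
        a = float(np.clip(rng.normal(p.a, p.a_sd) if p.a_sd else p.a, 0.0, 1.0))
        b = float(rng.normal(p.b, p.b_sd) if p.b_sd else p.b)
        c = float(rng.normal(p.c, p.c_sd) if p.c_sd else p.c)
        prob = np.clip(_gompertz(a, b, c, t), 0.0, 1.0)
        if noise == "binomial":
            counts = rng.binomial(n_items, prob)
        else:
            counts = np.rint(prob * n_items).astype(int)
        records.append(
            BehavioralRecord(
                subject=subject, n_items=n_items, fractions=counts / n_items
            )
        )
    return records
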