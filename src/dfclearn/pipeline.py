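"""End-to-end orchestration: simulate -> segment -> fit -> infer -> write.

A run is fully reproducible from (config, seed): the resolved config is
written next to the outputs, and a structured log records exclusions,
warnings and package versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    behavior_table,
    fit_cohort_gompertz,
    mixed_anova,
    parameter_group_contrasts,
)
from .config import PipelineConfig
from .design import EARLY, ENCODING, LATE, RETRIEVAL, make_design_schedule
from .exceptions import DataError
from .groupstats import (
    behavior_covariate_tests,
    behavioral_metrics,
    bh_fdr,
    compare_groups,
    covariate_regression,
)
from .io import (
    write_behavior,
    write_connectome_ring,
    write_schedule,
    write_subjects,
    write_table,
    write_timeseries,
)
from .mvar import EdgeCoefficientPanel, build_edge_panel
from .synth import simulate_cohort, simulate_learning_curves

logger = logging.getLogger(__name__)

ANALYSIS_CELLS = [
    (ENCODING, EARLY),
    (ENCODING, LATE),
    (RETRIEVAL, EARLY),
    (RETRIEVAL, LATE),
]


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run computed."""

    config: PipelineConfig
    schedule: object
    cohort: list
    behavior: pd.DataFrame
    gompertz_fits: pd.DataFrame
    anova: pd.DataFrame
    parameter_contrasts: pd.DataFrame
    panels: dict[tuple[str, str], EdgeCoefficientPanel]
    edge_stats: dict[tuple[str, str], pd.DataFrame]
    covariate_tables: dict[tuple[str, str, str], pd.DataFrame]
    behavior_covariates: pd.DataFrame
    log: dict = field(default_factory=dict)


def _apply_global_family(
    edge_stats: dict[tuple[str, str], pd.DataFrame], q: float
) -> None:
    """Re-adjust p values in one BH family across all condition x phase cells."""
    keys = list(edge_stats)
    pooled = np.concatenate([edge_stats[k]["p"].to_numpy() for k in keys])
    qvals, reject = bh_fdr(pooled, q=q)
    i = 0
    for k in keys:
        n = len(edge_stats[k])
        edge_stats[k]["q"] = qvals[i : i + n]
        edge_stats[k]["significant"] = reject[i : i + n]
        i += n


def run_pipeline(
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute the full analysis on a simulated cohort.

    Stages: simulate the cohort and behavior; fit Gompertz curves and
    the mixed ANOVA; build the four Encoding/Retrieval x Early/Late
    edge panels; run group comparisons and covariate regressions
    (dosage within the patient group; age and FSIQ across everyone);
    write all tables as tab-delimited text plus JSON sidecars.
    """
    cfg = config or PipelineConfig()
    run_log: dict = {"version": __version__, "warnings": [], "exclusions": []}

    schedule = make_design_schedule(
        tr_s=cfg.design.tr_s,
        epoch_len_s=cfg.design.epoch_len_s,
        n_cycles=cfg.design.n_cycles,
    )
    cohort = simulate_cohort(
        group_specs=cfg.group_specs(),
        n_hc=cfg.simulation.n_hc,
        n_scz=cfg.simulation.n_scz,
        schedule=schedule,
        covariate_model=cfg.covariates,
        seed=cfg.simulation.seed,
        node_labels=cfg.node_labels,
        smoothing_tau_s=cfg.simulation.smoothing_tau_s,
    )
    subjects = [ts.subject for ts in cohort]
    behavior_records = simulate_learning_curves(
        subjects,
        group_params=cfg.behavior.gompertz,
        n_items=cfg.behavior.n_items,
        n_blocks=cfg.design.n_cycles,
        seed=cfg.simulation.seed + 1,
        noise=cfg.behavior.noise,
    )
    behavior = behavior_table(behavior_records)

    if cfg.design.n_cycles >= 3:
        fits = fit_cohort_gompertz(behavior_records)
        n_failed = int((~fits["converged"]).sum())
        if n_failed:
            run_log["exclusions"].append(
                {"stage": "behavior", "n_subjects": n_failed, "reason": "fit failure"}
            )
        contrasts = parameter_group_contrasts(fits)
    else:
        # a 3-parameter curve needs at least 3 retrieval blocks
        fits = pd.DataFrame(
            columns=["subject", "group", "a", "b", "c", "inflection_time",
                     "sse", "converged", "degenerate"]
        )
        contrasts = pd.DataFrame()
        run_log["warnings"].append(
            "learning-curve fitting skipped: fewer than 3 retrieval blocks"
        )
    anova = mixed_anova(behavior).table

    panels: dict[tuple[str, str], EdgeCoefficientPanel] = {}
    edge_stats: dict[tuple[str, str], pd.DataFrame] = {}
    for condition, phase in ANALYSIS_CELLS:
        panel = build_edge_panel(
            cohort,
            condition,
            phase,
            mode=cfg.estimation.mode,
            p=cfg.estimation.p,
            hemodynamic_offset_volumes=cfg.estimation.hemodynamic_offset,
            include_intercept=cfg.estimation.include_intercept,
            demean=cfg.estimation.demean,
        )
        panels[(condition, phase)] = panel
        edge_stats[(condition, phase)] = compare_groups(
            panel, q_threshold=cfg.inference.q_threshold
        )
    if cfg.inference.family == "global":
        _apply_global_family(edge_stats, cfg.inference.q_threshold)

    covars = pd.DataFrame(
        {
            "age": {s.subject_id: s.age for s in subjects},
            "fsiq": {s.subject_id: s.fsiq for s in subjects},
            "dosage_ratio": {s.subject_id: s.dosage_ratio for s in subjects},
        }
    )
    covariate_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    for (condition, phase), panel in panels.items():
        for cov_name in ("age", "fsiq", "dosage_ratio"):
            series = covars[cov_name]
            if cov_name == "dosage_ratio":
                # dosage analysis runs within the patient group only
                series = series[panel.groups == "SCZ"]
            try:
                covariate_tables[(condition, phase, cov_name)] = covariate_regression(
                    panel, series, q_threshold=cfg.inference.q_threshold,
                    covariate_name=cov_name,
                )
            except DataError as e:
                run_log["warnings"].append(
                    f"covariate {cov_name} skipped for ({condition}, {phase}): {e}"
                )

    if len(fits):
        metrics = behavioral_metrics(behavior, fits, n_blocks=cfg.design.n_cycles)
        # dosage vs behavior within patients; age/FSIQ across all subjects
        beh_cov_frames = [
            behavior_covariate_tests(metrics, covars[["age", "fsiq"]]),
        ]
        dosage = covars["dosage_ratio"].dropna()
        if len(dosage) >= 3:
            beh_cov_frames.append(
                behavior_covariate_tests(
                    metrics.loc[metrics.index.isin(dosage.index)], dosage.to_frame()
                )
            )
        behavior_covariates = pd.concat(beh_cov_frames, ignore_index=True)
    else:
        behavior_covariates = pd.DataFrame()

    result = PipelineResult(
        config=cfg,
        schedule=schedule,
        cohort=cohort,
        behavior=behavior,
        gompertz_fits=fits,
        anova=anova,
        parameter_contrasts=contrasts,
        panels=panels,
        edge_stats=edge_stats,
        covariate_tables=covariate_tables,
        behavior_covariates=behavior_covariates,
        log=run_log,
    )
    if write_outputs:
        out = Path(output_dir or cfg.output_dir)
        _write_bundle(result, out)
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    cfg = result.config
    out.mkdir(parents=True, exist_ok=True)
    cfg.dump(out / "config_resolved.toml")
    write_schedule(result.schedule, out / "schedule.tsv")
    write_subjects([ts.subject for ts in result.cohort], out / "subjects.tsv")
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in result.cohort:
        write_timeseries(ts, ts_dir / f"{ts.subject.subject_id}.tsv")
    write_behavior_frame = result.behavior
    write_behavior_frame.to_csv(out / "behavior.tsv", sep="\t", index=False)
    write_table(result.gompertz_fits, out / "gompertz_fits.tsv")
    write_table(result.anova, out / "anova.tsv")
    (out / "anova.json").write_text(
        result.anova.to_json(orient="records", indent=2) + "\n"
    )
    write_table(result.parameter_contrasts, out / "parameter_contrasts.tsv")
    for (condition, phase), table in result.edge_stats.items():
        stem = f"{condition.lower()}_{phase.lower()}"
        sidecar = {
            "condition": condition,
            "phase": phase,
            "mode": cfg.estimation.mode,
            "p": cfg.estimation.p,
            "q_threshold": cfg.inference.q_threshold,
            "family": cfg.inference.family,
        }
        write_table(table, out / f"edge_stats_{stem}.tsv", sidecar=sidecar)
        write_connectome_ring(table, out / f"ring_{stem}.tsv")
        panel = result.panels[(condition, phase)]
        panel.to_long_frame().to_csv(
            out / f"edge_panel_{stem}.tsv", sep="\t", index=False
        )
    for (condition, phase, cov), table in result.covariate_tables.items():
        stem = f"{cov}_{condition.lower()}_{phase.lower()}"
        write_table(table, out / f"covariate_{stem}.tsv")
    write_table(result.behavior_covariates, out / "behavior_covariates.tsv")
    (out / "run_log.json").write_text(json.dumps(result.log, indent=2) + "\n")
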