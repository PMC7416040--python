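"""Tab-delimited table I/O for time series, schedules and results.

All tables are plain text (tab-separated, one header row) so a run's
outputs can be inspected, diffed and versioned.  Time-series files have
one column per node and one row per volume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSchedule, make_design_schedule
from .exceptions import DataError
from .synth import BehavioralRecord, NodeTimeSeries, SubjectRecord

SEP = "\t"


def write_timeseries(ts: NodeTimeSeries, path: str | Path) -> None:
    frame = pd.DataFrame(ts.data, columns=list(ts.node_labels))
    frame.to_csv(path, sep=SEP, index=False)


def read_timeseries(
    path: str | Path,
    subject: SubjectRecord,
    schedule: DesignSchedule,
) -> NodeTimeSeries:
    frame = pd.read_csv(path, sep=SEP)
    return NodeTimeSeries(
        subject=subject,
        schedule=schedule,
        node_labels=tuple(frame.columns),
        data=frame.to_numpy(dtype=float),
    )


def write_schedule(schedule: DesignSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, sep=SEP, index=False)


def subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": s.subject_id,
                "group": s.group,
                "age": s.age,
                "fsiq": s.fsiq,
                "dosage_ratio": s.dosage_ratio,
            }
            for s in subjects
        ]
    )


def write_subjects(subjects: list[SubjectRecord], path: str | Path) -> None:
    subjects_frame(subjects).to_csv(path, sep=SEP, index=False)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path, sep=SEP)
    required = {"subject", "group"}
    if not required.issubset(frame.columns):
        raise DataError(f"subjects table needs columns {sorted(required)}")

    def _opt(row, col):
        if col not in frame.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    return [
        SubjectRecord(
            subject_id=str(row["subject"]),
            group=str(row["group"]),
            age=_opt(row, "age"),
            fsiq=_opt(row, "fsiq"),
            dosage_ratio=_opt(row, "dosage_ratio"),
        )
        for _, row in frame.iterrows()
    ]


def write_behavior(records: list[BehavioralRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for block, fr in enumerate(rec.fractions, start=1):
            rows.append(
                {
                    "subject": rec.subject.subject_id,
                    "group": rec.subject.group,
                    "block": block,
                    "fraction": float(fr),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=SEP)
    required = {"subject", "block", "fraction"}
    if not required.issubset(frame.columns):
        raise DataError(f"behavior table needs columns {sorted(required)}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a result table; provenance goes into a JSON sidecar."""
    frame.to_csv(path, sep=SEP, index=False)
    if sidecar:
        import json

        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def write_connectome_ring(stat_table: pd.DataFrame, path: str | Path) -> None:
    """Machine-readable edge list for ring plots: source, target, signed
    difference, significance."""
    ring = stat_table[["source", "target", "difference", "significant"]].copy()
    ring.to_csv(path, sep=SEP, index=False)
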