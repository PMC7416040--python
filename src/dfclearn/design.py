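"""Block-design paradigm bookkeeping: node sets and epoch schedules.

The task paradigm alternates Encoding, Rest, Retrieval and Rest epochs of
equal duration, repeated over a number of cycles.  The first half of the
cycles is the Early phase of learning (approximately linear gains in
recall), the second half the Late phase (asymptotic performance).  Every
acquired volume carries exactly one (epoch, cycle, phase) label; all
downstream segmentation works off these labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError

ENCODING = "Encoding"
REST = "Rest"
RETRIEVAL = "Retrieval"
EARLY = "Early"
LATE = "Late"
BOTH = "Both"

#: One task cycle: study the item-location pairs, rest, recall, rest.
DEFAULT_EPOCH_ORDER: tuple[str, ...] = (ENCODING, REST, RETRIEVAL, REST)

#: Six-node learning network: dorsolateral prefrontal cortex, dorsal
#: anterior cingulate, hippocampus, superior parietal cortex, fusiform
#: gyrus, inferior temporal gyrus.
DEFAULT_NODE_LABELS: tuple[str, ...] = ("dlPFC", "dACC", "HPC", "SP", "FG", "ITG")


@dataclass(frozen=True)
class NodeSet:
    """An ordered set of network nodes, optionally with MNI centroids.

    Parameters
    ----------
    labels
        Unique node names, in a fixed order that defines edge ordering.
    centroids
        Optional (N, 3) array of MNI world coordinates in mm.
    radius_mm
        Sphere radius for ROI extraction; required positive when
        centroids are given.
    """

    labels: tuple[str, ...] = DEFAULT_NODE_LABELS
    centroids: np.ndarray | None = None
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ConfigError("node labels must be unique")
        if self.centroids is not None:
            cent = np.asarray(self.centroids, dtype=float)
            if cent.shape != (len(self.labels), 3):
                raise ConfigError(
                    f"centroids must have shape ({len(self.labels)}, 3), got {cent.shape}"
                )
            object.__setattr__(self, "centroids", cent)
            if self.radius_mm is None or not self.radius_mm > 0:
                raise ConfigError("radius_mm must be > 0 when centroids are given")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        """Number of ordered directed edges, N(N-1)."""
        n = self.n_nodes
        return n * (n - 1)

    def edges(self) -> list[tuple[str, str]]:
        """Ordered (source, target) pairs, row-major by target then source.

        For the default 6-node set this yields exactly 30 directed edges.
        """
        return [
            (src, tgt)
            for tgt in self.labels
            for src in self.labels
            if src != tgt
        ]

    def edge_names(self) -> list[str]:
        """Edge column names in stable order, ``source->target``."""
        return [f"{s}->{t}" for s, t in self.edges()]


@dataclass(frozen=True)
class DesignSchedule:
    """Per-volume labeling of the block paradigm.

    ``volume_labels`` has one row per volume with columns
    ``volume`` (0-based), ``epoch`` (kind), ``cycle`` (1-based),
    ``phase`` (Early/Late) and ``epoch_index`` (0-based global counter
    of epoch instances, so contiguous runs never merge across epochs).
    """

    tr_s: float
    epoch_len_s: float
    epoch_order: tuple[str, ...]
    n_cycles: int
    volume_labels: pd.DataFrame = field(repr=False)

    @property
    def volumes_per_epoch(self) -> int:
        return int(round(self.epoch_len_s / self.tr_s))

    @property
    def n_volumes(self) -> int:
        return self.n_cycles * len(self.epoch_order) * self.volumes_per_epoch

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.epoch_order))

    def to_frame(self) -> pd.DataFrame:
        return self.volume_labels.copy()


def make_design_schedule(
    tr_s: float = 3.0,
    epoch_len_s: float = 27.0,
    n_cycles: int = 8,
    epoch_order: tuple[str, ...] = DEFAULT_EPOCH_ORDER,
) -> DesignSchedule:
    """Build the fully labeled block-design schedule.

    Defaults reproduce the study design: TR = 3 s, 27 s epochs in
    Encoding/Rest/Retrieval/Rest order, 8 cycles -> 288 volumes with 9
    volumes per epoch; cycles 1-4 are Early, cycles 5-8 Late.

    Raises
    ------
    ConfigError
        If ``epoch_len_s`` is not an integer multiple of ``tr_s`` or
        ``n_cycles`` is odd (the Early/Late split would be undefined).
    """
    if not tr_s > 0:
        raise ConfigError("tr_s must be > 0")
    if not epoch_len_s > 0:
        raise ConfigError("epoch_len_s must be > 0")
    ratio = epoch_len_s / tr_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError(
            f"epoch_len_s ({epoch_len_s}) must be an integer multiple of tr_s ({tr_s})"
        )
    if n_cycles < 2 or n_cycles % 2 != 0:
        raise ConfigError("n_cycles must be an even integer >= 2 (Early/Late split)")
    if not epoch_order:
        raise ConfigError("epoch_order must be non-empty")

    vpe = int(round(ratio))
    records: list[tuple[int, str, int, str, int]] = []
    volume = 0
    epoch_index = 0
    for cycle in range(1, n_cycles + 1):
        phase = EARLY if cycle <= n_cycles // 2 else LATE
        for kind in epoch_order:
            for _ in range(vpe):
                records.append((volume, kind, cycle, phase, epoch_index))
                volume += 1
            epoch_index += 1
    labels = pd.DataFrame.from_records(
        records, columns=["volume", "epoch", "cycle", "phase", "epoch_index"]
    )
    return DesignSchedule(
        tr_s=float(tr_s),
        epoch_len_s=float(epoch_len_s),
        epoch_order=tuple(epoch_order),
        n_cycles=int(n_cycles),
        volume_labels=labels,
    )
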