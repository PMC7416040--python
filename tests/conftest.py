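import dataclasses

import numpy as np
import pytest

import dfclearn as d
from dfclearn.config import PipelineConfig, SimulationConfig


@pytest.fixture(scope="session")
def default_schedule():
    return d.make_design_schedule()


@pytest.fixture(scope="session")
def small_schedule():
    """Two-cycle schedule: one epoch per condition and phase, 9 volumes each."""
    return d.make_design_schedule(tr_s=3.0, epoch_len_s=27.0, n_cycles=2)


@pytest.fixture(scope="session")
def small_cohort(default_schedule):
    """12-subject cohort on the default schedule with default coupling."""
    return d.simulate_cohort(
        n_hc=6, n_scz=6, schedule=default_schedule, seed=2024
    )


@pytest.fixture
def small_config():
    return dataclasses.replace(
        PipelineConfig(), simulation=SimulationConfig(n_hc=5, n_scz=6, seed=7)
    )


def single_epoch_series(B, n_volumes, seed, noise_sd=1.0, intercept=None):
    """Simulate one long VAR(1) segment and wrap it for fitting."""
    n = np.asarray(B).shape[0]
    labels = tuple(f"n{i}" for i in range(n))
    schedule = d.make_design_schedule(
        tr_s=1.0, epoch_len_s=float(n_volumes), n_cycles=2, epoch_order=("Encoding",)
    )
    spec = d.CouplingSpec(
        "Encoding", "Both", np.asarray(B, dtype=float),
        intercept=intercept, noise_sd=noise_sd,
    )
    subject = d.SubjectRecord("sim", "HC")
    ts = d.simulate_network_timeseries(
        [spec], schedule, subject, seed, node_labels=labels
    )
    # both epochs of the schedule, as separate segments
    segs = tuple(
        ts.data[block["volume"].to_numpy()]
        for _, block in schedule.volume_labels.groupby("epoch_index")
    )
    return d.SegmentedSeries(
        segments=segs, node_labels=labels, condition="Encoding", phase="Both"
    )
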