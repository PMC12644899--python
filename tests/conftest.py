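"""Shared fixtures: small designs and session-scoped simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epespike.calibration import (
    day1_detected_counts,
    day_night_rate_contrast,
    infested_cohort_design,
    run_cohort,
)
from epespike.design import ExperimentDesign
from epespike.synth import NoiseModel, SpikeTrainParams

SEED = 20260922


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseModel:
    """No drift, no broadband noise, no irrigation bursts — events only."""
    return NoiseModel(white_noise_sd=0.0, drift_sd_per_hour=0.0,
                      irrigation_extra_rate=0.0,
                      electrode_sensitivity_half_life=float("inf"))


@pytest.fixture(scope="session")
def day1_cohort():
    """20 infested plants over the first infestation day, full pipeline.

    Returns (design, traces, ground truth, detected spike table)."""
    design = infested_cohort_design(20)
    traces, truth, spikes = run_cohort(design, seed=SEED)
    return design, traces, truth, spikes


@pytest.fixture(scope="session")
def day1_counts(day1_cohort) -> np.ndarray:
    design, traces, _, spikes = day1_cohort
    t_dai = design.recording_start_day + spikes["time_s"] / 86400.0
    day1 = spikes[(t_dai >= 0.0) & (t_dai < 1.0)]
    per_channel = day1.groupby("channel_id").size()
    return np.array([per_channel.get(t.channel_id, 0) for t in traces], dtype=int)


@pytest.fixture(scope="session")
def ratio_cohort():
    """100 infested plant-days through the full pipeline (day:night contrast)."""
    return day_night_rate_contrast(n_plant_days=100, seed=SEED)


@pytest.fixture(scope="session")
def truncation_cohort():
    """Large flat-diurnal cohort for amplitude-distribution laws.

    Flat day/night profile and frozen electrode sensitivity isolate the
    threshold-truncation effect; 2 s sampling keeps it fast.
    Returns (design, ground truth, detected spike table)."""
    train = SpikeTrainParams(day_night_rate_ratio=1.0)
    noise = NoiseModel(electrode_sensitivity_half_life=float("inf"))
    design = infested_cohort_design(160, sample_interval=2.0)
    _, truth, spikes = run_cohort(design, seed=SEED, train=train, noise=noise)
    return design, truth, spikes


def single_arm_design(treatment: str, *, n_pots: int, insects: int,
                      stage: str = "R5", start: float = -0.25, end: float = 1.0,
                      removal_day=None, locations=("stem",),
                      sample_interval: float = 1.0,
                      experiment_id: str = "scenario") -> ExperimentDesign:
    """One treatment arm with a short recording span for fast tests."""
    return ExperimentDesign(
        experiment_id=experiment_id,
        growth_stage=stage,
        n_pots=n_pots,
        insects_per_pot=0 if treatment == "non_infested" else insects,
        treatment=treatment,
        removal_day=removal_day,
        electrode_insertion_day=-3.0,
        recording_start_day=start,
        recording_end_day=end,
        irrigation_times=(),
        sample_interval=sample_interval,
        electrode_locations=locations,
    )
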