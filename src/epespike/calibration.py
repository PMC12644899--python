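"""Calibration cohorts: does the full pipeline recover the generator's
published operating points?

These helpers run the complete chain — simulate, preprocess, detect,
window — on seeded cohorts of infested plants and report the quantities
the model is calibrated against: the first-day detected-spike count per
plant (expected median inside 20–80), the day:night contrast of mean
hourly detected rates (expected near the injected 3.7), and the amplitude
model summaries (mean 1.9 mV, SD 0.8 mV, 99th percentile below 5 mV).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .design import ExperimentDesign
from .detect import DetectionParams, detect_spikes, events_to_frame
from .preprocess import FilterSpec, preprocess
from .quantify import DayNightRatio, median_day_night_ratio, select_windows, window_counts
from .synth import NoiseModel, SpikeTrainParams, sample_amplitudes, simulate_experiment
from .trace import SECONDS_PER_DAY

__all__ = [
    "infested_cohort_design",
    "run_cohort",
    "day1_detected_counts",
    "day_night_rate_contrast",
    "amplitude_model_summary",
]


def infested_cohort_design(n_plants: int,
                           insects_per_pot: int = 50,
                           recording_start_day: float = -0.25,
                           recording_end_day: float = 1.0,
                           sample_interval: float = 1.0,
                           experiment_id: str = "calibration",
                           ) -> ExperimentDesign:
    """Single-arm cohort of continuously infested R5 plants, stem channel,
    no irrigation inside the analysed span (benchmark-style infestation)."""
    return ExperimentDesign(
        experiment_id=experiment_id,
        growth_stage="R5",
        n_pots=n_plants,
        insects_per_pot=insects_per_pot,
        treatment="infested_untreated",
        electrode_insertion_day=-4.0,
        recording_start_day=recording_start_day,
        recording_end_day=recording_end_day,
        irrigation_times=(),
        sample_interval=sample_interval,
        electrode_locations=("stem",),
    )


def run_cohort(design: ExperimentDesign, seed,
               train: Optional[SpikeTrainParams] = None,
               noise: Optional[NoiseModel] = None):
    """Simulate one arm and run preprocessing + detection on every channel.

    Returns (traces, ground truth, detected spike table)."""
    spec = FilterSpec()
    params = DetectionParams()
    traces, truth = simulate_experiment(
        design, train=train, noise=noise, seed=seed, filter_spec=spec)
    events = []
    for t in traces:
        events.extend(detect_spikes(preprocess(t, spec), params))
    return traces, truth, events_to_frame(events)


def day1_detected_counts(n_plants: int = 20, seed=0,
                         train: Optional[SpikeTrainParams] = None,
                         noise: Optional[NoiseModel] = None) -> np.ndarray:
    """Detected spikes in the first 24 h of infestation, one value per plant."""
    design = infested_cohort_design(n_plants)
    traces, _, spikes = run_cohort(design, seed, train, noise)
    t_dai = design.recording_start_day + spikes["time_s"] / SECONDS_PER_DAY
    day1 = spikes[(t_dai >= 0.0) & (t_dai < 1.0)]
    per_channel = day1.groupby("channel_id").size()
    return np.array([per_channel.get(t.channel_id, 0) for t in traces], dtype=int)


def day_night_rate_contrast(n_plant_days: int = 100, seed=0,
                            train: Optional[SpikeTrainParams] = None,
                            noise: Optional[NoiseModel] = None,
                            days_per_plant: int = 5) -> DayNightRatio:
    """Full-pipeline day:night hourly-rate contrast pooled over infested
    plant-days.

    ``n_plant_days`` hourly-windowed infestation days are pooled from a
    cohort of ``n_plant_days / days_per_plant`` plants recorded over the
    first ``days_per_plant`` days of continuous infestation; the contrast
    is the mean hourly detected count over all day windows divided by the
    mean over all night windows.
    """
    if n_plant_days % days_per_plant:
        raise ValueError("n_plant_days must be a multiple of days_per_plant")
    design = infested_cohort_design(n_plant_days // days_per_plant,
                                    recording_end_day=float(days_per_plant))
    traces, _, spikes = run_cohort(design, seed, train, noise)
    hourly = window_counts(spikes, design, window_hours=1.0, phase_split=True,
                           channels=[t.channel_id for t in traces])
    return median_day_night_ratio(
        select_windows(hourly, 0.0, float(days_per_plant)))


def amplitude_model_summary(n: int = 10000, seed=0,
                            train: Optional[SpikeTrainParams] = None,
                            ) -> dict:
    """Sample mean, sample SD and 99th percentile of generator amplitude
    draws (mV)."""
    amps = sample_amplitudes(n, train or SpikeTrainParams(), seed)
    return {
        "mean_mV": float(np.mean(amps)),
        "sd_mV": float(np.std(amps, ddof=1)),
        "p99_mV": float(np.percentile(amps, 99)),
        "n": int(n),
    }
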