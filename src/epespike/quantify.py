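"""Windowed spike quantification.

Turns detected events into the model's reported quantities: counts per
half-open time window aligned to the infestation instant (DAI 0), the
log10(x + 1) transform used for all count statistics, day/night hourly
rates under the 14 h / 10 h photoperiod, the day:night ratio (median-based
as published, with a mean-rate companion), amplitude summaries, the
peak-aligned average spike waveform, and the threshold/passband separation
sweep that motivates the 1 mV threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .detect import DetectionParams, detect_spikes, events_to_frame
from .preprocess import FilterSpec, bandpass, remove_baseline
from .trace import SECONDS_PER_DAY, RecordingTrace

__all__ = [
    "log_transform",
    "day_night_label",
    "window_counts",
    "select_windows",
    "DayNightRatio",
    "median_day_night_ratio",
    "amplitude_summary",
    "average_spike_waveform",
    "parameter_sweep",
]

WINDOW_COLUMNS = ["channel_id", "window_start_dai", "window_end_dai", "phase",
                  "n_spikes", "log_count", "rate_per_hour"]


def log_transform(count):
    """log10(count + 1); strictly increasing, 0 iff the count is 0."""
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(count) else out


def day_night_label(time_dai, design: ExperimentDesign):
    """Photoperiod phase at a DAI timestamp: lights-on marks DAI k exactly.

    Day covers the half-open first ``photoperiod_day_hours`` of each
    24 h cycle, night the remainder, so over whole days the labelled day
    fraction is day_hours / 24.
    """
    t = np.asarray(time_dai, dtype=float)
    hour = (t * 24.0) % 24.0
    lab = np.where(hour < design.photoperiod_day_hours, "day", "night")
    return lab.item() if t.ndim == 0 else lab


def window_counts(events: pd.DataFrame, design: ExperimentDesign,
                  window_hours: float, phase_split: bool = False,
                  channels: Sequence[str] | None = None) -> pd.DataFrame:
    """Spike counts per channel per half-open window aligned to DAI 0.

    ``events`` must carry ``channel_id`` and ``time_s`` (seconds from the
    start of the recording) sorted ascending within each channel; times are
    mapped to DAI via the design's recording start.  The full window grid
    covering the recording span is emitted, including zero-count windows,
    for every channel in ``channels`` (defaults to the channels present in
    ``events``).  With ``phase_split`` (hourly windows only) each window is
    additionally labelled day or night.
    """
    if window_hours != 1.0 and (window_hours <= 0 or 24.0 % window_hours != 0):
        raise ValueError("window_hours must divide 24 (or equal 1)")
    if phase_split and window_hours != 1.0:
        raise ValueError("phase_split requires hourly windows")
    if len(events):
        grouped = events.groupby("channel_id", sort=False)["time_s"]
        if any((g.diff().dropna() < 0).any() for _, g in grouped):
            raise ValueError("events must be sorted by time within each channel")

    if channels is None:
        channels = sorted(events["channel_id"].unique())
    else:
        channels = sorted(channels)

    wh = float(window_hours)
    k0 = math.floor(design.recording_start_day * 24.0 / wh)
    k1 = math.ceil(design.recording_end_day * 24.0 / wh)
    ks = np.arange(k0, k1)
    starts = ks * wh / 24.0
    ends = (ks + 1) * wh / 24.0

    t_dai = design.recording_start_day + events["time_s"].to_numpy() / SECONDS_PER_DAY
    ev_k = np.floor(t_dai * 24.0 / wh).astype(int)
    counted = pd.DataFrame({"channel_id": events["channel_id"].to_numpy(), "k": ev_k})
    tally = counted.groupby(["channel_id", "k"]).size()

    if phase_split:
        phases = day_night_label(starts, design)
    else:
        phases = np.full(ks.size, "full")

    rows = []
    for ch in channels:
        counts = np.array([tally.get((ch, int(k)), 0) for k in ks], dtype=int)
        rows.append(pd.DataFrame({
            "channel_id": ch,
            "window_start_dai": starts,
            "window_end_dai": ends,
            "phase": phases,
            "n_spikes": counts,
            "log_count": log_transform(counts),
            "rate_per_hour": counts / wh,
        }))
    return pd.concat(rows, ignore_index=True)[WINDOW_COLUMNS]


def select_windows(table: pd.DataFrame, start_dai: float, end_dai: float
                   ) -> pd.DataFrame:
    """Windows lying entirely inside [start_dai, end_dai)."""
    keep = (table["window_start_dai"] >= start_dai - 1e-9) & \
           (table["window_end_dai"] <= end_dai + 1e-9)
    return table.loc[keep].reset_index(drop=True)


@dataclass
class DayNightRatio:
    median_ratio: float
    mean_rate_ratio: float
    defined: bool  # False when the night median is 0 (ratio undefined)
    n_day_windows: int
    n_night_windows: int


def median_day_night_ratio(table: pd.DataFrame) -> DayNightRatio:
    """Day:night contrast of raw hourly counts, pooled over the table.

    Returns the published median-based ratio together with the ratio of
    mean hourly rates.  Raw counts are used, never the log transform.  A
    zero night median (or zero night mean) makes the corresponding ratio
    undefined: it is flagged, not reported as infinity.
    """
    day = table.loc[table["phase"] == "day", "n_spikes"].to_numpy()
    night = table.loc[table["phase"] == "night", "n_spikes"].to_numpy()
    if day.size == 0 or night.size == 0:
        raise ValueError("need at least one day and one night window")
    med_day, med_night = float(np.median(day)), float(np.median(night))
    mean_day, mean_night = float(np.mean(day)), float(np.mean(night))
    defined = med_night > 0 and mean_night > 0
    return DayNightRatio(
        median_ratio=med_day / med_night if med_night > 0 else float("nan"),
        mean_rate_ratio=mean_day / mean_night if mean_night > 0 else float("nan"),
        defined=defined,
        n_day_windows=int(day.size),
        n_night_windows=int(night.size),
    )


def amplitude_summary(amplitudes) -> tuple[float, float, int]:
    """(mean mV, sample SD mV, n); the SD is NaN when n < 2."""
    a = np.asarray(amplitudes, dtype=float)
    n = int(a.size)
    if n == 0:
        return float("nan"), float("nan"), 0
    sd = float(np.std(a, ddof=1)) if n >= 2 else float("nan")
    return float(np.mean(a)), sd, n


def average_spike_waveform(event_times_s, trace: RecordingTrace,
                           half_window: float) -> tuple[np.ndarray, int, int]:
    """Peak-aligned mean waveform over events of one trace.

    Negative-polarity events are sign-flipped before averaging.  Events
    whose window would cross the trace edge are skipped and counted.
    Returns (waveform of 2*half_window + 1 samples, n_used, n_skipped).
    """
    times = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    if times.size == 0:
        raise ValueError("need at least one event")
    dt = trace.sample_interval
    h = int(round(half_window / dt))
    v = trace.voltage_mV
    segs = []
    skipped = 0
    for t in times:
        i = int(round(t / dt))
        if i - h < 0 or i + h + 1 > v.size:
            skipped += 1
            continue
        seg = v[i - h:i + h + 1]
        segs.append(-seg if v[i] < 0 else seg)
    if not segs:
        raise ValueError("all events fell too close to the trace edges")
    return np.mean(segs, axis=0), len(segs), skipped


def parameter_sweep(traces: Sequence[RecordingTrace],
                    grid: Iterable[tuple[float, float, float]],
                    day_window: tuple[float, float] = (0.0, 1.0),
                    ) -> pd.DataFrame:
    """Separation sweep over (threshold, low_cut, high_cut) grid points.

    Traces must be raw (unfiltered) and carry treatment labels; channels of
    non-infested arms form the control group, all others the infested
    group.  For each grid point the full preprocessing + detection pipeline
    runs and two figures of merit are reported over ``day_window`` (DAI):
    the mean log-count difference infested - control, and the total
    detected spike count.  The Pareto set jointly maximizing both is
    flagged — the published 1 mV / 0.0025–0.010 Hz operating point trades
    class separation against count resolution.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    is_control = [t.treatment == "non_infested" for t in traces]
    if not any(is_control) or all(is_control):
        raise ValueError("need both infested and control (non_infested) traces")
    lo_dai, hi_dai = day_window
    rows = []
    for thr, low, high in grid:
        spec = FilterSpec(low_cut=low, high_cut=high)
        params = DetectionParams(threshold=thr)
        logs = {True: [], False: []}
        total = 0
        for trace, ctrl in zip(traces, is_control):
            filt = bandpass(remove_baseline(trace), spec)
            events = detect_spikes(filt, params)
            t_dai = trace.start_dai + np.array([e.time_s for e in events]) / SECONDS_PER_DAY
            count = int(np.sum((t_dai >= lo_dai) & (t_dai < hi_dai))) if events else 0
            total += count
            logs[ctrl].append(log_transform(count))
        rows.append({
            "threshold": thr, "low_cut": low, "high_cut": high,
            "separation": float(np.mean(logs[False]) - np.mean(logs[True])),
            "total_spikes": total,
        })
    out = pd.DataFrame(rows)
    sep = out["separation"].to_numpy()
    tot = out["total_spikes"].to_numpy()
    pareto = [
        not np.any((sep >= s) & (tot >= t) & ((sep > s) | (tot > t)))
        for s, t in zip(sep, tot)
    ]
    out["pareto"] = pareto
    return out
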