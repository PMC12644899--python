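"""CSV round-tripping for recordings, spike tables and result tables.

All on-disk artifacts are plain long-format CSV (UTF-8, header line, "."
decimal separator).  Recordings use the dialect::

    time_s, plant_id, channel_id, electrode_location, treatment, voltage_mV

with an extra ``filtered`` 0/1 provenance column once a file has passed
preprocessing.  Values round-trip at full float precision (17 significant digits,
enough to reproduce any IEEE double exactly).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trace import RecordingTrace

RECORDING_COLUMNS = ["time_s", "plant_id", "channel_id", "electrode_location",
                     "treatment", "voltage_mV"]
SPIKE_COLUMNS = ["channel_id", "time_s", "amplitude_mV", "polarity"]


def recordings_frame(traces: Sequence[RecordingTrace]) -> pd.DataFrame:
    """Long-format table of a set of traces in the canonical dialect."""
    frames = []
    any_filtered = any(t.filtered for t in traces)
    for t in traces:
        df = pd.DataFrame({
            "time_s": t.times_s,
            "plant_id": t.plant_id,
            "channel_id": t.channel_id,
            "electrode_location": t.electrode_location,
            "treatment": t.treatment,
            "voltage_mV": t.voltage_mV,
        })
        if any_filtered:
            df["filtered"] = int(t.filtered)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["channel_id", "time_s"], kind="mergesort",
                           ignore_index=True)


def write_recordings(traces: Sequence[RecordingTrace], path) -> None:
    recordings_frame(traces).to_csv(path, index=False, float_format="%.17g")


def read_recordings(path, start_dai: float = 0.0) -> list[RecordingTrace]:
    """Read recordings CSV back into traces.

    The file stores seconds from the recording start; the DAI origin is
    design-level metadata and is supplied by the caller.  Rows may arrive
    in any order; they are sorted by (channel, time).  Duplicated
    timestamps on a channel, non-uniform sampling within a channel and
    mixed sample intervals across channels are rejected with the offending
    CSV row numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recordings file {path} is missing columns {missing}")
    df = df.reset_index().rename(columns={"index": "_row"})
    df["_row"] += 2  # header is line 1
    df = df.sort_values(["channel_id", "time_s"], kind="mergesort")
    traces = []
    intervals = {}
    for cid, g in df.groupby("channel_id", sort=True):
        t = g["time_s"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0.0)
        if dup.size:
            rows = g["_row"].to_numpy()[dup + 1][:5].tolist()
            raise ValueError(
                f"channel {cid}: duplicated timestamps (CSV rows {rows})"
            )
        if t.size < 2:
            raise ValueError(f"channel {cid}: need at least two samples")
        steps = np.diff(t)
        dt = float(np.median(steps))
        bad = np.flatnonzero(np.abs(steps - dt) > 1e-6 * max(dt, 1.0))
        if bad.size:
            rows = g["_row"].to_numpy()[bad + 1][:5].tolist()
            raise ValueError(
                f"channel {cid}: non-uniform sampling (CSV rows {rows})"
            )
        intervals[cid] = dt
        filtered = bool(g["filtered"].iloc[0]) if "filtered" in g else False
        traces.append(RecordingTrace(
            channel_id=str(cid),
            voltage_mV=g["voltage_mV"].to_numpy(dtype=float),
            sample_interval=dt,
            start_dai=start_dai,
            plant_id=str(g["plant_id"].iloc[0]),
            electrode_location=str(g["electrode_location"].iloc[0]),
            treatment=str(g["treatment"].iloc[0]),
            filtered=filtered,
        ))
    if len(set(intervals.values())) > 1:
        raise ValueError(f"mixed sample intervals across channels: {intervals}")
    return traces


def write_spikes(events: pd.DataFrame, path) -> None:
    events[SPIKE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path} is missing columns {missing}")
    return df.sort_values(["channel_id", "time_s"], kind="mergesort",
                          ignore_index=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def comparisons_frame(results) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten ComparisonResults into a results table and a long-format
    group-summary table."""
    rows, srows = [], []
    for r in results:
        w0, w1 = (r.window if r.window is not None else (float("nan"), float("nan")))
        rows.append({
            "window_start_dai": w0, "window_end_dai": w1,
            "contrast": r.contrast, "statistic_name": r.statistic_name,
            "statistic": r.statistic, "p_value": r.p_value,
            "significance_code": r.significance_code,
            "degenerate": r.degenerate,
        })
        for label, s in r.group_summaries.items():
            srows.append({
                "window_start_dai": w0, "window_end_dai": w1,
                "contrast": r.contrast, "group": label,
                "mean": s.mean, "se": s.se, "n": s.n,
            })
    return pd.DataFrame(rows), pd.DataFrame(srows)
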