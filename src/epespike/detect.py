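"""Threshold spike detection on the preprocessed signal.

A spike is a transient of the band-limited signal whose extremum reaches
the detection threshold (1 mV by default, inclusive).  The detection rule
is a windowed maximum: a sample is an event iff its score (|v|, v or -v
depending on polarity) reaches the threshold and is the maximum of the
score within +/- ``min_separation`` seconds, with exact ties resolved in
favour of the earlier sample.  The separation window (100 s by default,
the period of the upper passband edge) prevents one slow transient from
being counted several times; a direct consequence of the rule is that any
two reported events on a channel are more than ``min_separation`` apart.

:func:`detect_spikes` implements the rule with vectorized sliding-window
maxima; :func:`brute_force_detect` is a deliberately naive O(n*w)
transcription of the same definition kept as an independent oracle for
tests.  :func:`match_events` scores detections against simulator ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .trace import RecordingTrace

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "detect_spikes",
    "brute_force_detect",
    "events_to_frame",
    "match_events",
    "MatchResult",
]


@dataclass(frozen=True)
class DetectionParams:
    threshold: float = 1.0  # mV, inclusive
    polarity: str = "both"  # {"positive", "negative", "both"}
    min_separation: float = 100.0  # seconds

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.polarity not in ("positive", "negative", "both"):
            raise ValueError("polarity must be positive, negative or both")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class SpikeEvent:
    channel_id: str
    time_s: float  # seconds from recording start
    amplitude_mV: float  # |filtered signal| at the extremum
    polarity: str  # {"positive", "negative"}


def _score(v: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "both":
        return np.abs(v)
    if polarity == "positive":
        return v.copy()
    return -v


def _check_preprocessed(trace: RecordingTrace, params: DetectionParams) -> int:
    if not trace.filtered:
        raise ValueError(
            "detection requires a bandpass-filtered trace (run preprocessing "
            "first; raw drift would otherwise be counted as spikes)"
        )
    if params.min_separation < trace.sample_interval:
        raise ValueError("min_separation must be at least one sample interval")
    return int(round(params.min_separation / trace.sample_interval))


def _events_from_indices(trace: RecordingTrace, idx: np.ndarray,
                         score: np.ndarray) -> list[SpikeEvent]:
    v = trace.voltage_mV
    dt = trace.sample_interval
    return [
        SpikeEvent(
            channel_id=trace.channel_id,
            time_s=float(i * dt),
            amplitude_mV=float(abs(v[i])),
            polarity="positive" if v[i] >= 0 else "negative",
        )
        for i in idx
    ]


def detect_spikes(trace: RecordingTrace,
                  params: DetectionParams | None = None) -> list[SpikeEvent]:
    """All windowed-maximum threshold crossings of a preprocessed trace."""
    params = params or DetectionParams()
    w = _check_preprocessed(trace, params)
    s = _score(trace.voltage_mV, params.polarity)
    n = s.size
    if n == 0:
        return []
    winmax = maximum_filter1d(s, size=2 * w + 1, mode="constant", cval=-np.inf)
    cand = np.flatnonzero((s >= params.threshold) & (s == winmax))
    keep = []
    for i in cand:
        lo = max(0, i - w)
        seg = s[lo:min(n, i + w + 1)]
        if lo + int(np.argmax(seg)) == i:  # earliest window maximum wins ties
            keep.append(i)
    return _events_from_indices(trace, np.asarray(keep, dtype=int), s)


def brute_force_detect(trace: RecordingTrace,
                       params: DetectionParams | None = None) -> list[SpikeEvent]:
    """O(n*w) exhaustive scan implementing the detection rule literally.

    Test oracle only: a sample is an event iff its score reaches the
    threshold and no sample within the separation window beats it (earlier
    samples win exact ties).
    """
    params = params or DetectionParams()
    w = _check_preprocessed(trace, params)
    s = _score(trace.voltage_mV, params.polarity)
    n = s.size
    keep = []
    for i in range(n):
        if s[i] < params.threshold:
            continue
        lo = max(0, i - w)
        seg = s[lo:min(n, i + w + 1)]
        m = seg.max()
        if s[i] == m and lo + int(np.argmax(seg)) == i:
            keep.append(i)
    return _events_from_indices(trace, np.asarray(keep, dtype=int), s)


def events_to_frame(events: Sequence[SpikeEvent]) -> pd.DataFrame:
    """Spike table in the canonical bit-stable order (channel, time)."""
    df = pd.DataFrame(
        [(e.channel_id, e.time_s, e.amplitude_mV, e.polarity) for e in events],
        columns=["channel_id", "time_s", "amplitude_mV", "polarity"],
    )
    return df.sort_values(["channel_id", "time_s"], kind="mergesort",
                          ignore_index=True)


@dataclass
class MatchResult:
    n_true_positive: int
    n_false_positive: int
    n_missed: int
    pairs: pd.DataFrame  # detected_time_s, truth_time_s, channel_id

    @property
    def precision(self) -> float:
        d = self.n_true_positive + self.n_false_positive
        return self.n_true_positive / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.n_true_positive + self.n_missed
        return self.n_true_positive / d if d else float("nan")


def match_events(detected: pd.DataFrame, truth: pd.DataFrame,
                 tolerance: float) -> MatchResult:
    """Greedy one-to-one nearest-time matching within ``tolerance`` seconds.

    Both inputs are frames with ``channel_id`` and ``time_s`` columns
    (detections from :func:`events_to_frame`, truth from the simulator).
    Candidate pairs on the same channel are ranked by |time difference| and
    accepted greedily, each detection and each truth event at most once.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pairs = []
    used_d: set = set()
    used_t: set = set()
    cand = []
    for ch in sorted(set(detected["channel_id"]) & set(truth["channel_id"])):
        dt_ = detected.loc[detected["channel_id"] == ch, "time_s"].to_numpy()
        tt = truth.loc[truth["channel_id"] == ch, "time_s"].to_numpy()
        for i, td in enumerate(dt_):
            j0 = int(np.searchsorted(tt, td - tolerance))
            j1 = int(np.searchsorted(tt, td + tolerance, side="right"))
            for j in range(j0, j1):
                cand.append((abs(td - tt[j]), ch, i, j, td, tt[j]))
    for _, ch, i, j, td, tj in sorted(cand):
        if (ch, i) in used_d or (ch, j) in used_t:
            continue
        used_d.add((ch, i))
        used_t.add((ch, j))
        pairs.append({"channel_id": ch, "detected_time_s": td, "truth_time_s": tj})
    tp = len(pairs)
    return MatchResult(
        n_true_positive=tp,
        n_false_positive=len(detected) - tp,
        n_missed=len(truth) - tp,
        pairs=pd.DataFrame(pairs, columns=["channel_id", "detected_time_s",
                                           "truth_time_s"]),
    )
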