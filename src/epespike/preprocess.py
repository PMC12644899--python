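"""Baseline removal and the analysis bandpass.

The spike model operates on very slow biopotentials: the analysis band is
0.0025–0.010 Hz (periods of 100–400 s).  Preprocessing consists of two
steps:

1. :func:`remove_baseline` — subtract the per-channel median so all
   channels share baseline 0.  The median is robust against the sparse
   spike transients riding on the offset.
2. :func:`bandpass` — zero-phase Butterworth bandpass (order 2 per pass,
   applied forward and backward, so effective order 4) realized as
   second-order sections, with reflective padding of one low-cut period
   (400 s at defaults) at each end to control edge transients.

Zero-phase filtering preserves the timing of spike peaks, which matters
because detected event times feed the day/night rate comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trace import RecordingTrace


@dataclass(frozen=True)
class FilterSpec:
    """Passband of the analysis filter.

    low_cut / high_cut : Hz, passband edges (defaults 0.0025 and 0.010).
    order : Butterworth order per pass (the zero-phase forward-backward
        application doubles the effective order).
    zero_phase : apply forward-backward (no phase distortion) when True,
        a single causal pass otherwise.
    """

    low_cut: float = 0.0025
    high_cut: float = 0.010
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be a positive integer")

    def sos(self, fs: float):
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz is not below the Nyquist frequency "
                f"{fs / 2} Hz"
            )
        return signal.butter(
            self.order, [self.low_cut, self.high_cut], btype="bandpass", fs=fs,
            output="sos",
        )

    def min_samples(self, sample_interval: float) -> int:
        """Shortest trace the filter accepts: three low-cut periods."""
        return math.ceil(3.0 / (self.low_cut * sample_interval))


def frequency_response(spec: FilterSpec, freqs, fs: float) -> np.ndarray:
    """Magnitude gain of the *applied* filter at the given frequencies (Hz).

    For zero-phase operation the filter runs twice, so the applied gain is
    the squared magnitude of the designed Butterworth response.
    """
    sos = spec.sos(fs)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs, float) / fs)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def remove_baseline(trace: RecordingTrace) -> RecordingTrace:
    """Subtract the channel median so every channel sits on baseline 0.

    Idempotent: the median of a median-subtracted signal is 0.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot remove the baseline of an empty trace")
    v = trace.voltage_mV
    return trace.with_voltage(v - np.median(v), baseline_removed=True)


def bandpass_array(v: np.ndarray, sample_interval: float,
                   spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the analysis bandpass to a bare signal array."""
    spec = spec or FilterSpec()
    v = np.asarray(v, float)
    fs = 1.0 / sample_interval
    need = spec.min_samples(sample_interval)
    if v.size < need:
        raise ValueError(
            f"trace too short for the {spec.low_cut} Hz low cut: "
            f"{v.size} samples < required minimum {need}"
        )
    sos = spec.sos(fs)
    if spec.zero_phase:
        padlen = min(int(round(1.0 / (spec.low_cut * sample_interval))), v.size - 1)
        return signal.sosfiltfilt(sos, v, padtype="even", padlen=padlen)
    return signal.sosfilt(sos, v)


def bandpass(trace: RecordingTrace, spec: FilterSpec | None = None) -> RecordingTrace:
    """Band-limit a trace to the analysis passband; marks it ``filtered``."""
    out = bandpass_array(trace.voltage_mV, trace.sample_interval, spec)
    return trace.with_voltage(out, filtered=True)


def preprocess(trace: RecordingTrace, spec: FilterSpec | None = None) -> RecordingTrace:
    """Full preprocessing: common baseline, then the analysis bandpass."""
    return bandpass(remove_baseline(trace), spec)
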