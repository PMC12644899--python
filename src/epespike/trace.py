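"""In-memory container for one uniformly sampled voltage channel.

A :class:`RecordingTrace` holds the signal of a single electrode circuit
(one plant channel) in millivolts together with the metadata needed by the
downstream stages: sampling interval, the days-after-infestation (DAI) time
origin, electrode placement and treatment labels, and two provenance flags
set by the preprocessing stage (``baseline_removed``, ``filtered``).

Times are stored implicitly: sample ``i`` sits at ``i * sample_interval``
seconds from the start of the recording, and the recording starts at
``start_dai`` days relative to the infestation instant (DAI 0, which by
convention coincides with lights-on of the infestation day).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SECONDS_PER_DAY = 86400.0


@dataclass
class RecordingTrace:
    channel_id: str
    voltage_mV: np.ndarray
    sample_interval: float  # seconds
    start_dai: float = 0.0  # DAI of the first sample (negative = before infestation)
    plant_id: str = ""
    electrode_location: str = "stem"  # {"stem", "pod"}
    treatment: str = "non_infested"
    baseline_removed: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.voltage_mV.ndim != 1:
            raise ValueError("voltage_mV must be one-dimensional")
        if not np.isfinite(self.sample_interval) or self.sample_interval <= 0:
            raise ValueError("sample_interval must be a positive number of seconds")
        if self.electrode_location not in ("stem", "pod"):
            raise ValueError(f"unknown electrode_location {self.electrode_location!r}")

    @property
    def n_samples(self) -> int:
        return self.voltage_mV.size

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sample_interval

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds from the start of the recording."""
        return np.arange(self.n_samples) * self.sample_interval

    @property
    def times_dai(self) -> np.ndarray:
        """Sample times on the days-after-infestation axis."""
        return self.start_dai + self.times_s / SECONDS_PER_DAY

    def with_voltage(self, voltage_mV: np.ndarray, **flags) -> "RecordingTrace":
        """Copy of this trace carrying a new signal and updated provenance flags."""
        return dataclasses.replace(self, voltage_mV=np.asarray(voltage_mV, float), **flags)
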