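"""Greenhouse experiment designs and the three shipped scenario presets.

An :class:`ExperimentDesign` describes one treatment arm of a greenhouse
infestation experiment: how many pots, how many stink bug adults per pot,
which electrodes are inserted, the photoperiod, the recording span on the
days-after-infestation (DAI) axis and any irrigation events.  A complete
experiment (one preset) is a list of arms sharing the same timeline.

Presets mirror the three experiments the simulator emulates:

``early_season_vc``
    VC-stage soybeans, 6 pots per arm, 10 adults per pot, stem electrodes,
    arms: non-infested / infested untreated / infested insecticide-treated.
``late_season_r5``
    R5-stage soybeans, 5 pots per arm, 20 adults per pot, pod electrodes,
    same three arms.
``benchmark_r5``
    R5-stage soybeans, 4 pots per arm, 50 adults per pot, stem and pod
    electrodes on every plant, arms: non-infested / continuously infested /
    insects manually removed at 1 DAI / removed at 3 DAI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml

GROWTH_STAGES = ("VC", "R5")
TREATMENTS = (
    "non_infested",
    "infested_untreated",
    "infested_treated",
    "infested_removed",
)


@dataclass
class ExperimentDesign:
    experiment_id: str
    growth_stage: str  # {"VC", "R5"}
    n_pots: int
    insects_per_pot: int
    treatment: str
    removal_day: Optional[float] = None  # DAI; only for infested_removed
    electrode_insertion_day: float = -3.0  # negative DAI (days before infestation)
    recording_start_day: float = -3.0  # DAI
    recording_end_day: float = 7.0  # DAI
    photoperiod_day_hours: float = 14.0
    photoperiod_night_hours: float = 10.0
    lights_on_clock_hour: float = 8.0
    irrigation_times: tuple = ()  # DAI timestamps
    sample_interval: float = 1.0  # seconds
    electrode_locations: tuple = ("stem",)

    def __post_init__(self) -> None:
        self.irrigation_times = tuple(float(t) for t in self.irrigation_times)
        self.electrode_locations = tuple(self.electrode_locations)
        if self.growth_stage not in GROWTH_STAGES:
            raise ValueError(f"growth_stage must be one of {GROWTH_STAGES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.n_pots < 1:
            raise ValueError("n_pots must be a positive integer")
        if self.insects_per_pot < 0:
            raise ValueError("insects_per_pot must be non-negative")
        if abs(self.photoperiod_day_hours + self.photoperiod_night_hours - 24.0) > 1e-9:
            raise ValueError("photoperiod day + night hours must equal 24")
        if not (self.recording_start_day < 0.0 < self.recording_end_day):
            raise ValueError(
                "recording must start before infestation (DAI 0) and end after it"
            )
        if self.electrode_insertion_day >= 0:
            raise ValueError("electrodes are inserted before infestation (negative DAI)")
        if self.treatment == "infested_removed":
            if self.removal_day is None or self.removal_day < 0:
                raise ValueError("infested_removed requires a non-negative removal_day")
        elif self.removal_day is not None:
            raise ValueError("removal_day is only meaningful for infested_removed")
        if (self.insects_per_pot == 0) != (self.treatment == "non_infested"):
            raise ValueError("insects_per_pot must be 0 exactly for non_infested arms")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        for loc in self.electrode_locations:
            if loc not in ("stem", "pod"):
                raise ValueError(f"unknown electrode location {loc!r}")

    @property
    def span_days(self) -> float:
        return self.recording_end_day - self.recording_start_day

    @property
    def arm_label(self) -> str:
        """Treatment label, disambiguating removal arms by their removal day."""
        if self.treatment == "infested_removed":
            return f"infested_removed_{self.removal_day:g}dai"
        return self.treatment

    def plant_id(self, pot: int) -> str:
        return f"{self.experiment_id}-{self.arm_label}-p{pot:02d}"

    def channel_id(self, pot: int, location: str) -> str:
        return f"{self.plant_id(pot)}-{location}"


def _arm(base: dict, treatment: str, insects: int, **overrides) -> ExperimentDesign:
    kw = dict(base)
    kw.update(overrides)
    return ExperimentDesign(treatment=treatment, insects_per_pot=insects, **kw)


def _preset_early_season_vc() -> list[ExperimentDesign]:
    base = dict(
        experiment_id="early_season_vc",
        growth_stage="VC",
        n_pots=6,
        electrode_insertion_day=-3.0,
        recording_start_day=-3.0,
        recording_end_day=7.0,
        irrigation_times=(1.5, 3.5, 5.5),
        electrode_locations=("stem",),
    )
    return [
        _arm(base, "non_infested", 0),
        _arm(base, "infested_untreated", 10),
        _arm(base, "infested_treated", 10),
    ]


def _preset_late_season_r5() -> list[ExperimentDesign]:
    base = dict(
        experiment_id="late_season_r5",
        growth_stage="R5",
        n_pots=5,
        electrode_insertion_day=-3.0,
        recording_start_day=-3.0,
        recording_end_day=7.0,
        irrigation_times=(1.5, 3.5, 5.5),
        electrode_locations=("pod",),
    )
    return [
        _arm(base, "non_infested", 0),
        _arm(base, "infested_untreated", 20),
        _arm(base, "infested_treated", 20),
    ]


def _preset_benchmark_r5() -> list[ExperimentDesign]:
    base = dict(
        experiment_id="benchmark_r5",
        growth_stage="R5",
        n_pots=4,
        electrode_insertion_day=-4.0,
        recording_start_day=-4.0,
        recording_end_day=7.0,
        irrigation_times=(1.5, 3.5, 5.5),
        electrode_locations=("stem", "pod"),
    )
    return [
        _arm(base, "non_infested", 0),
        _arm(base, "infested_untreated", 50),
        _arm(base, "infested_removed", 50, removal_day=1.0),
        _arm(base, "infested_removed", 50, removal_day=3.0),
    ]


_PRESET_BUILDERS = {
    "early_season_vc": _preset_early_season_vc,
    "late_season_r5": _preset_late_season_r5,
    "benchmark_r5": _preset_benchmark_r5,
}

PRESET_NAMES = tuple(_PRESET_BUILDERS)


def design_to_dict(design: ExperimentDesign) -> dict:
    d = dataclass_asdict(design)
    d["irrigation_times"] = list(design.irrigation_times)
    d["electrode_locations"] = list(design.electrode_locations)
    return d


def dataclass_asdict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def design_from_dict(d: dict) -> ExperimentDesign:
    return ExperimentDesign(**d)


def load_preset(name: str) -> list[ExperimentDesign]:
    """Load one of the shipped scenario presets by name.

    Presets are stored as YAML config files under ``epespike/presets`` and
    validated through :class:`ExperimentDesign` on load.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("epespike.presets").joinpath(f"{name}.yaml").read_text()
    payload = yaml.safe_load(text)
    return [design_from_dict(d) for d in payload["designs"]]


def builtin_preset(name: str) -> list[ExperimentDesign]:
    """Programmatic construction of a preset (used to generate the YAML files)."""
    return _PRESET_BUILDERS[name]()
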