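"""Ground-truthed synthetic recordings of plant electrical spiking.

The generator emulates greenhouse soybean recordings during stink bug
infestation so every downstream stage can be validated against known
truth.  Per recording channel it composes:

* an inhomogeneous Poisson spike train whose rate tracks infestation
  pressure — a two-level diurnal step (day level = 3.7x night level,
  renormalized to the daily total), an exponential decline under
  continuous infestation that sets in after the first day, insecticide
  knockdown plus assessed mortality for treated pots, and an immediate
  drop to the control rate after manual removal;
* a stereotyped slow biphasic spike waveform whose gain is calibrated
  against the analysis bandpass, so that drawn amplitudes are nominal
  post-filter peak values (the published 1.9 / 0.8 mV statistics are
  measured on the filtered signal);
* baseline drift (band-limited random walk kept below the filter's low
  cut), broadband sensor noise, irrigation-driven rate burstiness, and a
  slow electrode-sensitivity decline emulating tissue "walling off".

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, one child stream per channel, so a simulation is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .design import ExperimentDesign
from .preprocess import FilterSpec, bandpass_array
from .trace import SECONDS_PER_DAY, RecordingTrace

__all__ = [
    "SpikeTrainParams",
    "MortalityModel",
    "NoiseModel",
    "GroundTruth",
    "VC_MORTALITY",
    "R5_MORTALITY",
    "default_mortality",
    "sample_spike_times",
    "sample_amplitudes",
    "render_spike_template",
    "template_filter_gain",
    "mortality_fraction",
    "diurnal_factors",
    "infestation_rate_curve",
    "simulate_experiment",
    "simulate_scenario",
]


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SpikeTrainParams:
    """Event-train parameters of an actively infested plant.

    Rates are events per plant per 24 h.  ``injected_rate_day1`` is the
    base rate during the first day of active infestation; with the default
    1 mV detection threshold about 87% of a Normal(1.9, 0.8) amplitude
    population is detectable, so 57.5 injected events/day put the expected
    detected day-one count near 50, the centre of the published 20–80
    range.  ``day_night_rate_ratio`` is the day:night contrast of hourly
    rates (default 3.7).  The exponential decline under continuous
    infestation (half-life ``decay_half_life`` days) starts after the
    first day, matching the observation that spiking shows no apparent
    decline during the first 24 h.  ``treated_knockdown_hours`` is the
    half-life of the fast feeding-suppression factor applied to
    insecticide-treated pots on top of the assessed-mortality survival
    fraction (contact knockdown and feeding deterrence act within hours,
    well before impairment is visible at the daily assessments).
    """

    injected_rate_day1: float = 57.5
    day_night_rate_ratio: float = 3.7
    control_rate: float = 10.0
    decay_half_life: float = 3.0
    amplitude_mean: float = 1.9
    amplitude_sd: float = 0.8
    template_rise_seconds: float = 15.0
    template_decay_seconds: float = 60.0
    post_removal_rate_factor: float = 1.0
    treated_knockdown_hours: float = 3.0

    def __post_init__(self) -> None:
        for name in ("injected_rate_day1", "control_rate", "decay_half_life",
                     "post_removal_rate_factor", "treated_knockdown_hours"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.amplitude_sd <= 0:
            raise ValueError("amplitude_sd must be > 0")
        if self.day_night_rate_ratio <= 0:
            raise ValueError("day_night_rate_ratio must be > 0")
        if self.template_rise_seconds <= 0 or self.template_decay_seconds <= 0:
            raise ValueError("template rise and decay must be > 0")
        if self.template_decay_seconds <= self.template_rise_seconds:
            raise ValueError("template decay must be slower than its rise")

    def detectable_fraction(self, threshold: float = 1.0) -> float:
        """Probability that a drawn amplitude reaches the detection threshold."""
        return float(_stats.norm.sf(threshold, self.amplitude_mean, self.amplitude_sd)
                     / _stats.norm.sf(0.0, self.amplitude_mean, self.amplitude_sd))


@dataclass(frozen=True)
class MortalityModel:
    """Dead-or-affected insect fraction over time for insecticide-treated pots.

    ``checkpoints`` are (DAI, fraction) pairs from the daily visual
    assessments; the curve interpolates linearly between them, is 0 at the
    infestation instant and constant after the last assessment.
    """

    checkpoints: tuple
    stage: str = "VC"

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(f)) for t, f in self.checkpoints)
        if not pts or pts[0][0] > 0:
            pts = ((0.0, 0.0),) + pts
        object.__setattr__(self, "checkpoints", pts)
        times = [t for t, _ in pts]
        fracs = [f for _, f in pts]
        if times[0] != 0.0 or fracs[0] != 0.0:
            raise ValueError("mortality must start at (0, 0): exposure begins at infestation")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("checkpoint times must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if any(f2 < f1 for f1, f2 in zip(fracs, fracs[1:])):
            raise ValueError("fractions must be non-decreasing")


VC_MORTALITY = MortalityModel(((0.0, 0.0), (1.0, 0.83), (2.0, 1.0)), stage="VC")
R5_MORTALITY = MortalityModel(((0.0, 0.0), (1.0, 0.62), (7.0, 0.98)), stage="R5")


def default_mortality(stage: str) -> MortalityModel:
    return VC_MORTALITY if stage == "VC" else R5_MORTALITY


@dataclass(frozen=True)
class NoiseModel:
    """Non-spike signal content and sensor imperfections.

    white_noise_sd : mV, per-sample broadband noise (mostly removed by the
        narrow analysis band).
    drift_sd_per_hour : mV, random-walk step scale of the baseline drift.
    drift_band : Hz, upper edge of the drift content; must stay below the
        analysis low cut so the bandpass removes drift.
    irrigation_extra_rate : variance of the random event-rate multiplier
        applied during irrigation windows (mean 1 — irrigation increases
        fluctuation of the count, not its expectation).
    irrigation_effect_hours : duration of that transient.
    electrode_sensitivity_half_life : days; recorded spike amplitudes decay
        with this half-life from electrode insertion onward ("walling off").
    """

    white_noise_sd: float = 0.2
    drift_sd_per_hour: float = 1.0
    drift_band: float = 0.001
    irrigation_extra_rate: float = 1.0
    irrigation_effect_hours: float = 2.0
    electrode_sensitivity_half_life: float = 60.0

    def __post_init__(self) -> None:
        for name in ("white_noise_sd", "drift_sd_per_hour", "drift_band",
                     "irrigation_extra_rate", "irrigation_effect_hours",
                     "electrode_sensitivity_half_life"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_band >= 0.0025:
            raise ValueError("drift_band must stay below the 0.0025 Hz analysis low cut")


@dataclass
class GroundTruth:
    """Injected events and insect-status time courses of one simulation.

    ``events``: channel_id, time_s, amplitude_mV (nominal post-filter
    amplitude actually injected, including sensitivity attenuation).
    ``insect_status``: pot_id, time_s, time_dai, n_non_affected,
    n_dead_or_affected at the daily assessment points.
    """

    events: pd.DataFrame
    insect_status: pd.DataFrame


# --------------------------------------------------------------------------
# elementary samplers


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_spike_times(rate_curve: Callable, span, seed, rate_max: float | None = None
                       ) -> np.ndarray:
    """Realize an inhomogeneous Poisson process by thinning.

    ``rate_curve`` maps time (array-aware) to a non-negative bounded rate in
    events per unit time; ``span`` is the half-open interval to cover.  The
    candidate stream runs at the supremum rate (estimated on a dense grid
    when not supplied) and candidates are kept with probability
    rate(t)/sup.  Sorted times are returned; a fixed seed fixes the draw.
    """
    rng = _as_rng(seed)
    t0, t1 = float(span[0]), float(span[1])
    if not t1 > t0:
        raise ValueError("span must be a non-empty interval")
    grid = np.linspace(t0, t1, 4097)
    r = np.asarray(rate_curve(grid), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("rate_curve must be finite (bounded) on the span")
    if np.any(r < 0):
        raise ValueError("rate_curve must be non-negative on the span")
    if rate_max is None:
        # pad the grid estimate: discontinuities (phase steps, knockdown
        # onset) can peak between grid points; thinning stays exact for any
        # upper bound, and candidates are re-checked against it below
        rate_max = float(r.max()) * 1.1
    if rate_max < 0 or not np.isfinite(rate_max):
        raise ValueError("rate_max must be a finite non-negative bound")
    if np.any(r > rate_max * (1 + 1e-9) + 1e-12):
        raise ValueError("rate_curve exceeds the supplied supremum bound")
    if rate_max == 0.0:
        return np.empty(0)
    n = rng.poisson(rate_max * (t1 - t0))
    cand = rng.uniform(t0, t1, n)
    rc = np.asarray(rate_curve(cand), dtype=float)
    if np.any(rc < 0) or np.any(~np.isfinite(rc)):
        raise ValueError("rate_curve must be finite and non-negative on the span")
    if np.any(rc > rate_max * (1 + 1e-9) + 1e-12):
        raise ValueError("rate_curve exceeds its supremum between grid points")
    keep = rng.uniform(0.0, rate_max, n) < rc
    return np.sort(cand[keep])


def sample_amplitudes(n: int, params: SpikeTrainParams | None = None, seed=0
                      ) -> np.ndarray:
    """Draw nominal spike amplitudes (mV) from Normal(mean, sd).

    Non-positive draws are redrawn; at the default Normal(1.9, 0.8) this
    truncation affects <1% of draws and biases the mean by <0.02 mV.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    params = params or SpikeTrainParams()
    rng = _as_rng(seed)
    out = rng.normal(params.amplitude_mean, params.amplitude_sd, int(n))
    bad = out <= 0.0
    while np.any(bad):
        out[bad] = rng.normal(params.amplitude_mean, params.amplitude_sd, int(bad.sum()))
        bad = out <= 0.0
    return out


# --------------------------------------------------------------------------
# spike waveform template


def _template_shape(rise: float, decay: float, sample_interval: float):
    """Unit-peak biphasic transient: fast rise, slower exponential return."""
    if rise <= 0 or decay <= 0:
        raise ValueError("rise and decay must be positive")
    if decay <= rise:
        raise ValueError("decay must be slower than rise")
    if sample_interval > rise / 2.0:
        raise ValueError(
            f"sample interval {sample_interval} s too coarse to resolve a "
            f"{rise} s rise (need <= {rise / 2.0} s)"
        )
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    horizon = t_peak + 10.0 * decay
    t = np.arange(0.0, horizon, sample_interval)
    f = np.exp(-t / decay) - np.exp(-t / rise)
    f /= f.max()
    return f, int(np.argmax(f))


@lru_cache(maxsize=32)
def template_filter_gain(rise: float, decay: float, sample_interval: float,
                         spec: FilterSpec) -> float:
    """Post-bandpass peak of the unit-peak template (calibrated once)."""
    shape, _ = _template_shape(rise, decay, sample_interval)
    pad = int(round(4.0 / (spec.low_cut * sample_interval)))
    v = np.zeros(shape.size + 2 * pad)
    v[pad:pad + shape.size] = shape
    return float(np.max(bandpass_array(v, sample_interval, spec)))


def render_spike_template(amplitude: float, rise: float, decay: float,
                          sample_interval: float,
                          spec: FilterSpec | None = None) -> np.ndarray:
    """Pre-filter waveform whose post-bandpass peak equals ``amplitude`` mV."""
    spec = spec or FilterSpec()
    shape, _ = _template_shape(rise, decay, sample_interval)
    if amplitude == 0.0:
        return np.zeros_like(shape)
    gain = template_filter_gain(rise, decay, sample_interval, spec)
    return shape * (amplitude / gain)


# --------------------------------------------------------------------------
# mortality and rate model


def mortality_fraction(t, model: MortalityModel):
    """Dead-or-affected fraction at DAI ``t`` (scalar or array), t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("mortality is defined from the infestation instant (t >= 0)")
    times = np.array([c[0] for c in model.checkpoints])
    fracs = np.array([c[1] for c in model.checkpoints])
    out = np.interp(t_arr, times, fracs)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def diurnal_factors(ratio: float, day_hours: float, night_hours: float
                    ) -> tuple[float, float]:
    """Two-level step factors (day, night) with mean 1 over a full day."""
    night = 24.0 / (day_hours * ratio + night_hours)
    return ratio * night, night


def infestation_rate_curve(design: ExperimentDesign,
                           train: SpikeTrainParams,
                           mortality: MortalityModel | None = None) -> Callable:
    """Event rate (events/day) as a function of DAI for one treatment arm.

    Composition for an actively infested pot:
    ``injected_rate_day1 x diurnal(t) x decay(t) [x survival(t) x knockdown(t)]``,
    where decay is 1 during the first day and halves every
    ``decay_half_life`` days afterwards.  Outside active infestation
    (before DAI 0, non-infested arms, after manual removal) the rate is the
    control level (times ``post_removal_rate_factor`` after removal).
    """
    if design.treatment == "infested_treated" and mortality is None:
        raise ValueError("infested_treated arms require a MortalityModel")
    f_day, f_night = diurnal_factors(
        train.day_night_rate_ratio,
        design.photoperiod_day_hours,
        design.photoperiod_night_hours,
    )

    def rate(t):
        t = np.asarray(t, dtype=float)
        hour = (t * 24.0) % 24.0
        diurnal = np.where(hour < design.photoperiod_day_hours, f_day, f_night)
        base = np.full_like(t, train.control_rate)
        if design.treatment != "non_infested":
            active = t >= 0.0
            if design.treatment == "infested_removed":
                active &= t < design.removal_day
                base = np.where(
                    t >= design.removal_day,
                    train.control_rate * train.post_removal_rate_factor,
                    base,
                )
            tpos = np.clip(t, 0.0, None)
            decay = np.where(
                tpos <= 1.0, 1.0, 0.5 ** ((tpos - 1.0) / train.decay_half_life)
            )
            inj = train.injected_rate_day1 * decay
            if design.treatment == "infested_treated":
                surv = 1.0 - mortality_fraction(tpos, mortality)
                knock = 0.5 ** (tpos * 24.0 / train.treated_knockdown_hours)
                inj = inj * surv * knock
            base = np.where(active, inj, base)
        return base * diurnal

    return rate


# --------------------------------------------------------------------------
# full experiment simulation


def _irrigated(rate: Callable, design: ExperimentDesign, noise: NoiseModel,
               rng: np.random.Generator) -> Callable:
    """Doubly stochastic burstiness: a random mean-1 multiplier per irrigation."""
    if not design.irrigation_times or noise.irrigation_extra_rate == 0:
        return rate
    var = noise.irrigation_extra_rate
    shape_k = 1.0 / var
    mults = rng.gamma(shape_k, var, len(design.irrigation_times))
    starts = np.array(design.irrigation_times)
    ends = starts + noise.irrigation_effect_hours / 24.0

    def wrapped(t):
        t = np.asarray(t, dtype=float)
        out = np.asarray(rate(t), dtype=float).copy()
        for s, e, m in zip(starts, ends, mults):
            out[(t >= s) & (t < e)] *= m
        return out

    return wrapped


def _drift(n: int, dt: float, noise: NoiseModel, rng: np.random.Generator
           ) -> np.ndarray:
    steps = rng.normal(0.0, noise.drift_sd_per_hour * np.sqrt(dt / 3600.0), n)
    walk = np.cumsum(steps)
    if noise.drift_band <= 0 or noise.drift_sd_per_hour == 0:
        return walk
    sos = _signal.butter(2, noise.drift_band, btype="low", fs=1.0 / dt, output="sos")
    return _signal.sosfiltfilt(sos, walk)


def simulate_experiment(design: ExperimentDesign,
                        train: SpikeTrainParams | None = None,
                        noise: NoiseModel | None = None,
                        mortality: MortalityModel | None = None,
                        seed=0,
                        filter_spec: FilterSpec | None = None,
                        ) -> tuple[list[RecordingTrace], GroundTruth]:
    """Simulate one treatment arm: raw traces plus ground truth.

    Each pot carries one channel per electrode location in the design.
    Channels are statistically independent realizations of the arm's rate
    process.  ``filter_spec`` is the analysis bandpass against which the
    spike template gain is calibrated (defaults to the standard band).
    """
    train = train or SpikeTrainParams()
    noise = noise or NoiseModel()
    spec = filter_spec or FilterSpec()
    if design.treatment == "infested_treated" and mortality is None:
        mortality = default_mortality(design.growth_stage)

    dt = design.sample_interval
    n = int(round(design.span_days * SECONDS_PER_DAY / dt))
    base_rate = infestation_rate_curve(design, train, mortality)
    shape, peak_idx = _template_shape(
        train.template_rise_seconds, train.template_decay_seconds, dt
    )
    gain = template_filter_gain(
        train.template_rise_seconds, train.template_decay_seconds, dt, spec
    )
    unit = shape / gain

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    channels = [
        (pot, loc)
        for pot in range(design.n_pots)
        for loc in design.electrode_locations
    ]
    children = ss.spawn(len(channels))

    hl = noise.electrode_sensitivity_half_life
    traces: list[RecordingTrace] = []
    ev_rows: list[pd.DataFrame] = []
    for (pot, loc), child in zip(channels, children):
        rng = np.random.default_rng(child)
        rate = _irrigated(base_rate, design, noise, rng)
        times_dai = sample_spike_times(
            rate, (design.recording_start_day, design.recording_end_day), rng
        )
        amps = sample_amplitudes(times_dai.size, train, rng)
        if hl > 0 and np.isfinite(hl):
            sens = 0.5 ** ((times_dai - design.electrode_insertion_day) / hl)
        else:
            sens = np.ones_like(times_dai)
        eff = amps * sens

        v = np.zeros(n)
        idx = np.round(
            (times_dai - design.recording_start_day) * SECONDS_PER_DAY / dt
        ).astype(int)
        inside = (idx >= 0) & (idx < n)
        idx, eff_in, t_in = idx[inside], eff[inside], times_dai[inside]
        for i, a in zip(idx, eff_in):
            lo = i - peak_idx
            s0, s1 = max(0, lo), min(n, lo + unit.size)
            v[s0:s1] += a * unit[s0 - lo:s1 - lo]
        v += _drift(n, dt, noise, rng)
        if noise.white_noise_sd > 0:
            v += rng.normal(0.0, noise.white_noise_sd, n)

        cid = design.channel_id(pot, loc)
        traces.append(RecordingTrace(
            channel_id=cid,
            voltage_mV=v,
            sample_interval=dt,
            start_dai=design.recording_start_day,
            plant_id=design.plant_id(pot),
            electrode_location=loc,
            treatment=design.treatment,
        ))
        ev_rows.append(pd.DataFrame({
            "channel_id": cid,
            "time_s": (t_in - design.recording_start_day) * SECONDS_PER_DAY,
            "amplitude_mV": eff_in,
        }))

    events = (
        pd.concat(ev_rows, ignore_index=True)
        if ev_rows else
        pd.DataFrame(columns=["channel_id", "time_s", "amplitude_mV"])
    )
    events = events.sort_values(["channel_id", "time_s"], kind="mergesort",
                                ignore_index=True)
    status = _insect_status(design, mortality)
    return traces, GroundTruth(events=events, insect_status=status)


_ASSESSMENT_DAYS = (0.0, 1.0, 2.0, 3.0, 4.0, 7.0)


def _insect_status(design: ExperimentDesign,
                   mortality: MortalityModel | None) -> pd.DataFrame:
    rows = []
    days = [d for d in _ASSESSMENT_DAYS
            if design.recording_start_day <= d <= design.recording_end_day]
    for pot in range(design.n_pots):
        pid = design.plant_id(pot)
        for d in days:
            if design.treatment == "infested_treated" and mortality is not None:
                dead = int(round(design.insects_per_pot * mortality_fraction(d, mortality)))
            else:
                dead = 0
            rows.append({
                "pot_id": pid,
                "time_s": (d - design.recording_start_day) * SECONDS_PER_DAY,
                "time_dai": d,
                "n_non_affected": design.insects_per_pot - dead,
                "n_dead_or_affected": dead,
            })
    return pd.DataFrame(rows, columns=["pot_id", "time_s", "time_dai",
                                       "n_non_affected", "n_dead_or_affected"])


def simulate_scenario(designs: Sequence[ExperimentDesign],
                      train: SpikeTrainParams | None = None,
                      noise: NoiseModel | None = None,
                      seed=0,
                      filter_spec: FilterSpec | None = None,
                      ) -> tuple[list[RecordingTrace], GroundTruth]:
    """Simulate every arm of a multi-arm experiment under one master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(designs))
    traces: list[RecordingTrace] = []
    events, status = [], []
    for design, child in zip(designs, children):
        tr, gt = simulate_experiment(
            design, train=train, noise=noise, seed=child, filter_spec=filter_spec
        )
        traces.extend(tr)
        events.append(gt.events)
        status.append(gt.insect_status)
    ids = [t.channel_id for t in traces]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping channel ids across arms")
    return traces, GroundTruth(
        events=pd.concat(events, ignore_index=True),
        insect_status=pd.concat(status, ignore_index=True),
    )
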