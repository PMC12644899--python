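"""Windowing, transforms, ratios, waveform averaging and the sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epespike.preprocess import FilterSpec
from epespike.quantify import (
    amplitude_summary,
    average_spike_waveform,
    day_night_label,
    log_transform,
    median_day_night_ratio,
    parameter_sweep,
    select_windows,
    window_counts,
)
from epespike.synth import SpikeTrainParams, render_spike_template, simulate_experiment
from epespike.trace import RecordingTrace

from conftest import SEED, single_arm_design

DESIGN = single_arm_design("infested_untreated", n_pots=2, insects=50,
                           start=-1.0, end=2.0)


def _events(channel_times: dict) -> pd.DataFrame:
    rows = [(ch, t) for ch, ts in channel_times.items() for t in ts]
    return pd.DataFrame(rows, columns=["channel_id", "time_s"])


class TestLogTransform:
    @pytest.mark.parametrize("count, expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_exact_values(self, count, expected):
        assert log_transform(count) == expected

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_and_zero_only_at_zero(self, n):
        assert log_transform(n + 1) > log_transform(n)
        assert (log_transform(n) == 0.0) == (n == 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(-1)


class TestDayNight:
    def test_boundaries_are_half_open(self):
        assert day_night_label(0.0, DESIGN) == "day"
        assert day_night_label(14.0 / 24.0, DESIGN) == "night"
        assert day_night_label(1.0, DESIGN) == "day"

    def test_day_fraction_over_whole_days(self):
        hours = np.arange(0, 72) / 24.0 + 1 / 48.0  # hour centres over 3 days
        labels = day_night_label(hours, DESIGN)
        assert np.mean(labels == "day") == pytest.approx(14.0 / 24.0)


class TestWindowCounts:
    def test_empty_events_give_complete_zero_grid(self):
        table = window_counts(_events({}), DESIGN, 24.0, channels=["c1"])
        assert len(table) == 3  # days -1, 0, 1
        assert (table["n_spikes"] == 0).all()
        assert (table["phase"] == "full").all()

    def test_boundary_event_counts_in_later_window(self):
        # recording starts at DAI -1, so 86400 s = DAI 0 exactly
        table = window_counts(_events({"c": [86400.0]}), DESIGN, 24.0)
        hit = table[table["n_spikes"] > 0]
        assert list(hit["window_start_dai"]) == [0.0]

    def test_hourly_counts_sum_to_daily(self):
        rng = np.random.default_rng(SEED)
        times = np.sort(rng.uniform(0, DESIGN.span_days * 86400.0, 500))
        ev = _events({"c": times})
        daily = window_counts(ev, DESIGN, 24.0)
        hourly = window_counts(ev, DESIGN, 1.0, phase_split=True)
        assert hourly["n_spikes"].sum() == daily["n_spikes"].sum() == 500
        for ws in daily["window_start_dai"]:
            sub = hourly[(hourly["window_start_dai"] >= ws)
                         & (hourly["window_end_dai"] <= ws + 1.0)]
            day_total = daily.loc[daily["window_start_dai"] == ws, "n_spikes"].sum()
            assert sub["n_spikes"].sum() == day_total

    def test_log_column_is_exact(self):
        table = window_counts(_events({"c": [10.0, 20.0, 30.0]}), DESIGN, 24.0)
        assert (table["log_count"] == np.log10(table["n_spikes"] + 1)).all()

    def test_unsorted_events_rejected(self):
        ev = _events({"c": [100.0, 50.0]})
        with pytest.raises(ValueError, match="sorted"):
            window_counts(ev, DESIGN, 24.0)

    def test_invalid_window_length_rejected(self):
        with pytest.raises(ValueError):
            window_counts(_events({}), DESIGN, 7.0, channels=["c"])


class TestDayNightRatio:
    def _table(self, day_counts, night_counts):
        n = len(day_counts) + len(night_counts)
        return pd.DataFrame({
            "channel_id": "c",
            "window_start_dai": np.arange(n) / 24.0,
            "window_end_dai": (np.arange(n) + 1) / 24.0,
            "phase": ["day"] * len(day_counts) + ["night"] * len(night_counts),
            "n_spikes": list(day_counts) + list(night_counts),
        })

    def test_equal_counts_give_unit_ratio(self):
        r = median_day_night_ratio(self._table([3, 3, 3], [3, 3]))
        assert r.median_ratio == 1.0 and r.mean_rate_ratio == 1.0

    def test_direct_computation(self):
        r = median_day_night_ratio(self._table([4, 4, 4], [1, 1]))
        assert r.median_ratio == 4.0 and r.mean_rate_ratio == 4.0

    def test_zero_night_median_is_flagged_not_infinite(self):
        r = median_day_night_ratio(self._table([2, 2], [0, 0, 1]))
        assert not r.defined
        assert np.isnan(r.median_ratio)

    def test_scaling_counts_leaves_ratios_unchanged(self):
        a = median_day_night_ratio(self._table([4, 2, 6], [1, 2, 1]))
        b = median_day_night_ratio(self._table([12, 6, 18], [3, 6, 3]))
        assert a.median_ratio == b.median_ratio
        assert a.mean_rate_ratio == pytest.approx(b.mean_rate_ratio)

    def test_missing_phase_rejected(self):
        with pytest.raises(ValueError):
            median_day_night_ratio(self._table([1, 2], []))


class TestAmplitudeSummary:
    def test_constant_values(self):
        assert amplitude_summary([2.0, 2.0, 2.0]) == (2.0, 0.0, 3)

    def test_two_values(self):
        mean, sd, n = amplitude_summary([1.0, 3.0])
        assert (mean, n) == (2.0, 2)
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_single_value_has_undefined_sd(self):
        mean, sd, n = amplitude_summary([1.5])
        assert mean == 1.5 and np.isnan(sd) and n == 1

    def test_simulator_truth_recovers_published_moments(self, truncation_cohort):
        _, truth, _ = truncation_cohort
        mean, sd, n = amplitude_summary(truth.events["amplitude_mV"])
        assert n >= 5000
        assert mean == pytest.approx(1.9, abs=0.05)
        assert sd == pytest.approx(0.8, abs=0.05)


class TestAverageWaveform:
    def _trace_with_templates(self, times, amp=2.0, noise_sd=0.0, n=20000, seed=0):
        spec = FilterSpec()
        w = render_spike_template(amp, 15.0, 60.0, 1.0, spec)
        peak = int(np.argmax(w))
        v = np.zeros(n)
        for t in times:
            i = int(t) - peak
            v[i:i + w.size] += w
        if noise_sd:
            v += np.random.default_rng(seed).normal(0, noise_sd, n)
        return RecordingTrace(channel_id="c", voltage_mV=v, sample_interval=1.0,
                              filtered=True)

    def test_single_event_returns_its_segment(self):
        tr = self._trace_with_templates([5000.0])
        wave, used, skipped = average_spike_waveform([5000.0], tr, 300.0)
        assert used == 1 and skipped == 0
        assert wave.size == 601
        assert np.array_equal(wave, tr.voltage_mV[4700:5301])

    def test_averaging_identical_templates_recovers_template(self):
        # spacing exceeds the template extent, so windows stay tail-free
        times = [2000.0 + 1500.0 * k for k in range(10)]
        tr = self._trace_with_templates(times)
        wave, used, _ = average_spike_waveform(times, tr, 200.0)
        assert used == 10
        ref = tr.voltage_mV[1800:2201]
        assert np.max(np.abs(wave - ref)) < 1e-9

    def test_noise_suppression_follows_sqrt_n(self):
        times = [2000.0 + 1500.0 * k for k in range(100)]
        tr = self._trace_with_templates(times, noise_sd=0.3, n=155000, seed=4)
        wave, used, _ = average_spike_waveform(times, tr, 200.0)
        nominal_peak = float(np.max(self._trace_with_templates([2000.0]).voltage_mV))
        assert used == 100
        # central limit: the averaged peak converges at sd/sqrt(n)
        assert abs(float(np.max(wave)) - nominal_peak) < 3 * 0.3 / np.sqrt(100)

    def test_edge_events_are_skipped_and_counted(self):
        tr = self._trace_with_templates([5000.0])
        wave, used, skipped = average_spike_waveform([50.0, 5000.0], tr, 300.0)
        assert used == 1 and skipped == 1


@pytest.fixture(scope="module")
def arm_traces(quiet_noise):
    infested = single_arm_design("infested_untreated", n_pots=3, insects=50,
                                 experiment_id="sweep")
    control = single_arm_design("non_infested", n_pots=3, insects=0,
                                experiment_id="sweep")
    tr_i, _ = simulate_experiment(infested, noise=quiet_noise, seed=SEED)
    tr_c, _ = simulate_experiment(control, noise=quiet_noise, seed=SEED + 1)
    return tr_i + tr_c


class TestParameterSweep:
    def test_degenerate_single_point_grid(self, arm_traces):
        out = parameter_sweep(arm_traces, [(1.0, 0.0025, 0.010)])
        assert len(out) == 1
        assert out["separation"].iloc[0] > 0
        assert bool(out["pareto"].iloc[0])

    def test_published_threshold_beats_high_threshold(self, arm_traces):
        """5 mV excludes almost the entire amplitude population."""
        out = parameter_sweep(arm_traces, [(1.0, 0.0025, 0.010),
                                           (5.0, 0.0025, 0.010)])
        sep = dict(zip(out["threshold"], out["separation"]))
        tot = dict(zip(out["threshold"], out["total_spikes"]))
        assert sep[1.0] > sep[5.0]
        assert tot[1.0] > tot[5.0]

    def test_widening_band_admits_confounders(self, arm_traces):
        """Fast out-of-band transients raise counts but blur separation."""
        rng = np.random.default_rng(SEED + 3)
        noisy = []
        for tr in arm_traces:
            v = tr.voltage_mV.copy()
            n = v.size
            for t in np.sort(rng.uniform(500, n - 500, 60)):
                i = np.arange(max(0, int(t) - 40), min(n, int(t) + 40))
                v[i] += 3.0 * np.exp(-0.5 * ((i - t) / 8.0) ** 2)
            noisy.append(tr.with_voltage(v))
        out = parameter_sweep(noisy, [(1.0, 0.0025, 0.010), (1.0, 0.0025, 0.05)])
        narrow = out[out["high_cut"] == 0.010].iloc[0]
        wide = out[out["high_cut"] == 0.05].iloc[0]
        assert wide["total_spikes"] > narrow["total_spikes"]
        assert wide["separation"] < narrow["separation"]

    def test_empty_grid_rejected(self, arm_traces):
        with pytest.raises(ValueError):
            parameter_sweep(arm_traces, [])
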