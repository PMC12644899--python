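"""Generator unit tests: event sampler, amplitudes, template, mortality,
rate composition and simulation bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from epespike.design import ExperimentDesign
from epespike.preprocess import FilterSpec, bandpass_array
from epespike.synth import (
    MortalityModel,
    NoiseModel,
    R5_MORTALITY,
    SpikeTrainParams,
    VC_MORTALITY,
    diurnal_factors,
    infestation_rate_curve,
    mortality_fraction,
    render_spike_template,
    sample_amplitudes,
    sample_spike_times,
    simulate_experiment,
)

from conftest import SEED, single_arm_design


class TestSampleSpikeTimes:
    def test_zero_rate_yields_no_events(self):
        times = sample_spike_times(lambda t: np.zeros_like(t), (0.0, 24.0), seed=1)
        assert times.size == 0

    def test_constant_rate_matches_poisson_mean(self):
        lam = 3.0  # events per hour over 24 h
        counts = [
            sample_spike_times(lambda t: np.full_like(t, lam), (0.0, 24.0), seed=k).size
            for k in range(1000)
        ]
        expected = 24.0 * lam
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se
        # events are sorted and inside the span
        t = sample_spike_times(lambda t: np.full_like(t, lam), (0.0, 24.0), seed=0)
        assert np.all(np.diff(t) >= 0) and t.min() >= 0 and t.max() < 24.0

    def test_day_night_step_recovers_injected_ratio(self):
        f_day, f_night = diurnal_factors(3.7, 14.0, 10.0)
        base = 4.0  # events per hour

        def rate(t):
            return base * np.where(np.asarray(t) % 24.0 < 14.0, f_day, f_night)

        day = night = 0
        reps = 400
        for k in range(reps):
            t = sample_spike_times(rate, (0.0, 24.0), seed=k)
            day += np.sum(t % 24.0 < 14.0)
            night += np.sum(t % 24.0 >= 14.0)
        ratio = (day / (14 * reps)) / (night / (10 * reps))
        se = ratio * np.sqrt(1.0 / day + 1.0 / night)
        assert abs(ratio - 3.7) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sample_spike_times(lambda t: np.asarray(t) - 12.0, (0.0, 24.0), seed=1)

    def test_rate_above_supremum_rejected(self):
        with pytest.raises(ValueError, match="supremum"):
            sample_spike_times(lambda t: np.full_like(t, 5.0), (0.0, 24.0),
                               seed=1, rate_max=1.0)


class TestAmplitudes:
    def test_zero_draws(self):
        assert sample_amplitudes(0, seed=1).size == 0

    def test_defaults_recover_published_moments(self):
        a = sample_amplitudes(10000, seed=SEED)
        assert np.all(a > 0)
        assert abs(a.mean() - 1.9) < 0.05
        assert abs(a.std(ddof=1) - 0.8) < 0.05
        assert np.percentile(a, 99) <= 5.0


class TestTemplate:
    def test_zero_amplitude_is_silent(self):
        w = render_spike_template(0.0, 15.0, 60.0, 1.0)
        assert np.all(w == 0.0)

    def test_post_filter_peak_matches_nominal_amplitude(self):
        spec = FilterSpec()
        w = render_spike_template(2.0, 15.0, 60.0, 1.0, spec)
        pad = 2000
        v = np.zeros(w.size + 2 * pad)
        v[pad:pad + w.size] = w
        f = bandpass_array(v, 1.0, spec)
        assert 1.9 <= f.max() <= 2.1  # within 5% of nominal
        assert abs(f.mean()) < 1e-6  # bandpass removes DC

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            render_spike_template(1.0, 15.0, 60.0, 30.0)


class TestMortality:
    def test_printed_checkpoints_are_exact(self):
        assert mortality_fraction(1.0, VC_MORTALITY) == 0.83
        assert mortality_fraction(2.0, VC_MORTALITY) == 1.0
        assert mortality_fraction(1.0, R5_MORTALITY) == 0.62
        assert mortality_fraction(7.0, R5_MORTALITY) == 0.98

    def test_zero_at_infestation_and_constant_after_last(self):
        assert mortality_fraction(0.0, R5_MORTALITY) == 0.0
        assert mortality_fraction(30.0, R5_MORTALITY) == 0.98

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mortality_fraction(-0.5, VC_MORTALITY)

    def test_curve_is_monotone(self):
        grid = np.linspace(0.0, 10.0, 401)
        frac = mortality_fraction(grid, R5_MORTALITY)
        assert np.all(np.diff(frac) >= 0)
        assert np.all((frac >= 0) & (frac <= 1))

    def test_invalid_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            MortalityModel(((0.0, 0.0), (1.0, 0.8), (2.0, 0.5)))
        with pytest.raises(ValueError):
            MortalityModel(((0.0, 0.2), (1.0, 0.8)))


class TestRateComposition:
    def test_treated_rate_monte_carlo_matches_integral(self):
        """Realized counts match base x diurnal x survival x knockdown."""
        design = single_arm_design("infested_treated", n_pots=1, insects=10,
                                   stage="VC")
        rate = infestation_rate_curve(design, SpikeTrainParams(), VC_MORTALITY)
        span = (0.0, 0.5)
        grid = np.linspace(*span, 20001)
        expected = np.trapezoid(rate(grid), grid)
        counts = [sample_spike_times(rate, span, seed=k).size for k in range(1000)]
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_removed_arm_reverts_to_control_rate(self):
        train = SpikeTrainParams()
        design = single_arm_design("infested_removed", n_pots=1, insects=50,
                                   end=3.0, removal_day=1.0)
        rate = infestation_rate_curve(design, train)
        f_day, f_night = diurnal_factors(train.day_night_rate_ratio, 14.0, 10.0)
        assert rate(1.5) == train.control_rate * f_day  # post-removal, day phase
        assert rate(0.5) == train.injected_rate_day1 * f_day  # active, no decay yet
        # -0.1 DAI is 21.6 h clock time, i.e. night phase before infestation
        assert rate(-0.1) == train.control_rate * f_night

    def test_default_day1_expectation_within_published_detection_range(self):
        train = SpikeTrainParams()
        expected_detected = train.injected_rate_day1 * train.detectable_fraction(1.0)
        assert 20.0 <= expected_detected <= 80.0


class TestSimulation:
    def test_silent_control_gives_flat_traces_and_empty_truth(self, quiet_noise):
        train = SpikeTrainParams(control_rate=0.0)
        design = single_arm_design("non_infested", n_pots=2, insects=0,
                                   sample_interval=5.0)
        traces, truth = simulate_experiment(design, train=train, noise=quiet_noise,
                                            seed=1)
        assert len(traces) == 2
        assert all(np.all(t.voltage_mV == 0.0) for t in traces)
        assert truth.events.empty

    def test_seed_determinism_and_divergence(self):
        design = single_arm_design("infested_untreated", n_pots=2, insects=50,
                                   sample_interval=5.0)
        tr_a, gt_a = simulate_experiment(design, seed=3)
        tr_b, gt_b = simulate_experiment(design, seed=3)
        tr_c, gt_c = simulate_experiment(design, seed=4)
        for a, b in zip(tr_a, tr_b):
            assert np.array_equal(a.voltage_mV, b.voltage_mV)
        pd.testing.assert_frame_equal(gt_a.events, gt_b.events)
        assert not gt_a.events["time_s"].equals(gt_c.events["time_s"])

    def test_ground_truth_bookkeeping(self):
        design = single_arm_design("infested_treated", n_pots=3, insects=20,
                                   stage="R5", end=2.0, sample_interval=5.0)
        traces, truth = simulate_experiment(design, seed=9)
        span_s = design.span_days * 86400.0
        assert ((truth.events["time_s"] >= 0) & (truth.events["time_s"] < span_s)).all()
        assert set(truth.events["channel_id"]) <= {t.channel_id for t in traces}
        status = truth.insect_status
        assert (status["n_non_affected"] + status["n_dead_or_affected"]
                == design.insects_per_pot).all()
        # one status series per pot, R5 checkpoint fractions respected
        at_1dai = status[status["time_dai"] == 1.0]
        assert (at_1dai["n_dead_or_affected"] == round(20 * 0.62)).all()

    def test_treated_arm_requires_mortality_curve(self):
        design = single_arm_design("infested_treated", n_pots=1, insects=10)
        rate_err = pytest.raises(ValueError, match="MortalityModel")
        with rate_err:
            infestation_rate_curve(design, SpikeTrainParams(), None)
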