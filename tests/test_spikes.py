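"""In-vivo modulation pipeline: identification, rates, smoothing, epochs."""

import math

import numpy as np
import pytest

from motorseq import (
    MotionState,
    PairedRecording,
    RateTrace,
    UndefinedStatisticError,
    ValidationError,
    VelocityTrace,
    analyse_recording,
    epoch_correlations,
    firing_rates,
    gaussian_smooth,
    instantaneous_rate,
    segment_locomotion,
    validate_purkinje,
)
from motorseq.spikes import CannotIdentifyError, _pearson
from motorseq.simulate import RecordingGenConfig, simulate_recording

from oracles import pearson_textbook


def make_recording(ss, cs, duration=10.0, dt=0.01, mask=None):
    n = int(duration / dt)
    vel = VelocityTrace(values=np.zeros(n), dt=dt)
    return PairedRecording(cell_id="c", ss_times=np.asarray(ss, dtype=float),
                           cs_times=np.asarray(cs, dtype=float), velocity=vel,
                           state_mask=mask)


class TestPurkinjeValidation:
    def test_constructed_full_pause(self):
        cs = np.arange(1.0, 9.0, 1.0)
        ss = np.arange(0.05, 10.0, 0.05)
        # carve a 15 ms SS-free window after every CS
        keep = np.ones(ss.size, dtype=bool)
        for c in cs:
            keep &= ~((ss > c) & (ss <= c + 0.015))
        rec = make_recording(ss[keep], cs)
        val = validate_purkinje(rec, pause_window=0.010)
        assert val.fraction_paused == 1.0 and val.is_single_unit

    def test_one_violated_pause_in_ten(self):
        cs = np.arange(1.0, 11.0, 1.0)
        ss = np.concatenate([cs[:1] + 0.002, cs + 0.5])  # one SS 2 ms after one CS
        rec = make_recording(np.sort(ss), cs, duration=12.0)
        val = validate_purkinje(rec, pause_window=0.010)
        assert val.fraction_paused == pytest.approx(0.9)
        assert not val.is_single_unit

    def test_no_complex_spikes_cannot_identify(self):
        with pytest.raises(CannotIdentifyError):
            validate_purkinje(make_recording([0.1, 0.2], []))

    def test_poisson_gap_probability(self, rng):
        # independent 60 Hz SS / 1 Hz CS: P(pause) = exp(-rate * window)
        duration, rate = 400.0, 60.0
        ss = np.sort(rng.uniform(0, duration, int(rate * duration)))
        cs = np.sort(rng.uniform(0, duration, int(duration)))
        rec = make_recording(ss, cs, duration=duration)
        val = validate_purkinje(rec, pause_window=0.010)
        expected = math.exp(-rate * 0.010)
        se = math.sqrt(expected * (1 - expected) / cs.size)
        assert abs(val.fraction_paused - expected) < 4 * se


class TestLocomotionSegmentation:
    def test_constant_zero_velocity_is_all_rest(self):
        vel = VelocityTrace(values=np.zeros(1000), dt=0.01)
        assert (segment_locomotion(vel) == MotionState.REST).all()

    def test_long_block_is_locomotion(self):
        v = np.zeros(6000)
        v[1000:4500] = 10.0  # 35 s at dt=0.01
        mask = segment_locomotion(VelocityTrace(values=v, dt=0.01))
        assert (mask[1000:4500] == MotionState.LOCOMOTION).all()
        assert (mask[:1000] == MotionState.REST).all()

    def test_short_block_is_excluded(self):
        v = np.zeros(6000)
        v[1000:2000] = 10.0  # 10 s < 20 s minimum
        mask = segment_locomotion(VelocityTrace(values=v, dt=0.01))
        assert (mask[1000:2000] == MotionState.EXCLUDED).all()
        assert not (mask == MotionState.LOCOMOTION).any()

    def test_brief_gap_is_bridged(self):
        v = np.zeros(8000)
        v[1000:3500] = 10.0
        v[3550:6000] = 10.0  # 0.5 s dip inside one movement period
        mask = segment_locomotion(VelocityTrace(values=v, dt=0.01))
        assert (mask[3500:3550] == MotionState.LOCOMOTION).all()


class TestInstantaneousRate:
    def test_regular_train(self):
        ss = np.arange(0.0, 5.01, 0.1)  # 10 Hz
        rate = instantaneous_rate(ss, grid_dt=0.01)
        assert rate.values == pytest.approx(10.0, rel=1e-9)

    def test_two_isis(self):
        rate = instantaneous_rate([0.0, 0.1, 0.3], grid_dt=0.05, t_end=0.3)
        # samples at 0, 0.05 in first ISI; 0.1..0.3 in second
        assert rate.values[0] == pytest.approx(10.0)
        assert rate.values[-1] == pytest.approx(5.0)

    def test_fewer_than_two_spikes_raises(self):
        with pytest.raises(UndefinedStatisticError):
            instantaneous_rate([1.0], grid_dt=0.01)

    def test_time_average_matches_count_rate(self, rng):
        ss = np.sort(rng.uniform(0, 100.0, 6000))
        rate = instantaneous_rate(ss, grid_dt=0.005, t0=ss[0], t_end=ss[-1])
        count_rate = (ss.size - 1) / (ss[-1] - ss[0])
        assert np.mean(rate.values) == pytest.approx(count_rate, rel=0.10)


class TestGaussianSmoothing:
    def test_constant_is_fixed_point(self):
        trace = RateTrace(values=np.full(500, 42.0), dt=0.01)
        out = gaussian_smooth(trace)
        np.testing.assert_allclose(out.values, 42.0, rtol=1e-12)

    def test_impulse_response_is_unit_area(self):
        values = np.zeros(801)
        values[400] = 1.0
        out = gaussian_smooth(RateTrace(values=values, dt=0.01), window=0.2)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        dt, f = 0.002, 2.0
        t = dt * np.arange(20000)
        trace = RateTrace(values=np.sin(2 * np.pi * f * t), dt=dt)
        out = gaussian_smooth(trace, window=0.2)
        sigma = 0.2 / (2 * math.sqrt(2 * math.log(2)))
        expected = math.exp(-0.5 * (2 * math.pi * f * sigma) ** 2)
        interior = slice(2000, -2000)
        gain = out.values[interior].std() / trace.values[interior].std()
        assert gain == pytest.approx(expected, rel=0.01)

    def test_interior_mean_preserved(self):
        rng = np.random.default_rng(0)
        trace = RateTrace(values=rng.uniform(20, 80, 4000), dt=0.01)
        out = gaussian_smooth(trace, window=0.2)
        interior = slice(200, -200)
        assert out.values[interior].mean() == pytest.approx(
            trace.values[interior].mean(), rel=0.005)

    def test_window_must_cover_two_samples(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(RateTrace(values=np.zeros(100), dt=0.2), window=0.2)


class TestEpochCorrelations:
    def _ramped_velocity(self, n=6000, dt=0.01, seed=0):
        rng = np.random.default_rng(seed)
        t = dt * np.arange(n)
        v = 10 + 4 * np.sin(2 * np.pi * 0.4 * t) + rng.normal(0, 0.5, n)
        return VelocityTrace(values=v, dt=dt)

    def test_affine_rate_gives_unit_correlation_both_signs(self):
        vel = self._ramped_velocity()
        for b in (2.0, -3.0):
            rate = RateTrace(values=5.0 + b * vel.values, dt=vel.dt)
            result = epoch_correlations(rate, vel)
            assert result.max_abs_r == pytest.approx(1.0, abs=1e-9)
            rs = [e.r for e in result.epoch_correlations]
            assert np.allclose(np.abs(rs), 1.0)
            assert np.sign(rs[0]) == np.sign(b)

    def test_epoch_tiling_count(self):
        vel = self._ramped_velocity(n=4000)  # 40 s span
        rate = RateTrace(values=vel.values.copy(), dt=vel.dt)
        result = epoch_correlations(rate, vel, epoch=2.0, step=0.2)
        expected = math.floor((40.0 - 2.0) / 0.2) + 1
        assert len(result.epoch_correlations) == expected

    def test_time_shift_leaves_r_values_unchanged(self):
        vel = self._ramped_velocity(n=3000)
        rate = RateTrace(values=np.roll(vel.values, 7) + 3.0, dt=vel.dt)
        base = epoch_correlations(rate, vel)
        shifted = epoch_correlations(
            RateTrace(values=rate.values, dt=rate.dt, t0=5.0),
            VelocityTrace(values=vel.values, dt=vel.dt, t0=5.0))
        np.testing.assert_allclose([e.r for e in base.epoch_correlations],
                                   [e.r for e in shifted.epoch_correlations],
                                   atol=1e-12)

    def test_zero_variance_epoch_is_undefined_and_excluded(self):
        vel = VelocityTrace(values=np.ones(300), dt=0.01)  # 3 s constant
        rate = RateTrace(values=np.linspace(0, 10, 300), dt=0.01)
        result = epoch_correlations(rate, vel)
        assert all(np.isnan(e.r) for e in result.epoch_correlations)
        assert np.isnan(result.max_abs_r)

    def test_pearson_matches_textbook_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=200)
            y = rng.normal(size=200) + 0.3 * x
            assert _pearson(x, y) == pytest.approx(pearson_textbook(x, y), abs=1e-12)

    def test_rate_zscoring_does_not_change_r(self):
        vel = self._ramped_velocity(n=3000, seed=3)
        raw = 50 + 2 * vel.values + np.random.default_rng(4).normal(0, 3, 3000)
        rate = RateTrace(values=raw, dt=vel.dt)
        z = RateTrace(values=(raw - raw.mean()) / raw.std(), dt=vel.dt)
        a = epoch_correlations(rate, vel)
        b = epoch_correlations(z, vel)
        np.testing.assert_allclose([e.r for e in a.epoch_correlations],
                                   [e.r for e in b.epoch_correlations], atol=1e-12)


class TestFiringRates:
    def test_counts_over_duration(self):
        mask = np.full(2000, MotionState.LOCOMOTION, dtype=np.int8)  # 20 s wait, dt 0.01 -> 20 s
        ss = np.linspace(0.0, 9.99, 600)  # 600 spikes in first 10 s
        mask[1000:] = MotionState.REST
        rec = make_recording(ss, [5.0], duration=20.0, mask=mask)
        rates = firing_rates(rec, mask)
        assert rates["ss_rate_locomotion"] == pytest.approx(60.0)
        assert rates["cs_rate_locomotion"] == pytest.approx(0.1)

    def test_no_rest_samples_flagged(self):
        mask = np.full(1000, MotionState.LOCOMOTION, dtype=np.int8)
        rec = make_recording([0.1, 0.2], [0.5], mask=mask)
        rates = firing_rates(rec, mask)
        assert math.isnan(rates["ss_rate_rest"])

    def test_generator_rate_recovery_and_ordering(self):
        rests, locos = [], []
        for baseline in (60.0, 90.0):
            rest_rates = []
            for seed in range(5):
                cfg = RecordingGenConfig(ss_baseline=baseline, seed=seed,
                                         cs_rate=0.0, duration=60.0,
                                         locomotion_bouts=((15.0, 45.0),))
                rec, led = simulate_recording(cfg)
                rates = firing_rates(rec, led.state_mask_true)
                rest_rates.append(rates["ss_rate_rest"])
            rests.append(np.mean(rest_rates))
        # ~30 s rest per recording, 5 recordings: SE ~ sqrt(r/150)
        for mean_rate, baseline in zip(rests, (60.0, 90.0)):
            se = math.sqrt(baseline / 150.0)
            assert abs(mean_rate - baseline) < 3 * se
        assert rests[1] > rests[0]


class TestFullPipeline:
    def test_strong_coupling_recovers_high_correlation(self):
        cfg = RecordingGenConfig(seed=7, gamma_shape=8.0, coupling_gain=3.0,
                                 velocity_mod_amp=6.0, velocity_mod_freqs=(0.5, 0.9))
        rec, _ = simulate_recording(cfg)
        result = analyse_recording(rec)
        assert result.max_abs_r >= 0.9
        assert result.ss_rate_locomotion > result.ss_rate_rest

    def test_max_abs_r_monotone_in_coupling_gain(self):
        maxima = []
        for gain in (0.0, 1.0, 2.5):
            vals = []
            for seed in (1, 2, 3):
                cfg = RecordingGenConfig(seed=seed, coupling_gain=gain,
                                         duration=60.0, locomotion_bouts=((10.0, 50.0),),
                                         velocity_mod_freqs=(0.5, 0.9))
                rec, _ = simulate_recording(cfg)
                vals.append(analyse_recording(rec).max_abs_r)
            maxima.append(np.mean(vals))
        assert maxima[0] < maxima[1] < maxima[2]
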