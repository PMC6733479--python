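"""Simulator: beat trains, PTT synthesis, templates, and the clock model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pttsaw import synth
from pttsaw.synth import (
    ClockModel,
    SimulationConfig,
    alignment_offset,
    apply_clock_skew,
    generate_beat_times,
    ppg_pulse_template,
    preset_clock,
    synthesize_ecg,
    synthesize_ppg,
    synthesize_true_ptt,
)


def _quiet(duration=10.0, **kw):
    base = dict(
        duration=duration,
        mean_hr=60.0,
        hrv_amplitudes=(),
        rr_jitter_sd=0.0,
        ptt_modulations=(),
        noise_sd_ecg=0.0,
        noise_sd_ppg=0.0,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestBeatTimes:
    def test_constant_rate_beats_on_integer_seconds(self):
        beats = generate_beat_times(_quiet(duration=10.0))
        assert np.allclose(beats, np.arange(10))

    def test_beat_count_matches_rate_times_duration(self):
        beats = generate_beat_times(_quiet(duration=1600.0, mean_hr=75.0))
        assert abs(len(beats) - 2000) <= 1

    def test_same_seed_reproduces_bitwise(self):
        cfg = SimulationConfig(duration=60.0, seed=42)
        a = generate_beat_times(cfg)
        b = generate_beat_times(SimulationConfig(duration=60.0, seed=42))
        assert np.array_equal(a, b)

    def test_nonpositive_rr_rejected(self):
        cfg = _quiet(duration=30.0, hrv_amplitudes=((0.1, 2.0),))
        with pytest.raises(ValueError, match="RR"):
            generate_beat_times(cfg)

    def test_strictly_increasing_with_jitter(self):
        beats = generate_beat_times(SimulationConfig(duration=120.0, seed=3))
        assert np.all(np.diff(beats) > 0)


class TestTruePtt:
    def test_constant_baseline(self):
        beats = np.arange(10.0)
        ptt = synthesize_true_ptt(beats, _quiet(ptt_baseline=0.25))
        assert np.allclose(ptt, 0.25)

    def test_linear_trend_interpolated_at_midpoint(self):
        cfg = _quiet(duration=100.0, ptt_trend=((0.0, 0.0), (100.0, 0.05)))
        ptt = synthesize_true_ptt(np.array([50.0]), cfg)
        assert ptt[0] == pytest.approx(0.275, abs=1e-12)

    def test_single_modulation_peaks_at_its_frequency(self):
        cfg = _quiet(duration=1600.0, ptt_modulations=((0.1, 0.005),))
        t = np.arange(0.0, 1600.0, 0.25)
        ptt = synthesize_true_ptt(t, cfg)
        spec = np.abs(np.fft.rfft(ptt - ptt.mean()))
        freqs = np.fft.rfftfreq(t.size, d=0.25)
        assert freqs[np.argmax(spec)] == pytest.approx(0.1, abs=0.001)

    def test_nonpositive_ptt_rejected(self):
        cfg = _quiet(ptt_baseline=0.004, ptt_modulations=((0.1, 0.05),))
        with pytest.raises(ValueError, match="positive"):
            synthesize_true_ptt(np.arange(20.0), cfg)

    def test_empty_beats_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            synthesize_true_ptt(np.empty(0), _quiet())


class TestEcg:
    def test_single_beat_peak_at_nominal_index(self):
        cfg = _quiet(duration=3.0)
        wf = synthesize_ecg(np.array([1.0]), cfg)
        assert np.argmax(wf.samples) == round(1.0 * cfg.fs_ecg)

    def test_zero_beats_gives_noise_of_full_length(self):
        cfg = _quiet(duration=2.0, noise_sd_ecg=0.01)
        wf = synthesize_ecg(np.empty(0), cfg)
        assert wf.n == round(2.0 * cfg.fs_ecg)
        assert 0 < wf.samples.std() < 0.02

    def test_every_beat_contributes_one_peak(self):
        from scipy.signal import find_peaks

        cfg = _quiet(duration=101.0)
        beats = np.arange(0.5, 100.5)
        wf = synthesize_ecg(beats, cfg)
        peaks, _ = find_peaks(wf.samples, height=0.5)
        assert peaks.size == 100

    def test_beats_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="within"):
            synthesize_ecg(np.array([5.0]), _quiet(duration=2.0))


class TestPpg:
    def test_template_steepest_ascent_at_half_upstroke(self):
        u = np.linspace(-0.05, 1.0, 200001)
        v = ppg_pulse_template(u)
        du = u[1] - u[0]
        i = np.argmax(np.diff(v))
        assert u[i] + du / 2 == pytest.approx(
            synth.PPG_UPSTROKE_WIDTH / 2, abs=2 * du
        )

    def test_discrete_sampling_keeps_ascent_within_one_sample(self):
        cfg = _quiet(duration=3.0)
        wf = synthesize_ppg(np.array([1.0]), np.array([0.25]), cfg)
        d = np.diff(wf.samples)
        t_est = (np.argmax(d) + 0.5) / cfg.fs_ppg
        assert abs(t_est - 1.25) <= 1.0 / cfg.fs_ppg

    def test_zero_beats_flat_baseline(self):
        wf = synthesize_ppg(np.empty(0), np.empty(0), _quiet(duration=2.0))
        assert np.allclose(wf.samples, 0.0)

    def test_overlapping_upstrokes_rejected(self):
        cfg = _quiet(duration=5.0)
        beats = np.array([1.0, 1.05])
        with pytest.raises(ValueError, match="overlap"):
            synthesize_ppg(beats, np.full(2, 0.25), cfg)


class TestClockModel:
    def test_zero_drift_is_identity_with_no_events(self):
        cfg = _quiet(duration=20.0, noise_sd_ppg=0.01)
        wf = synthesize_ppg(np.arange(1.0, 19.0), np.full(18, 0.25), cfg)
        out, events = apply_clock_skew(wf, ClockModel(drift_ppm=0.0))
        assert np.array_equal(out.samples, wf.samples)
        assert events.size == 0

    @pytest.mark.parametrize(
        "drift, expected_period", [(80.0, 100.0), (160.0, 50.0)]
    )
    def test_correction_events_at_quantum_over_drift(self, drift, expected_period):
        clock = ClockModel(drift_ppm=drift, correction_quantum=0.008)
        t = np.arange(0, 400.0, 1 / 125.0)
        _, events = alignment_offset(clock, t)
        assert np.allclose(np.diff(events), expected_period, atol=0.01)
        assert events[0] == pytest.approx(expected_period, abs=0.01)

    def test_offset_is_sawtooth_with_quantum_amplitude(self):
        clock = preset_clock("skwhsmh")
        t = np.arange(0, 1600.0, 0.25)
        offset, events = alignment_offset(clock, t)
        assert offset.min() >= 0.0
        assert offset.max() <= clock.correction_quantum + 1e-12
        # drop by ~one quantum across each event
        for ev in events[:3]:
            i = np.searchsorted(t, ev)
            # drop of one quantum, less the drift accumulated over the step
            assert offset[i] - offset[i - 1] == pytest.approx(
                -clock.correction_quantum, abs=5e-5
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        drift=st.floats(20.0, 500.0),
        quantum=st.floats(0.004, 0.02),
    )
    def test_offset_period_property(self, drift, quantum):
        clock = ClockModel(drift_ppm=drift, correction_quantum=quantum)
        t = np.arange(0.0, 3.5 * clock.period, 0.1)
        offset, events = alignment_offset(clock, t)
        assert np.all((offset >= -1e-12) & (offset <= quantum + 1e-12))
        if events.size >= 2:
            assert np.allclose(np.diff(events), clock.period, rtol=1e-6, atol=0.1)

    def test_preset_periods(self):
        assert preset_clock("skwhsmh").period == pytest.approx(100.0)
        assert preset_clock("cgmh75").period == pytest.approx(75.0)
        assert preset_clock("cgmh150").period == pytest.approx(150.0)
        assert preset_clock("cgmh10").period == pytest.approx(10.0)
        assert np.isinf(preset_clock("clean").period)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            preset_clock("nope")


class TestDeterminism:
    def test_full_simulation_is_bit_identical_under_seed(self):
        cfg = SimulationConfig(duration=60.0, seed=9)
        clock = preset_clock("skwhsmh")
        e1, p1, t1 = synth.simulate_subject(cfg, clock)
        e2, p2, t2 = synth.simulate_subject(
            SimulationConfig(duration=60.0, seed=9), clock
        )
        assert np.array_equal(e1.samples, e2.samples)
        assert np.array_equal(p1.samples, p2.samples)
        assert np.array_equal(t1.beat_times, t2.beat_times)
        assert np.array_equal(t1.true_ptt, t2.true_ptt)

    def test_different_seeds_differ(self):
        e1, _, _ = synth.simulate_subject(SimulationConfig(duration=30.0, seed=1), None)
        e2, _, _ = synth.simulate_subject(SimulationConfig(duration=30.0, seed=2), None)
        assert not np.array_equal(e1.samples, e2.samples)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"duration": 0.0},
            {"mean_hr": 10.0},
            {"mean_hr": 400.0},
            {"ptt_baseline": 0.0},
            {"fs_ecg": 50.0},
            {"fs_ppg": 10.0},
            {"hrv_amplitudes": ((0.1, -0.01),)},
            {"rr_jitter_sd": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)
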