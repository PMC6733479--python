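"""PTT extraction: upsampling, R peaks, pulse arrival, pairing, resampling."""

import numpy as np
import pytest

from pttsaw import synth
from pttsaw.core import Waveform
from pttsaw.ptt import (
    compute_ptt,
    detect_pulse_arrival,
    detect_r_peaks,
    extract_ptt_series,
    resample_ptt,
    upsample_ppg,
)
from pttsaw.synth import SimulationConfig, alignment_offset, simulate_subject


class TestUpsample:
    def test_constant_signal_stays_constant(self):
        wf = upsample_ppg(Waveform(np.full(125, 3.3), 125.0), 500.0)
        assert wf.fs == 500.0
        assert np.allclose(wf.samples, 3.3)

    def test_linear_ramp_reproduced_exactly(self):
        ramp = np.arange(250) * 0.4
        wf = upsample_ppg(Waveform(ramp, 125.0), 500.0)
        t = wf.times
        assert np.allclose(wf.samples, 0.4 * 125.0 * t, atol=1e-12)

    def test_sine_error_bounded_by_curvature_term(self):
        # linear interpolation error <= (dt^2 / 8) * max|f''|
        t125 = np.arange(0, 5, 1 / 125.0)
        wf = upsample_ppg(Waveform(np.sin(2 * np.pi * t125), 125.0), 500.0)
        truth = np.sin(2 * np.pi * wf.times)
        bound = (1 / 125.0) ** 2 / 8 * (2 * np.pi) ** 2
        assert np.abs(wf.samples - truth).max() <= bound * 1.001

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError, match="target_fs"):
            upsample_ppg(Waveform(np.zeros(500), 500.0), 125.0)


class TestRPeaks:
    def test_noise_free_beats_found_within_one_sample(self):
        cfg = SimulationConfig(
            duration=101.0, mean_hr=60.0, hrv_amplitudes=(), rr_jitter_sd=0.0,
            noise_sd_ecg=0.0, seed=0,
        )
        beats = synth.generate_beat_times(cfg) + 0.5
        ecg = synth.synthesize_ecg(beats, cfg)
        det = detect_r_peaks(ecg)
        assert det.size == beats.size
        assert np.abs(det - beats).max() <= 1.0 / cfg.fs_ecg + 1e-12

    def test_flat_signal_yields_no_peaks_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            det = detect_r_peaks(Waveform(np.zeros(5000), 500.0))
        assert det.size == 0

    def test_snr10_sensitivity_and_ppv_above_99_percent(self):
        cfg = SimulationConfig(duration=600.0, noise_sd_ecg=0.1, seed=11)
        beats = synth.generate_beat_times(cfg)
        ecg = synth.synthesize_ecg(beats, cfg)
        det = detect_r_peaks(ecg)
        d = np.abs(beats[:, None] - det[None, :])
        sens = (d.min(axis=1) < 0.05).mean()
        ppv = (d.min(axis=0) < 0.05).mean()
        assert sens >= 0.99
        assert ppv >= 0.99

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="5 s"):
            detect_r_peaks(Waveform(np.zeros(500), 500.0))


def _pulse_at(fs, arrival, duration=3.0):
    """PPG with one pulse whose continuous steepest ascent is at `arrival`."""
    t = np.arange(int(duration * fs)) / fs
    u = t - (arrival - synth.PPG_UPSTROKE_WIDTH / 2)
    return Waveform(synth.ppg_pulse_template(u), fs, label="PPG")


class TestPulseArrival:
    def test_single_pulse_found_within_one_sample_at_500hz(self):
        ppg = _pulse_at(500.0, 1.25)
        arr = detect_pulse_arrival(ppg, np.array([1.0]))
        assert abs(arr[0] - 1.25) <= 1 / 500.0

    def test_descending_window_marked_missing(self):
        wf = Waveform(np.linspace(1, 0, 1500), 500.0)
        arr = detect_pulse_arrival(wf, np.array([0.5]))
        assert np.isnan(arr[0])

    def test_window_past_record_end_marked_missing(self):
        ppg = _pulse_at(500.0, 1.25, duration=1.5)
        arr = detect_pulse_arrival(ppg, np.array([1.0]))
        assert np.isnan(arr[0])

    def test_steeper_of_two_upstrokes_wins(self):
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        shallow = 0.3 * synth.ppg_pulse_template(t - 0.20)
        steep = synth.ppg_pulse_template(t - 0.44)
        wf = Waveform(shallow + steep, fs)
        arr = detect_pulse_arrival(wf, np.array([0.0]))
        assert arr[0] == pytest.approx(0.50, abs=0.01)


class TestComputePtt:
    def test_basic_pairing(self):
        bt, ptt = compute_ptt(
            np.array(12.0 * np.arange(12)),
            np.array(12.0 * np.arange(12)) + 0.25,
            min_beats=10,
        )
        assert np.allclose(ptt, 0.25)

    def test_missing_arrival_dropped(self):
        r = np.arange(12.0)
        a = r + 0.25
        a[4] = np.nan
        bt, ptt = compute_ptt(r, a)
        assert bt.size == 11
        assert 4.0 not in bt

    def test_out_of_window_ptt_dropped(self):
        r = np.arange(12.0)
        a = r + 0.25
        a[3] = r[3] + 0.9  # beyond w_max
        bt, _ = compute_ptt(r, a)
        assert 3.0 not in bt

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError, match="valid beats"):
            compute_ptt(np.arange(5.0), np.arange(5.0) + 0.25)


class TestResample:
    def test_constant_ptt_constant_grid(self):
        t, p = resample_ptt(np.arange(20.0), np.full(20, 0.25))
        assert np.allclose(p, 0.25)
        assert np.allclose(np.diff(t), 0.25)

    def test_knots_reproduced_at_coincident_grid_points(self):
        beats = np.arange(0.0, 20.0, 1.0)  # all knots on the 4 Hz grid
        vals = 0.25 + 0.01 * np.sin(beats)
        t, p = resample_ptt(beats, vals)
        on_knots = np.isin(t, beats)
        assert np.allclose(p[on_knots], vals, atol=1e-12)

    def test_slow_sine_tracked_within_one_ms(self):
        beats = np.arange(0.0, 200.0, 1.0)
        vals = 0.25 + 0.01 * np.sin(2 * np.pi * 0.05 * beats)
        t, p = resample_ptt(beats, vals)
        truth = 0.25 + 0.01 * np.sin(2 * np.pi * 0.05 * t)
        assert np.abs(p - truth).max() <= 0.001

    def test_duplicate_beats_rejected(self):
        b = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="duplicate|increasing"):
            resample_ptt(b, np.full(5, 0.25))

    def test_grid_never_extrapolates(self):
        beats = np.array([0.3, 1.1, 2.2, 3.05, 4.4])
        t, _ = resample_ptt(beats, np.full(5, 0.25))
        assert t[0] == beats[0]
        assert t[-1] <= beats[-1]


class TestEndToEnd:
    def test_identity_at_matched_rates_zero_noise(self):
        """With PPG natively at the ECG rate and no noise, the chain is exact
        to the detectors' 2 ms sample quantization (plus spline overshoot on
        the uniform grid)."""
        cfg = SimulationConfig(
            duration=400.0, noise_sd_ecg=0.0, noise_sd_ppg=0.0,
            rr_jitter_sd=0.0, fs_ppg=500.0, seed=3,
        )
        ecg, ppg, truth = simulate_subject(cfg, None)
        series, _ = extract_ptt_series(ecg, ppg)
        true_beat = np.interp(series.beat_times, truth.beat_times, truth.true_ptt)
        assert np.abs(series.ptt_beat - true_beat).max() <= 0.002 + 1e-9
        true_uniform = np.interp(series.t_uniform, truth.beat_times, truth.true_ptt)
        assert np.abs(series.ptt_uniform - true_uniform).max() <= 0.003

    def test_recovery_within_one_native_ppg_sample(self, clean_subject):
        series = clean_subject["series"]
        truth = clean_subject["truth"]
        true_beat = np.interp(series.beat_times, truth.beat_times, truth.true_ptt)
        err = series.ptt_beat - true_beat
        assert abs(err.mean()) <= 0.008
        # per-beat scatter: one native PPG sample of arrival quantization
        # plus R-peak jitter under noise
        assert np.abs(err).max() <= 0.012

    def test_sawtooth_transfers_into_extracted_ptt(self, skew_subject):
        """With the 80 ppm / 8 ms preset, extracted-minus-true PTT is a
        sawtooth of period 100 +- 2 s and peak-to-peak 8 +- 2 ms."""
        from pttsaw.removal import estimate_sawtooth_template
        from pttsaw.spectral import detect_jumps

        series = skew_subject["series"]
        truth = skew_subject["truth"]
        diff = series.ptt_uniform - np.interp(
            series.t_uniform, truth.beat_times, truth.true_ptt
        )
        jumps = detect_jumps(series.t_uniform, diff, min_jump=0.005)
        period = np.median(np.diff(jumps))
        assert period == pytest.approx(100.0, abs=2.0)
        template = estimate_sawtooth_template(diff, period)
        # peak-to-peak from the fundamental (robust to per-phase noise):
        # a sawtooth of pp amplitude A has fundamental amplitude A / pi.
        c1 = 2 * np.abs(np.fft.rfft(template)[1]) / template.size
        assert c1 * np.pi == pytest.approx(0.008, abs=0.002)

    def test_residual_after_removing_offset_is_small(self, skew_subject):
        series = skew_subject["series"]
        truth = skew_subject["truth"]
        clock = skew_subject["clock"]
        offset, _ = alignment_offset(clock, series.beat_times)
        true_beat = np.interp(series.beat_times, truth.beat_times, truth.true_ptt)
        resid = series.ptt_beat - (true_beat - offset)
        assert np.sqrt(np.mean(resid**2)) <= 0.004

    def test_pairing_is_monotone_and_positive(self, skew_subject):
        ann = skew_subject["annotations"]
        series = skew_subject["series"]
        valid = ann.arrival_times[np.isfinite(ann.arrival_times)]
        assert np.all(np.diff(valid) > 0)  # each arrival used once
        assert np.all(series.ptt_beat > 0)
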