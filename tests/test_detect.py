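import numpy as np
import pytest
from scipy import signal as sps

import ecgdecim as ed
from ecgdecim.detect import window_samples
from ecgdecim.errors import DegenerateSignalError


class TestBandpass:
    def test_dc_rejected(self):
        out = ed.bandpass(np.ones(1000), fs=80.0)
        assert np.abs(out).max() < 1e-6

    def test_midband_tone_passes_at_unit_gain(self):
        fs = 80.0
        x = np.sin(2 * np.pi * 14 * np.arange(int(20 * fs)) / fs)
        out = ed.bandpass(x, fs)
        measured = np.abs(out[400:-400]).max()
        # oracle: designed filter's response at 14 Hz (zero-phase => |H|^2)
        sos = sps.butter(3, [8, 20], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[14.0], fs=fs)
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=1e-3)
        assert abs(measured - 1.0) < 0.05

    def test_baseline_wander_attenuated_20db(self):
        fs = 80.0
        x = np.sin(2 * np.pi * 0.3 * np.arange(int(60 * fs)) / fs)
        out = ed.bandpass(x, fs)
        assert 20 * np.log10(np.abs(out[2000:-2000]).max()) <= -20

    def test_f2_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            ed.bandpass(np.zeros(100), fs=30.0)


class TestEnhanceAndMovingAverage:
    def test_enhance_squares_elementwise(self):
        np.testing.assert_array_equal(ed.enhance(np.array([-2.0, 3.0])),
                                      [4.0, 9.0])
        assert (ed.enhance(np.zeros(5)) == 0).all()
        assert (ed.enhance(np.random.default_rng(0).standard_normal(100))
                >= 0).all()

    def test_constant_sequence_invariant(self):
        out = ed.moving_average(np.full(500, 3.7), window_s=0.1, fs=100)
        np.testing.assert_allclose(out, 3.7)
        assert out.size == 500

    @pytest.mark.parametrize("window_s,fs,expected", [
        (0.097, 80, 7),     # nearest odd to 7.76
        (0.611, 80, 49),    # nearest odd to 48.88
        (0.097, 360, 35),   # nearest odd to 34.92
        (0.001, 100, 3),    # floored at the 3-sample minimum
    ])
    def test_window_sample_conversion(self, window_s, fs, expected):
        assert window_samples(window_s, fs) == expected

    def test_impulse_train_mean_matches_density(self):
        # one unit impulse per second; a 1 s centred window averages to ~1/fs
        fs, dur = 100, 30
        x = np.zeros(fs * dur)
        x[fs // 2 :: fs] = 1.0
        out = ed.moving_average(x, window_s=1.0, fs=fs)
        w = window_samples(1.0, fs)
        interior = out[w : -w]
        assert interior.mean() == pytest.approx(1.0 / fs, rel=0.05)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            ed.moving_average(np.ones(10), window_s=1.0, fs=100)


class TestDetect:
    def test_zero_signal_no_detections(self):
        rec = ed.EcgRecord("z", np.zeros(8000), fs=80.0)
        result = ed.detect(rec)
        assert result.r_indices.size == 0

    def test_clean_synthetic_all_beats_within_one_sample(self):
        rec = ed.generate(ed.SyntheticEcgSpec(duration_s=60, fs=80,
                                              heart_rate_bpm=60, seed=1))
        result = ed.detect(rec)
        assert result.r_indices.size == rec.beat_indices.size == 60
        assert np.abs(result.r_indices - rec.beat_indices).max() <= 1

    def test_tall_t_waves_cause_no_false_positives(self, optimum_spec):
        spec = ed.tall_t_spec(ed.SyntheticEcgSpec(
            duration_s=120, fs=360, heart_rate_bpm=75, rr_jitter_sd_s=0.04,
            seed=9))
        rec = ed.generate(spec)
        sig = ed.resample(rec, optimum_spec)
        det = ed.detect(sig)
        outcome = ed.match_beats(rec.beat_indices, det.map_indices(rec.fs),
                                 rec.fs, 0.075)
        assert outcome.fp == 0
        assert outcome.fn == 0

    @pytest.mark.parametrize("scale", [0.1, 10.0])
    def test_scale_invariance(self, scale):
        rec = ed.generate(ed.SyntheticEcgSpec(duration_s=60, fs=80,
                                              heart_rate_bpm=70,
                                              rr_jitter_sd_s=0.03, seed=2))
        base = ed.detect(rec)
        scaled = ed.detect(rec.with_samples(rec.samples * scale))
        np.testing.assert_array_equal(base.r_indices, scaled.r_indices)

    def test_r_peaks_inside_disjoint_blocks(self):
        rec = ed.generate(ed.SyntheticEcgSpec(duration_s=60, fs=80,
                                              heart_rate_bpm=80,
                                              rr_jitter_sd_s=0.05, seed=3))
        result = ed.detect(rec, keep_trace=True)
        blocks = result.trace.blocks
        assert result.r_indices.size == len(blocks)
        for idx, (s, e) in zip(result.r_indices, blocks):
            assert s <= idx < e
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            assert e1 <= s2

    def test_too_short_signal_rejected(self):
        rec = ed.EcgRecord("s", np.ones(30), fs=80.0)
        with pytest.raises(DegenerateSignalError):
            ed.detect(rec)

    def test_index_mapping_to_original_rate(self):
        det = ed.DetectionResult(r_indices=np.array([80, 160]), fs=80.0)
        np.testing.assert_array_equal(det.map_indices(360.0), [360, 720])

    def test_fscore_non_increasing_with_noise(self, optimum_spec):
        clean = ed.generate(ed.SyntheticEcgSpec(
            duration_s=120, fs=360, heart_rate_bpm=70, rr_jitter_sd_s=0.04,
            seed=11))
        gs = []
        for sd in (0.0, 0.05, 0.1, 0.2, 0.4):
            noisy = ed.add_noise(clean, sd, wander_amp=0.3, wander_freq=0.3,
                                 seed=99)
            outcome, _ = ed.evaluate_record(noisy, optimum_spec,
                                            compute_prd=False)
            gs.append(outcome.g)
        assert all(a >= b - 1e-12 for a, b in zip(gs, gs[1:]))
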