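import numpy as np
import pytest
from scipy import signal as sps

import ecgdecim as ed
from ecgdecim.compress import _output_length
from ecgdecim.errors import DegenerateSignalError


class TestResampleSpec:
    def test_reduced_factors_exact(self):
        spec = ed.ResampleSpec.create(360, 390, 80)
        assert (spec.up_factor, spec.down_factor) == (2, 9)
        assert spec.fs_in * spec.up_factor / spec.down_factor == spec.K

    def test_qt_rate_reduces_to_exact_rational(self):
        spec = ed.ResampleSpec.create(250, 390, 80)
        assert (spec.up_factor, spec.down_factor) == (8, 25)

    def test_k_must_not_exceed_b(self):
        with pytest.raises(ValueError):
            ed.ResampleSpec.create(360, 390, 400)

    def test_configurable_k_floor(self):
        with pytest.raises(ValueError, match="floor"):
            ed.ResampleSpec.create(360, 390, 40)
        spec = ed.ResampleSpec.create(360, 390, 40, k_floor=None)
        assert spec.K == 40

    def test_design_grid_includes_b(self):
        spec = ed.ResampleSpec.create(360, 390, 80)
        assert spec.design_grid_hz == 9360
        assert spec.grid_factors() == (26, 117)


class TestDesignFilter:
    def test_identity_spec_gives_passthrough(self):
        spec = ed.ResampleSpec.create(360, 390, 360)
        filt = ed.design_filter(spec)
        assert filt.taps.tolist() == [1.0]
        assert filt.gain == 1.0

    def test_dc_response_equals_up_factor(self, optimum_spec):
        filt = ed.design_filter(optimum_spec)
        up, _ = optimum_spec.grid_factors()
        assert filt.taps.sum() == pytest.approx(up, rel=1e-6)
        assert filt.gain == up

    def test_cutoff_is_output_nyquist(self, optimum_spec):
        # 360 Hz -> 80 Hz via 390 Hz: stopband edge at K/2 = 40 Hz
        filt = ed.design_filter(optimum_spec)
        grid = optimum_spec.design_grid_hz
        assert filt.cutoff * grid / (2 * np.pi) == pytest.approx(40.0)

    def test_measured_stopband_attenuation(self, optimum_spec):
        filt = ed.design_filter(optimum_spec, stopband_atten_db=60)
        grid = optimum_spec.design_grid_hz
        w, h = sps.freqz(filt.taps, worN=4096, fs=grid)
        stop = np.abs(h[w >= 40.0]) / filt.gain
        assert 20 * np.log10(stop.max()) <= -60

    def test_taps_symmetric(self, optimum_spec):
        taps = ed.design_filter(optimum_spec).taps
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)


class TestResample:
    def test_identity_is_exact(self, rng):
        rec = ed.EcgRecord("x", rng.standard_normal(1000), 360.0)
        spec = ed.ResampleSpec.create(360, 390, 360)
        sig = ed.resample(rec, spec)
        assert np.abs(sig.samples - rec.samples).max() <= 1e-9
        assert sig.fs_out == 360

    def test_pure_sine_matches_analytic_resampling(self, optimum_spec):
        fs, f0 = 360.0, 5.0
        t = np.arange(int(10 * fs)) / fs
        rec = ed.EcgRecord("sine", np.sin(2 * np.pi * f0 * t), fs)
        sig = ed.resample(rec, optimum_spec)
        t_out = np.arange(sig.n) / sig.fs_out
        analytic = np.sin(2 * np.pi * f0 * t_out)
        edge = int(2 * sig.fs_out)  # discard edge transients
        dev = np.abs(sig.samples[edge:-edge] - analytic[edge:-edge])
        assert dev.max() < 0.01
        assert sig.fs_out == 80.0

    def test_passband_tone_amplitude_preserved(self, optimum_spec):
        # 30 Hz is below 0.9x the passband edge (36 Hz) of the 40 Hz filter
        fs = 360.0
        t = np.arange(int(30 * fs)) / fs
        sig = ed.resample(ed.EcgRecord("t", np.sin(2 * np.pi * 30 * t), fs),
                          optimum_spec)
        interior = sig.samples[200:-200]
        assert abs(np.abs(interior).max() - 1.0) < 0.01

    def test_stopband_tone_suppressed(self, optimum_spec):
        fs = 360.0
        t = np.arange(int(30 * fs)) / fs
        sig = ed.resample(ed.EcgRecord("t", np.sin(2 * np.pi * 50 * t), fs),
                          optimum_spec)
        assert np.abs(sig.samples[200:-200]).max() <= 10 ** (-60 / 20)

    def test_length_ratio_approaches_k_over_fs(self, optimum_spec, rng):
        for n in (1000, 10_000, 100_000):
            rec = ed.EcgRecord("x", rng.standard_normal(n), 360.0)
            sig = ed.resample(rec, optimum_spec)
            assert sig.n == _output_length(n, 2, 9)
            assert sig.n / n == pytest.approx(80 / 360, abs=1 / n * 9)

    def test_signal_shorter_than_filter_rejected(self, optimum_spec):
        rec = ed.EcgRecord("short", np.ones(50), 360.0)
        with pytest.raises(DegenerateSignalError):
            ed.resample(rec, optimum_spec)

    def test_trace_zero_stuffing_structure(self, rng):
        spec = ed.ResampleSpec.create(100, 200, 50)
        rec = ed.EcgRecord("x", rng.standard_normal(400), 100.0)
        sig, trace = ed.resample(rec, spec, keep_trace=True)
        up, _ = spec.grid_factors()
        J = trace.J
        mask = np.ones(J.size, dtype=bool)
        mask[::up] = False
        assert np.all(J[mask] == 0.0)
        np.testing.assert_array_equal(J[::up], rec.samples)


class TestOracleEquivalence:
    def test_fast_path_equals_literal_three_step(self, rng):
        for _ in range(60):
            up = int(rng.integers(1, 11))
            down = int(rng.integers(1, 11))
            taps = rng.standard_normal(int(rng.integers(3, 41)) * 2 + 1)
            x = rng.standard_normal(int(rng.integers(20, 2001)))
            fast = ed.rational_resample(x, taps, up, down)
            literal, _ = ed.resample_literal(x, taps, up, down)
            assert fast.shape == literal.shape
            assert np.abs(fast - literal).max() <= 1e-9


class TestReconstruct:
    def test_identity_roundtrip_exact(self, rng):
        rec = ed.EcgRecord("x", rng.standard_normal(2000), 360.0)
        spec = ed.ResampleSpec.create(360, 390, 360)
        back = ed.reconstruct(ed.resample(rec, spec))
        assert np.abs(back.samples - rec.samples).max() <= 1e-9

    def test_bandlimited_signal_reconstructs_below_one_percent(self, rng,
                                                               optimum_spec):
        # energy confined below 30 Hz << the 40 Hz output Nyquist
        lp = sps.firwin(401, 30, fs=360)
        x = sps.filtfilt(lp, [1], rng.standard_normal(int(60 * 360)))
        rec = ed.EcgRecord("bl", x, 360.0)
        back = ed.reconstruct(ed.resample(rec, optimum_spec))
        m = 2000
        assert ed.prd(x[m:-m], back.samples[m:-m]) < 1.0

    def test_white_noise_error_energy_matches_spectrum_above_nyquist(
            self, rng, optimum_spec):
        x = rng.standard_normal(int(60 * 360))
        rec = ed.EcgRecord("wn", x, 360.0)
        back = ed.reconstruct(ed.resample(rec, optimum_spec))
        m = 2000
        xi, ri = x[m:-m], back.samples[m:-m]
        err_frac = np.sum((xi - ri) ** 2) / np.sum(xi**2)
        X = np.fft.rfft(xi)
        f = np.fft.rfftfreq(xi.size, 1 / 360)
        spectral_frac = np.sum(np.abs(X[f > 40]) ** 2) / np.sum(np.abs(X) ** 2)
        assert err_frac == pytest.approx(spectral_frac, rel=0.10)

    def test_reconstruction_length_matches_original(self, clean_record,
                                                    optimum_spec):
        back = ed.reconstruct(ed.resample(clean_record, optimum_spec))
        assert back.n == clean_record.n
        assert back.fs == clean_record.fs
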