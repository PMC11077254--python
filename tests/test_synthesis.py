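"""Carrier noise, spectral envelopes, stimulus synthesis and verification.

Spectral assertions use an independent averaged-periodogram oracle
(scipy.signal.welch called directly, or raw FFT band powers) rather than
the package's own SpectrumReport wherever the property under test is the
synthesized signal itself.
"""

import math
import wave

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from tinnisynth import (
    Audiogram,
    ConfigurationError,
    NoHearingLossError,
    Signal,
    SynthesisConfig,
    ValidationError,
    apply_envelope,
    envelope_placebo,
    envelope_v1,
    envelope_v2,
    gaussian_noise,
    loss_region,
    normalize,
    read_wav,
    smoothing_width,
    spectrum_report,
    synthesize_placebo,
    synthesize_study,
    write_wav,
)


def _band_power(x, fs, f_lo, f_hi):
    """Oracle: total power in [f_lo, f_hi] from the raw periodogram."""
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1 / fs)
    m = (f >= f_lo) & (f <= f_hi)
    return float(np.sum(np.abs(X[m]) ** 2))


class TestGaussianNoise:
    def test_seed_determinism_bitwise(self, fast_config):
        a = gaussian_noise(fast_config)
        b = gaussian_noise(fast_config)
        assert np.array_equal(a.samples, b.samples)

    def test_moments_at_full_duration(self):
        config = SynthesisConfig(seed=2, duration=60.0)
        s = gaussian_noise(config)
        n = len(s.samples)
        assert n == 60 * 44100
        assert abs(float(np.mean(s.samples))) <= 4 * config.target_rms / math.sqrt(n)
        assert s.rms == pytest.approx(config.target_rms, rel=1e-12)

    def test_spectral_flatness_octave_bands(self):
        """Adjacent octave-band powers agree within 0.5 dB at 60 s (Welch oracle)."""
        s = gaussian_noise(SynthesisConfig(seed=5, duration=60.0))
        f, psd = sps.welch(s.samples, fs=44100, nperseg=8192, noverlap=4096, detrend=False)
        p1 = np.sum(psd[(f >= 500) & (f < 1000)])
        p2 = np.sum(psd[(f >= 1000) & (f < 2000)])
        # octave bands double in bin count, so compare mean PSD
        m1 = p1 / np.sum((f >= 500) & (f < 1000))
        m2 = p2 / np.sum((f >= 1000) & (f < 2000))
        assert abs(10 * math.log10(m1 / m2)) < 0.5


class TestSmoothingWidth:
    @pytest.mark.parametrize(
        "delta, expected",
        [(40, 0.25), (5, 1.0), (1000, 0.05), (0, 1.0), (10, 1.0), (200, 0.05)],
    )
    def test_mapping(self, delta, expected):
        assert smoothing_width(delta) == pytest.approx(expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValidationError):
            smoothing_width(-1)

    @given(st.floats(0, 500), st.floats(0, 500))
    @settings(deadline=None, max_examples=100)
    def test_monotone_nonincreasing(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert smoothing_width(hi) <= smoothing_width(lo)


class TestEnvelopes:
    def test_v1_confined_to_loss_band(self, sloping_audiogram):
        r = loss_region(sloping_audiogram)
        e = envelope_v1(sloping_audiogram, r, w=0.25)
        assert e.passband == (1000, 8000)
        # well outside the transitions the gain sits at the stopband floor
        assert e.gain_db(1000 * 2 ** (-2 * 0.25)) <= -60 + 1e-9
        assert e.gain_db(8000 * 2 ** (2 * 0.25)) <= -60 + 1e-9

    def test_v1_flat_loss_gives_flat_passband(self):
        a = Audiogram("right", [(500, 10), (1000, 50), (2000, 50), (4000, 50), (8000, 50)])
        r = loss_region(a)
        e = envelope_v1(a, r, w=0.2)
        f = np.geomspace(1000, 8000, 50)
        assert np.allclose(e.gain_db(f), 0.0, atol=1e-9)

    def test_v1_deeper_loss_gets_more_gain(self, sloping_audiogram):
        r = loss_region(sloping_audiogram)
        e = envelope_v1(sloping_audiogram, r, w=0.25)
        # thresholds rise 20 -> 65 dB HL across the band, so gain rises too
        assert e.gain_db(1000) < e.gain_db(4000) < e.gain_db(8000) == pytest.approx(0.0)

    @pytest.mark.parametrize("pitch, lo, hi", [(4000, 3600, 4400), (1000, 900, 1100)])
    def test_v2_band_rule(self, pitch, lo, hi):
        e = envelope_v2(pitch)
        assert e.passband == (lo, hi)
        # geometric band center within 1% of the pitch
        assert math.sqrt(lo * hi) == pytest.approx(pitch, rel=0.01)

    def test_placebo_band_is_normal_range(self, sloping_audiogram):
        r = loss_region(sloping_audiogram)
        e = envelope_placebo(sloping_audiogram, r)
        assert e.passband == (125, 1000)

    def test_placebo_needs_normal_range(self):
        a = Audiogram("right", [(125, 40), (1000, 50), (4000, 60)])
        r = loss_region(a)
        with pytest.raises(ConfigurationError):
            envelope_placebo(a, r)


class TestApplyEnvelope:
    def test_identity_envelope(self, fast_config):
        from tinnisynth import SpectralEnvelope

        s = gaussian_noise(fast_config)
        e = SpectralEnvelope(np.array([10.0, 20000.0]), np.array([0.0, 0.0]))
        out = apply_envelope(s, e)
        assert np.allclose(out.samples, s.samples, atol=1e-12)

    def test_floor_envelope_attenuates_everything(self, fast_config):
        from tinnisynth import SpectralEnvelope

        s = gaussian_noise(fast_config)
        e = SpectralEnvelope(np.array([10.0, 20000.0]), np.array([-60.0, -60.0]))
        out = apply_envelope(s, e)
        ratio = np.sum(out.samples**2) / np.sum(s.samples**2)
        assert 10 * math.log10(ratio) <= -60 + 0.1

    def test_v2_band_confines_99_percent_of_power(self, fast_config):
        s = gaussian_noise(fast_config)
        out = apply_envelope(s, envelope_v2(4000))
        total = _band_power(out.samples, 44100, 0, 22050)
        in_band = _band_power(out.samples, 44100, 3400, 4600)
        assert in_band / total >= 0.99


class TestStudySound:
    def test_spectrum_peaks_in_emphasis_band(self, sloping_audiogram, matched_profile, fast_config):
        s = synthesize_study(sloping_audiogram, matched_profile, fast_config)
        rep = spectrum_report(s, (1000, 8000))
        assert 3600 <= rep.peak_frequency <= 4400

    def test_bitwise_determinism_including_wav(self, sloping_audiogram, matched_profile,
                                               fast_config, tmp_path):
        s1 = synthesize_study(sloping_audiogram, matched_profile, fast_config)
        s2 = synthesize_study(sloping_audiogram, matched_profile, fast_config)
        assert np.array_equal(s1.samples, s2.samples)
        p1, p2 = tmp_path / "a.wav", tmp_path / "b.wav"
        write_wav(s1, p1)
        write_wav(s2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_low_frequency_rejection(self, sloping_audiogram, matched_profile, fast_config):
        """Below 500 Hz (an octave under the 1 kHz loss onset) the PSD sits
        >= 40 dB under the passband median (Welch oracle)."""
        s = synthesize_study(sloping_audiogram, matched_profile, fast_config)
        f, psd = sps.welch(s.samples, fs=44100, nperseg=8192, noverlap=4096, detrend=False)
        db = 10 * np.log10(psd + 1e-30)
        band_median = np.median(db[(f >= 1000) & (f <= 8000)])
        low_max = db[(f > 0) & (f < 500)].max()
        assert band_median - low_max >= 40

    def test_psd_additivity_of_components(self, sloping_audiogram, matched_profile, fast_config):
        """v3's band power matches the sum of its components' (independent
        noise seeds, so cross terms vanish statistically)."""
        from dataclasses import replace

        cfg = fast_config
        r = loss_region(sloping_audiogram)
        e1 = envelope_v1(sloping_audiogram, r, w=smoothing_width(5.0))
        v1 = apply_envelope(gaussian_noise(cfg), e1)
        v2 = apply_envelope(gaussian_noise(replace(cfg, seed=cfg.seed + 1)), envelope_v2(4000))
        scale = 10 ** (cfg.emphasis_gain_db / 20)
        combined = v1.samples + scale * v2.samples
        p_sum = np.sum(v1.samples**2) + scale**2 * np.sum(v2.samples**2)
        assert np.sum(combined**2) == pytest.approx(p_sum, rel=0.05)

    def test_pitch_outside_loss_region_warns(self, fast_config):
        a = Audiogram("right", [(250, 10), (500, 15), (1000, 50), (2000, 55), (4000, 60), (8000, 60)])
        from tinnisynth import TinnitusProfile

        p = TinnitusProfile("right", 250, 60, 55, "positive", 24, True)
        with pytest.warns(UserWarning, match="outside the hearing-loss region"):
            s = synthesize_study(a, p, fast_config)
        assert s.provenance["notes"]  # recorded, not fatal


class TestPlaceboSound:
    def test_band_edges(self, sloping_audiogram, fast_config):
        s = synthesize_placebo(sloping_audiogram, fast_config)
        assert s.provenance["passband_hz"] == (125, 1000)
        rep = spectrum_report(s, (125, 1000))
        bin_hz = 44100 / 8192
        transition = 1000 * (2**0.05 - 1)
        assert rep.band_edges[1] == pytest.approx(1000, abs=bin_hz + transition)
        assert rep.band_edges[0] == pytest.approx(125, abs=bin_hz + 125 * (1 - 2**-0.05))

    def test_no_energy_in_loss_frequencies(self, sloping_audiogram, fast_config):
        s = synthesize_placebo(sloping_audiogram, fast_config)
        f, psd = sps.welch(s.samples, fs=44100, nperseg=8192, noverlap=4096, detrend=False)
        db = 10 * np.log10(psd + 1e-30)
        band_median = np.median(db[(f >= 125) & (f <= 1000)])
        assert band_median - db[f >= 2000].max() >= 40

    def test_fully_normal_audiogram_rejected(self, fast_config):
        a = Audiogram("right", [(250, 5), (1000, 10), (4000, 10), (8000, 10)])
        with pytest.raises(NoHearingLossError):
            synthesize_placebo(a, fast_config)


class TestNormalizeAndWav:
    def test_rms_exact(self):
        rng = np.random.default_rng(0)
        s = Signal(rng.standard_normal(44100), 44100)
        out = normalize(s, 0.1)
        assert out.rms == pytest.approx(0.1, abs=1e-6)

    def test_peak_limiting(self):
        t = np.arange(44100) / 44100
        s = Signal(np.clip(10 * np.sin(2 * np.pi * 440 * t), -32, 32), 44100)
        out = normalize(s, 0.9)  # would clip at RMS 0.9
        assert out.peak == pytest.approx(0.999, abs=1e-9)
        assert out.provenance["peak_limited"]

    def test_zero_signal_rejected(self):
        with pytest.raises(ValidationError):
            normalize(Signal(np.zeros(100), 44100), 0.1)

    def test_wav_header_and_round_trip(self, tmp_path, fast_config):
        s = normalize(gaussian_noise(fast_config), 0.1)
        path = tmp_path / "s.wav"
        write_wav(s, path)
        with wave.open(str(path)) as wf:  # independent stdlib reader
            assert wf.getframerate() == 44100
            assert wf.getnchannels() == 1
            assert wf.getsampwidth() == 2
        back = read_wav(path)
        assert np.max(np.abs(back.samples - s.samples)) <= 2**-15

    def test_empty_signal_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_wav(Signal(np.array([]), 44100), tmp_path / "x.wav")


class TestSpectrumReport:
    def test_pure_tone_peak(self):
        t = np.arange(2 * 44100) / 44100
        s = Signal(0.5 * np.sin(2 * np.pi * 1000 * t), 44100)
        rep = spectrum_report(s, (900, 1100))
        assert rep.peak_frequency == pytest.approx(1000, abs=44100 / 8192)

    def test_too_short_signal(self):
        with pytest.raises(ValidationError):
            spectrum_report(Signal(np.ones(1000), 44100), (100, 1000))
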