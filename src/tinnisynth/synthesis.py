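"""Individualized therapy-sound synthesis.

The treatment stimulus is built from seeded Gaussian white noise at
44.1 kHz, shaped in the frequency domain:

* **v1** — the noise band-pass filtered to the patient's hearing-loss
  frequency range, with an in-band gain that follows the audiogram (more
  loss -> more relative energy) and raised-cosine transitions whose width in
  octaves is the *smoothing*: inversely proportional to how abruptly the
  loss begins (steep onset -> sharp filter edge, shallow onset -> gentle
  edge, so the stimulus spectrum tracks the loss configuration).
* **v2** — an independent noise confined to the tinnitus-pitch emphasis
  band, 10% below to 10% above the matched pitch, mixed on top of v1 a few
  dB hot so the combined spectrum peaks at the tinnitus pitch.
* **v3 = v1 + v2** — the study-group stimulus, RMS-normalized and
  peak-limited for 16-bit delivery.
* **placebo** — the complement: noise confined to the normal-hearing range
  below the loss onset, flat in-band, with the narrowest transition so no
  energy spills into the loss frequencies.

All filtering is frequency-domain multiplication by a dB envelope sampled
per FFT bin (interpolated linearly in log2-frequency and dB), which gives
exact band edges, no passband ripple, and a verifiable stopband floor.
Every output is a pure function of (audiogram, profile, config): identical
seeds give bitwise-identical samples.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .audiogram import (
    NORMAL_CUTOFF_DB_HL,
    Audiogram,
    HearingLossRegion,
    loss_region,
    onset_delta,
)
from .errors import ConfigurationError, ValidationError
from .screening import TinnitusProfile

#: Fractional half-width of the tinnitus-pitch emphasis band (band spans
#: pitch·(1±PITCH_BAND_FRACTION)).
PITCH_BAND_FRACTION = 0.10

#: Fixed raised-cosine transition width (octaves) of the emphasis band.
PITCH_BAND_TRANSITION_OCTAVES = 0.02


@dataclass(frozen=True)
class SynthesisConfig:
    """Synthesis parameters.

    sample_rate : Hz, 44 100 by default (must exceed twice the highest
    audiometric frequency).  duration : seconds per file (looped on the
    playback device).  target_rms : linear digital RMS after normalization.
    emphasis_gain_db : how far the pitch-band PSD sits above the v1 passband
    plateau.  stopband_floor_db : envelope amplitude floor outside
    passbands, relative to the passband maximum.  smoothing_c / w_min /
    w_max : constants of the onset-delta -> transition-width mapping (see
    :func:`smoothing_width`).  flat_v1 : use a flat 0 dB passband for v1
    instead of the audiogram-shaped one.
    """

    sample_rate: int = 44100
    duration: float = 60.0
    seed: int = 0
    target_rms: float = 0.1
    emphasis_gain_db: float = 6.0
    stopband_floor_db: float = -60.0
    normal_cutoff: float = NORMAL_CUTOFF_DB_HL
    smoothing_c: float = 10.0
    w_min: float = 0.05
    w_max: float = 1.0
    flat_v1: bool = False

    def __post_init__(self):
        if self.sample_rate <= 2 * 20000:
            raise ValidationError("sample_rate must exceed twice the audiometric maximum (40 kHz)")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if not (0 < self.target_rms < 1):
            raise ValidationError("target_rms must be in (0, 1)")
        if self.stopband_floor_db >= 0:
            raise ValidationError("stopband floor must be negative (re passband)")
        if not (0 < self.w_min <= self.w_max):
            raise ValidationError("need 0 < w_min <= w_max")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class Signal:
    """Sampled mono waveform with provenance (seed, config digest, notes)."""

    samples: np.ndarray
    sample_rate: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("signal must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self.samples) else 0.0

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0


@dataclass(frozen=True)
class SpectralEnvelope:
    """Gain-versus-frequency curve, interpolated linearly in log2-f and dB.

    Outside the stored points the gain continues at the boundary value
    (the stopband floor for band envelopes).  ``passband`` records the
    nominal [low, high] edge frequencies in Hz.
    """

    frequencies_hz: np.ndarray
    gains_db: np.ndarray
    passband: tuple[float, float] | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=np.float64)
        g = np.asarray(self.gains_db, dtype=np.float64)
        if f.ndim != 1 or f.shape != g.shape or len(f) < 2:
            raise ValidationError("envelope needs matching 1-D frequency/gain arrays (>= 2 points)")
        if np.any(np.diff(f) <= 0):
            raise ValidationError("envelope frequencies must be strictly increasing")
        if np.any(f <= 0):
            raise ValidationError("envelope frequencies must be positive")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "gains_db", g)

    def gain_db(self, f) -> np.ndarray:
        """Envelope gain in dB (amplitude) at frequencies ``f`` (Hz)."""
        f = np.asarray(f, dtype=np.float64)
        logf = np.log2(np.maximum(f, 1e-6))
        return np.interp(logf, np.log2(self.frequencies_hz), self.gains_db)

    def linear_gain(self, f) -> np.ndarray:
        return 10.0 ** (self.gain_db(f) / 20.0)


@dataclass(frozen=True)
class SpectrumReport:
    """Welch-PSD summary of a synthesized sound.

    ``band_edges`` are the outermost frequencies within 3 dB of the passband
    median; ``out_of_band_rejection`` is the passband median minus the
    loudest PSD bin outside the hinted band (expanded by a margin to skip
    the filter transitions).
    """

    frequencies_hz: np.ndarray
    psd_db: np.ndarray
    peak_frequency: float
    band_edges: tuple[float, float]
    out_of_band_rejection: float

    def to_dict(self, max_points: int = 512) -> dict:
        step = max(1, len(self.frequencies_hz) // max_points)
        return {
            "peak_frequency_hz": self.peak_frequency,
            "band_edges_hz": list(self.band_edges),
            "out_of_band_rejection_db": self.out_of_band_rejection,
            "psd": {
                "frequency_hz": self.frequencies_hz[::step].tolist(),
                "power_db": self.psd_db[::step].tolist(),
            },
        }


# ---------------------------------------------------------------------------
# carrier

def gaussian_noise(config: SynthesisConfig) -> Signal:
    """Seeded zero-mean Gaussian white noise scaled to the target RMS.

    The carrier for every stimulus; identical (seed, config) gives
    bitwise-identical samples.
    """
    rng = np.random.default_rng(config.seed)
    x = rng.standard_normal(config.n_samples)
    x *= config.target_rms / np.sqrt(np.mean(np.square(x)))
    return Signal(
        samples=x,
        sample_rate=config.sample_rate,
        provenance={"seed": config.seed, "config": config.digest(), "kind": "white-noise"},
    )


# ---------------------------------------------------------------------------
# envelopes

def smoothing_width(
    delta: float, c: float = 10.0, w_min: float = 0.05, w_max: float = 1.0
) -> float:
    """Map the loss-onset threshold jump to a filter transition width.

    The smoothing is inversely proportional to the onset delta — an abrupt
    loss onset gets a sharp band edge, a shallow onset a gentle one —
    clamped to [w_min, w_max] octaves.  ``delta`` is in dB; ``c`` carries
    units of dB·octave so c/delta is octaves.  A zero delta returns w_max.
    """
    if delta < 0:
        raise ValidationError("onset delta must be nonnegative")
    if delta == 0:
        return w_max
    return float(min(max(c / delta, w_min), w_max))


def _raised_cosine_band(
    f_lo: float,
    f_hi: float,
    w_lo: float,
    w_hi: float,
    floor_db: float,
    pass_gain: Callable[[np.ndarray], np.ndarray],
    n_pass: int = 129,
    n_trans: int = 65,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a band envelope: floor / raised-cosine rise / passband /
    raised-cosine fall / floor, on a log2-frequency grid."""
    if not (0 < f_lo < f_hi):
        raise ValidationError("band edges must satisfy 0 < f_lo < f_hi")
    l_lo, l_hi = math.log2(f_lo), math.log2(f_hi)

    # lower transition over [f_lo/2^w_lo, f_lo]
    x = np.linspace(0.0, 1.0, n_trans)
    lo_f = 2.0 ** (l_lo - w_lo * (1.0 - x))
    g_edge_lo = float(pass_gain(np.array([f_lo]))[0])
    lo_g = floor_db + 0.5 * (1.0 - np.cos(np.pi * x)) * (g_edge_lo - floor_db)

    pass_f = 2.0 ** np.linspace(l_lo, l_hi, n_pass)
    pass_g = np.asarray(pass_gain(pass_f), dtype=np.float64)

    hi_f = 2.0 ** (l_hi + w_hi * x)
    g_edge_hi = float(pass_gain(np.array([f_hi]))[0])
    hi_g = floor_db + 0.5 * (1.0 + np.cos(np.pi * x)) * (g_edge_hi - floor_db)

    f = np.concatenate([lo_f, pass_f[1:-1], hi_f])
    g = np.concatenate([lo_g, pass_g[1:-1], hi_g])
    # guard against numerically equal neighbors at the joins
    keep = np.concatenate([[True], np.diff(f) > 0])
    return f[keep], g[keep]


def envelope_v1(
    a: Audiogram,
    r: HearingLossRegion,
    w: float,
    *,
    floor_db: float = -60.0,
    normal_cutoff: float | None = None,
    flat: bool = False,
) -> SpectralEnvelope:
    """Loss-configuration envelope: passband over the hearing-loss region.

    In-band amplitude gain is proportional to the threshold excess over the
    normal cutoff (normalized so the passband maximum is 0 dB), so
    frequencies with deeper loss receive proportionally more energy; a flat
    0 dB passband is available with ``flat=True``.  Raised-cosine
    transitions of ``w`` octaves at both edges; the gain reaches the
    stopband floor outside [f_start/2^w, f_end·2^w].
    """
    if r.f_start >= r.f_end:
        raise ConfigurationError("degenerate hearing-loss region (single frequency)")
    cutoff = r.normal_cutoff if normal_cutoff is None else normal_cutoff

    if flat:
        def pass_gain(f):
            return np.zeros_like(np.asarray(f, dtype=np.float64))
    else:
        logf_k = np.log2(a.frequencies)
        thr_k = a.thresholds

        def pass_gain(f):
            f = np.asarray(f, dtype=np.float64)
            thr = np.interp(np.log2(f), logf_k, thr_k)
            excess = np.maximum(thr - cutoff, 1e-3)
            max_excess = max(float(thr_k.max()) - cutoff, 1e-3)
            return np.maximum(20.0 * np.log10(excess / max_excess), floor_db)

    f, g = _raised_cosine_band(r.f_start, r.f_end, w, w, floor_db, pass_gain)
    return SpectralEnvelope(f, g, passband=(r.f_start, r.f_end))


def envelope_v2(
    pitch: float,
    *,
    transition_octaves: float = PITCH_BAND_TRANSITION_OCTAVES,
    floor_db: float = -60.0,
) -> SpectralEnvelope:
    """Tinnitus-pitch emphasis envelope: unit band 10% below to 10% above
    the matched pitch, with fixed narrow raised-cosine edges."""
    f_lo = (1.0 - PITCH_BAND_FRACTION) * pitch
    f_hi = (1.0 + PITCH_BAND_FRACTION) * pitch

    def pass_gain(f):
        return np.zeros_like(np.asarray(f, dtype=np.float64))

    f, g = _raised_cosine_band(f_lo, f_hi, transition_octaves, transition_octaves, floor_db, pass_gain)
    return SpectralEnvelope(f, g, passband=(f_lo, f_hi))


def envelope_placebo(
    a: Audiogram,
    r: HearingLossRegion,
    *,
    w: float = 0.05,
    floor_db: float = -60.0,
) -> SpectralEnvelope:
    """Placebo envelope: flat band over the normal-hearing range below the
    loss onset, with the narrowest transition so no energy reaches the loss
    frequencies."""
    f_lo = a.span[0]
    f_hi = r.f_start
    if f_hi <= f_lo:
        raise ConfigurationError("no normal-hearing range below the loss onset")

    def pass_gain(f):
        return np.zeros_like(np.asarray(f, dtype=np.float64))

    f, g = _raised_cosine_band(f_lo, f_hi, w, w, floor_db, pass_gain)
    return SpectralEnvelope(f, g, passband=(f_lo, f_hi))


def apply_envelope(s: Signal, e: SpectralEnvelope) -> Signal:
    """Shape a signal's spectrum by the envelope (frequency-domain multiply).

    The real FFT of the signal is multiplied by the envelope's linear gain
    interpolated per bin and inverse-transformed; length is preserved.  The
    DC bin receives the envelope's low-frequency boundary gain.
    """
    n = len(s.samples)
    spec = np.fft.rfft(s.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / s.sample_rate)
    spec *= e.linear_gain(freqs)
    out = np.fft.irfft(spec, n=n)
    prov = dict(s.provenance)
    prov["envelope_passband"] = e.passband
    return Signal(samples=out, sample_rate=s.sample_rate, provenance=prov)


# ---------------------------------------------------------------------------
# stimuli

def synthesize_study(
    a: Audiogram, p: TinnitusProfile, config: SynthesisConfig
) -> Signal:
    """Build the study-group stimulus v3 = v1 + emphasized v2.

    v1 is noise shaped to the hearing-loss region (transition width from the
    onset delta); v2 is an independent noise in the pitch emphasis band,
    scaled so its in-band PSD sits ``emphasis_gain_db`` above v1's passband
    plateau — the combined spectrum therefore peaks at the tinnitus pitch.
    The result is RMS-normalized and peak-limited.  A pitch outside the loss
    region is recorded as a warning, not an error.
    """
    region = loss_region(a, config.normal_cutoff)
    try:
        delta = onset_delta(a, region)
    except ConfigurationError:
        # no measured normal frequency at all; fall back to the onset excess
        delta = region.onset_threshold - config.normal_cutoff
    w = smoothing_width(delta, config.smoothing_c, config.w_min, config.w_max)

    env1 = envelope_v1(
        a, region, w, floor_db=config.stopband_floor_db,
        normal_cutoff=config.normal_cutoff, flat=config.flat_v1,
    )
    env2 = envelope_v2(p.pitch, floor_db=config.stopband_floor_db)

    notes = []
    if not (region.f_start <= p.pitch <= region.f_end):
        msg = (
            f"tinnitus pitch {p.pitch} Hz lies outside the hearing-loss region "
            f"[{region.f_start}, {region.f_end}] Hz"
        )
        warnings.warn(msg)
        notes.append(msg)

    v1 = apply_envelope(gaussian_noise(config), env1)
    cfg2 = replace(config, seed=config.seed + 1)
    v2 = apply_envelope(gaussian_noise(cfg2), env2)
    # both carriers have the same pre-filter PSD and both envelopes peak at
    # 0 dB, so a fixed amplitude scale realizes the PSD emphasis exactly
    v2_scaled = v2.samples * 10.0 ** (config.emphasis_gain_db / 20.0)

    v3 = Signal(
        samples=v1.samples + v2_scaled,
        sample_rate=config.sample_rate,
        provenance={
            "seed": config.seed,
            "config": config.digest(),
            "kind": "study-v3",
            "loss_band_hz": (region.f_start, region.f_end),
            "emphasis_band_hz": env2.passband,
            "transition_octaves": w,
            "notes": notes,
        },
    )
    return normalize(v3, config.target_rms)


def synthesize_placebo(a: Audiogram, config: SynthesisConfig) -> Signal:
    """Build the placebo stimulus: noise confined to the normal-hearing
    range below the loss onset, flat in-band, narrowest smoothing.

    Raises if the audiogram has no hearing loss (there is then no frequency
    range to avoid) or no normal range below the loss onset.
    """
    region = loss_region(a, config.normal_cutoff)
    env = envelope_placebo(a, region, w=config.w_min, floor_db=config.stopband_floor_db)
    out = apply_envelope(gaussian_noise(config), env)
    out.provenance.update(
        {
            "seed": config.seed,
            "config": config.digest(),
            "kind": "placebo",
            "passband_hz": env.passband,
        }
    )
    return normalize(out, config.target_rms)


def normalize(s: Signal, target_rms: float) -> Signal:
    """Scale to the target RMS; if that would clip, scale to peak 0.999 and
    record the actual RMS in provenance."""
    rms = s.rms
    if len(s.samples) == 0 or rms == 0.0:
        raise ValidationError("cannot normalize an all-zero or empty signal")
    y = s.samples * (target_rms / rms)
    prov = dict(s.provenance)
    peak = np.max(np.abs(y))
    if peak > 1.0:
        y = y * (0.999 / peak)
        prov["peak_limited"] = True
    prov["actual_rms"] = float(np.sqrt(np.mean(np.square(y))))
    return Signal(samples=y, sample_rate=s.sample_rate, provenance=prov)


# ---------------------------------------------------------------------------
# I/O and verification

def write_wav(s: Signal, path) -> None:
    """Write mono 16-bit PCM WAV; read-back matches within one quantization
    step (1/32767)."""
    if len(s.samples) == 0:
        raise ValidationError("cannot write an empty signal")
    if s.peak > 1.0:
        raise ValidationError("samples exceed full scale; normalize first")
    pcm = np.round(s.samples * 32767.0).astype(np.int16)
    wavfile.write(path, s.sample_rate, pcm)


def read_wav(path) -> Signal:
    """Read a mono 16-bit PCM WAV back into a float Signal."""
    sr, pcm = wavfile.read(path)
    if pcm.ndim != 1:
        raise ValidationError("expected a mono WAV file")
    return Signal(samples=pcm.astype(np.float64) / 32767.0, sample_rate=int(sr))


def spectrum_report(
    s: Signal,
    passband_hint: tuple[float, float],
    *,
    nperseg: int = 8192,
    oob_margin_octaves: float = 0.5,
) -> SpectrumReport:
    """Verify a stimulus spectrum with an averaged periodogram.

    Welch PSD (Hann window, 50% overlap); the peak frequency is the argmax
    of the lightly smoothed PSD; band edges are the outermost bins within
    3 dB of the passband median; rejection is measured against the loudest
    bin outside the hinted band expanded by ``oob_margin_octaves`` (to skip
    the filter transitions).
    """
    if s.duration < 1.0:
        raise ValidationError("need at least 1 s of signal for a spectrum report")
    f_lo, f_hi = passband_hint
    # detrend=False: the stimuli are zero-mean by construction, and mean
    # removal pollutes the two lowest PSD bins through the analysis window
    freqs, psd = sps.welch(
        s.samples, fs=s.sample_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False,
    )
    psd_db = 10.0 * np.log10(psd + 1e-30)

    kernel = np.ones(5) / 5.0
    smoothed = np.convolve(psd, kernel, mode="same")
    pos = freqs > 0
    peak_frequency = float(freqs[pos][np.argmax(smoothed[pos])])

    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not in_band.any():
        raise ValidationError("passband hint contains no PSD bins")
    band_median = float(np.median(psd_db[in_band]))
    hot = psd_db >= band_median - 3.0
    hot_freqs = freqs[hot & pos]
    band_edges = (float(hot_freqs.min()), float(hot_freqs.max()))

    margin = 2.0 ** oob_margin_octaves
    oob = pos & ((freqs < f_lo / margin) | (freqs > f_hi * margin))
    rejection = band_median - float(psd_db[oob].max()) if oob.any() else math.inf

    return SpectrumReport(
        frequencies_hz=freqs,
        psd_db=psd_db,
        peak_frequency=peak_frequency,
        band_edges=band_edges,
        out_of_band_rejection=rejection,
    )


def plot_spectrum(report: SpectrumReport, path, title: str = "Stimulus spectrum") -> None:
    """Save a PSD plot (PNG) for visual verification of a stimulus."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    pos = report.frequencies_hz > 0
    ax.semilogx(report.frequencies_hz[pos], report.psd_db[pos], lw=0.8)
    ax.axvline(report.peak_frequency, color="r", ls="--", lw=0.8, label=f"peak {report.peak_frequency:.0f} Hz")
    for edge in report.band_edges:
        ax.axvline(edge, color="g", ls=":", lw=0.8)
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("PSD (dB)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
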