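"""Synthesize the placebo variant for the same sloping audiogram.

The placebo sound occupies only the normal-hearing range below the loss
onset (here 125-1000 Hz) with the narrowest transition, so none of its
energy reaches the frequencies where the patient has hearing loss.
"""

from pathlib import Path

from tinnisynth import Audiogram, SynthesisConfig, spectrum_report, synthesize_placebo, write_wav

audiogram = Audiogram("right", [
    (125, 5), (250, 5), (500, 10), (1000, 20), (2000, 35),
    (3000, 45), (4000, 50), (6000, 60), (8000, 65),
])

sound = synthesize_placebo(audiogram, SynthesisConfig(seed=42, duration=60.0))

outdir = Path("scratch")
outdir.mkdir(exist_ok=True)
write_wav(sound, outdir / "placebo.wav")

report = spectrum_report(sound, sound.provenance["passband_hz"])
lo, hi = sound.provenance["passband_hz"]
print(f"passband         : {lo:.0f}-{hi:.0f} Hz")
print(f"band edges (-3dB): {report.band_edges[0]:.0f}-{report.band_edges[1]:.0f} Hz")
print(f"OOB rejection    : {report.out_of_band_rejection:.1f} dB")
# The upper edge sits at the loss onset (1 kHz): the placebo deliberately
# avoids stimulating the deprived frequency region.
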