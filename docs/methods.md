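# Methods

## Scope and model

`tinnisynth` implements a sound-enrichment treatment pipeline for tinnitus
whose working hypothesis is cochlear: tinnitus generated by sensorineural
hearing loss, localized (per the discordant outer/inner hair-cell damage
model) where the hearing threshold is about 45–55 dB HL. The pipeline has
four computational parts — audiogram interrogation, eligibility screening,
stimulus synthesis, and dosing — plus a fixture generator that stands in
for patient data. Counseling content, questionnaire instruments (THI/VAS),
clinical outcome statistics, and absolute acoustic calibration of digital
amplitude to dB HL on a specific transducer are out of scope; the digital
RMS is a normalization constant only, and presentation level is prescribed
in dB HL anchors that the playback device realizes.

## Audiogram model

An audiogram is a strictly increasing ladder of (frequency, threshold)
points per ear, 125 Hz–20 kHz, −10…120 dB HL. Thresholds between measured
frequencies are interpolated **linearly in log2-frequency**, the
audiometric convention (the ladder is octave-spaced and clinical judgments
are per octave); no extrapolation outside the measured span. The
hearing-loss region is the closed interval from the lowest to the highest
measured frequency whose threshold exceeds the normal cutoff (15 dB HL,
configurable). The *onset delta* Δ is |threshold(onset) −
threshold(adjacent normal)| where the adjacent-normal frequency is the
measured frequency nearest the onset in octaves, in either direction, with
a threshold ≤ cutoff. Taking the nearest normal neighbor regardless of
direction is a deliberate design choice: for a sloping high-frequency loss
the nearest normal point is almost always the frequency just below the
onset, and the rule remains well-defined for unusual configurations. When
no normal point exists at all, synthesis falls back to Δ = onset threshold
− cutoff.

## Eligibility rules

A candidate is eligible iff all of: no organic finding; threshold at the
matched pitch within the **closed** window [45, 55] dB HL; residual
inhibition positive; every measured threshold ≤ 90 dB HL (the exclusion is
strict: 91 excludes, 90 does not); duration strictly > 6 months; tonal
tinnitus; and a nonempty hearing-loss region. `check_eligibility` returns
*all* violated criteria; cohort tallies attribute each exclusion to the
first violated criterion in the clinical work-up order (organic →
pitch-threshold → RI → profound → chronicity → tonality → no-loss), so that
counts conserve: admitted = included + Σ excluded. Laterality only decides
whether masking/RI noise is presented binaurally; it never affects
eligibility. Randomization into study/placebo groups is a seeded
permutation split at round(ratio·n); the allocation mechanism is a design
choice (the protocol itself only requires reproducible random assignment),
and input order cannot affect it because ids are canonically sorted before
permutation.

Assessment constants: pitch matching with contralateral tones at 30 dB SL,
5 dB audiometer steps for TLL and MML, RI probe = narrowband noise at
MML + 10 dB for 60 s.

## Stimulus synthesis

**Carrier.** Seeded zero-mean Gaussian noise, 44 100 Hz, scaled to a
pre-filter RMS of `target_rms` (default 0.1 ≈ −20 dBFS, leaving headroom
for the emphasis band before peak-limiting). Default duration 60 s per
file, intended for looped playback on the patient's phone.

**Filtering.** All band-limiting is frequency-domain: the real FFT of the
carrier is multiplied by a spectral envelope sampled per bin and inverse
transformed. Envelopes are piecewise curves in (log2-frequency, dB)
interpolated linearly, with raised-cosine transitions and a stopband floor
of −60 dB re the passband maximum. This gives exact, verifiable band edges
and no passband ripple; the trade-off (relative to a causal IIR/FIR
realization) is that the result is a fixed-length file, which matches the
delivery format.

**Smoothing.** The transition width in octaves is `w = clamp(c/Δ, w_min,
w_max)` with c = 10 dB·octave, w_min = 0.05, w_max = 1.0: inversely
proportional to the onset delta, so an abrupt loss edge produces a sharp
spectral edge and a shallow slope a gradual one. Only the inverse
proportionality is dictated by the protocol; the constants are package
defaults, configurable in `SynthesisConfig`. Δ = 0 maps to w_max.

**v1 (loss-configuration sound).** Passband = the hearing-loss region.
In-band *amplitude* gain is proportional to the threshold excess,
`g(f) = (HL(f) − cutoff) / max_excess`, i.e. `20·log10` of that ratio in
dB, normalized so the passband maximum is 0 dB — deeper loss receives
proportionally more energy, and a flat loss yields an exactly flat 0 dB
passband. A flat passband for arbitrary audiograms is available behind
`SynthesisConfig(flat_v1=True)` for users who prefer uniform enrichment.

**v2 (pitch emphasis).** Unit passband exactly [0.9, 1.1]·pitch with fixed
narrow 0.02-octave raised-cosine edges (the band is a therapeutic target,
not a loss contour, so its edges do not depend on the audiogram).

**v3 (study sound).** v1 and v2 use *independent* carriers with seeds
(seed, seed + 1) derived from the master seed. Because both carriers share
the same pre-filter PSD and both envelopes peak at 0 dB, scaling v2 by
`10^(emphasis/20)` realizes the configured PSD emphasis (+6 dB default)
exactly, analytically, with no empirical calibration step. The mix ratio is
a package default: the protocol specifies only that the combined spectrum
must peak at the tinnitus pitch, which any positive emphasis guarantees
(verified spectrally in the test suite). The sum is RMS-normalized; if
normalization would clip, the signal is rescaled to peak 0.999 and the
achieved RMS recorded in provenance. A pitch outside the loss region is a
recorded warning, not an error — the stimulus is still well-defined.

**Placebo.** Flat passband from the lowest measured frequency up to the
loss onset, transition width w_min, so the deprived region receives no
stimulation. Requires both a loss region (otherwise there is nothing to
avoid) and a normal range below it.

**Output.** Mono 16-bit PCM WAV; read-back agrees within one quantization
step. Identical (audiogram, profile, config) produce bitwise-identical
samples and WAV bytes.

## Spectral verification

`spectrum_report` uses an averaged periodogram (Welch: 8192-sample
segments, 50% overlap, Hann window, `detrend=False`). Detrending is
disabled deliberately: the stimuli are zero-mean by construction, and
per-segment mean removal interacts with the analysis window to pollute the
two lowest PSD bins by tens of dB, which would corrupt the stopband
measurement. The peak frequency is the argmax of the PSD smoothed with a
5-bin moving average (suppressing single-bin noise spikes); band edges are
the outermost bins within 3 dB of the in-band median; out-of-band rejection
is the in-band median minus the loudest bin outside the hinted band
expanded by a margin (default 0.5 octave). The margin must cover the
raised-cosine transition — the stopband only begins one transition width
past the band edge — so callers verifying a study sound with a wide
transition pass `oob_margin_octaves = max(w, 0.5)`, with w read from the
signal's provenance.

## Fixture generator

The generator emulates the population the protocol targets: sloping
high-frequency sensorineural audiograms (near 8 dB HL below the onset,
rising from 20 dB HL at the onset at a configurable slope, default
15 dB/octave from 1 kHz, capped at 90 dB HL), whose slope makes some
measured frequency land in the 45–55 dB HL window; profiles whose pitch
sits at such a frequency, with TLL 5–15 dB above the pitch threshold, MML
at or one step below TLL, chronic tonal tinnitus, and laterality drawn
25/25/50% (right/left/bilateral). Threshold jitter is uniform ±3 dB,
bounded so no construction can cross a criterion boundary (the pitch
threshold is centered at 50 inside [45, 55]; profound fixtures center the
top frequency at 95 > 90 + 3). Cohorts are built per category — eligible,
organic, pitch-out (pitch at a normal-hearing frequency), RI-negative,
profound — each violating exactly its defining criterion, shuffled under
the seed. The default composition is 96/6/11/10/4 (127 admitted).

What the fixtures do **not** emulate: measurement noise and test–retest
variability in audiometry and pitch matching, octave confusion in pitch
matching, non-sloping (flat, notched, low-frequency) loss configurations,
multi-criterion failures, and any longitudinal treatment response. Passing
tests therefore demonstrate the correctness of the rules, arithmetic and
synthesis on protocol-conformant inputs, not robustness to messy clinical
measurements.

## Dosing

Three contiguous phases over [0, 6] months: 6 h/day at TLL + step (upper
bound is patient comfort, a device-side instruction not modeled
numerically), 3 h/day at MML + step, 2 h/day at TLL − step, with step = the
5 dB audiometer minimum. Quantifying "just above / just below" as one
instrument step is a package decision; the protocol states only the
direction. Daily hours strictly decrease, and anchors are nonincreasing
whenever MML is within two steps of TLL (clinically MML ≤ TLL and close to
it). Adherence logs map days to phases at 30 days/month.

## Problem sizes and numerical notes

The test suite synthesizes at 6 s (≈32 Welch segments, enough for ±0.5 dB
band-power statistics) and checks carrier moments at the full 60 s delivery
duration; the acceptance script synthesizes 8 s of placebo audio. Spectral
property tests use five synthetic patients spanning loss onsets 500–2000 Hz
and slopes 15–25 dB/octave. Band-edge equality tests are exact (the edges
are configured, not estimated); estimated quantities use bin-width
(44100/8192 ≈ 5.4 Hz) or statistical tolerances stated per test.
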