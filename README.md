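# tinnisynth

Audiogram-driven synthesis of individualized **sound-enrichment therapy
stimuli** for hearing-loss-related tinnitus, together with the
psychoacoustic **eligibility screening** that selects candidates whose
tinnitus is plausibly generated by cochlear hearing loss, the phased
six-month **dosing schedule**, and **spectral verification** of every
generated sound.

## Who this is for

Audiology researchers and clinicians who want to generate, verify and
administer personalized band-pass noise stimuli for tinnitus sound therapy,
and to reproduce the screening arithmetic of a placebo-controlled
sound-enrichment protocol without any patient-level data (a built-in
fixture generator emulates realistic cohorts).

## The method

Under the discordant-damage model, tinnitus of cochlear origin arises where
outer-hair-cell damage maximally exceeds inner-hair-cell damage —
empirically a hearing threshold of ≈45–55 dB HL at the tinnitus frequency.
A candidate is **eligible** when the threshold at their matched tinnitus
pitch `f_t` satisfies `45 ≤ HL(f_t) ≤ 55` dB, residual inhibition is
positive (tinnitus decreases after 60 s of narrowband noise at MML + 10 dB),
no threshold exceeds 90 dB HL, no organic cause was found, and the tinnitus
is tonal and chronic (> 6 months).

The **study stimulus** starts from seeded Gaussian white noise at 44.1 kHz
and is shaped in the frequency domain:

* `v1` — noise band-passed to the hearing-loss region `[f_start, f_end]`
  (thresholds > 15 dB HL), in-band amplitude gain proportional to the
  threshold excess `HL(f) − 15`, raised-cosine edges of width
  `w = clamp(10/Δ, 0.05, 1)` octaves where `Δ` is the threshold jump at the
  loss onset (abrupt onset → sharp edge);
* `v2` — independent noise in the pitch emphasis band
  `[0.9·f_t, 1.1·f_t]`, mixed +6 dB above v1's passband plateau;
* `v3 = v1 + v2`, RMS-normalized — its spectrum peaks at the tinnitus pitch.

The **placebo stimulus** is the complement: noise confined to the
normal-hearing range below the loss onset, so the deprived frequency region
receives no stimulation. Dosing de-escalates over six months: 6 h/day above
the tinnitus loudness level (TLL), then 3 h/day just above the minimum
masking level (MML), then 2 h/day just below the TLL.

## Worked example

`examples/synthesize_study_sound.py` builds the stimulus for a patient with
sloping loss from 1–8 kHz and a 4 kHz tinnitus pitch:

```
loss region      : 1000-8000 Hz
emphasis band    : 3600-4400 Hz
PSD peak         : 4221 Hz
band edges (-3dB): 2929-9022 Hz
OOB rejection    : 51.1 dB
wrote            : scratch/study_4khz.wav (60 s @ 44100 Hz)
```

The emphasis band is 10% either side of the 4 kHz pitch; the Welch-PSD peak
(4221 Hz) falls inside it, and energy outside the loss band is suppressed by
51 dB. `examples/screen_cohort.py` screens a 127-candidate synthetic intake:

```
admitted : 127
excluded :   6  ORGANIC
excluded :  11  PITCH_THRESHOLD_OUT_OF_RANGE
excluded :  10  RI_NEGATIVE
excluded :   4  PROFOUND_LOSS
included : 96
study group  : 52 participants
placebo group: 44 participants
```

See also `examples/synthesize_placebo_sound.py` and
`examples/dosing_plan.py`. The same workflow is available from the shell:

```bash
tinnisynth fixtures --outdir cohort/
tinnisynth screen  --cohort cohort/cohort.csv --out flow.json
tinnisynth synth   --audiogram a.csv --profile p.json --group study --seed 42 --out sound.wav
tinnisynth verify  --wav sound.wav --audiogram a.csv --pitch 4000 --report report.json
tinnisynth plan    --profile p.json --out plan.json
```

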