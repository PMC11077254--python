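"""Synthetic audiograms, tinnitus profiles and screening cohorts.

No patient-level data ship with the protocol, so every part of the toolkit
is exercised against generated fixtures that reproduce the structure the
protocol assumes: sloping high-frequency sensorineural audiograms whose
45–55 dB HL region contains the tinnitus pitch, profiles that satisfy (or
deliberately violate exactly one of) the eligibility criteria, and whole
cohorts with prescribed exclusion-category counts.

Generation is deterministic under the fixture seed, and the ±3 dB threshold
jitter is bounded so a record's screening category can never flip: every
construction keeps at least a 3 dB margin to the criterion boundaries
(e.g. the pitch-frequency threshold is centered at 50 dB HL inside the
[45, 55] window, profound thresholds at 95 dB HL above the 90 dB cutoff).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audiogram import (
    NORMAL_CUTOFF_DB_HL,
    STANDARD_FREQUENCIES_HZ,
    EXTENDED_FREQUENCIES_HZ,
    Audiogram,
    Ear,
    threshold_at,
)
from .errors import ConfigurationError, ValidationError
from .screening import (
    PITCH_THRESHOLD_WINDOW_DB_HL,
    Laterality,
    RIOutcome,
    TinnitusProfile,
)

#: Default screening-cohort composition: category -> record count.  The
#: defaults reproduce a 127-candidate intake in which 6 are excluded for
#: organic findings, 11 for a pitch-frequency threshold outside 45–55 dB HL,
#: 10 for negative residual inhibition and 4 for profound loss, leaving 96.
DEFAULT_COHORT_COUNTS = {
    "eligible": 96,
    "organic": 6,
    "pitch_out": 11,
    "ri_negative": 10,
    "profound": 4,
}

_CATEGORIES = tuple(DEFAULT_COHORT_COUNTS)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic population.

    loss_onset_hz : frequency where hearing loss begins; slope_db_per_octave
    : how fast thresholds rise above the onset; pitch_quantile : where along
    the qualifying (45–55 dB HL) frequencies the tinnitus pitch is placed;
    jitter_db : half-width of the uniform threshold jitter;
    cohort_counts : records per screening category.
    """

    loss_onset_hz: float = 1000.0
    slope_db_per_octave: float = 15.0
    pitch_quantile: float = 0.5
    seed: int = 0
    jitter_db: float = 3.0
    extended_ladder: bool = False
    cohort_counts: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_COUNTS))

    def __post_init__(self):
        if self.slope_db_per_octave < 0:
            raise ValidationError("slope must be nonnegative")
        if not (0.0 <= self.pitch_quantile <= 1.0):
            raise ValidationError("pitch_quantile must be in [0, 1]")
        if self.jitter_db < 0:
            raise ValidationError("jitter must be nonnegative")
        unknown = set(self.cohort_counts) - set(_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown cohort categories: {sorted(unknown)}")
        if any(n < 0 for n in self.cohort_counts.values()):
            raise ValidationError("cohort counts must be nonnegative")

    @property
    def ladder(self) -> tuple[float, ...]:
        return EXTENDED_FREQUENCIES_HZ if self.extended_ladder else STANDARD_FREQUENCIES_HZ


@dataclass(frozen=True)
class CohortRecord:
    record_id: str
    profile: TinnitusProfile
    audiogram: Audiogram
    organic_flag: bool
    category: str

    def as_screen_input(self) -> tuple[TinnitusProfile, Audiogram, bool]:
        return (self.profile, self.audiogram, self.organic_flag)


def gen_audiogram(
    spec: FixtureSpec,
    *,
    profound: bool = False,
    ear: Ear | str = Ear.RIGHT,
    rng: np.random.Generator | None = None,
) -> Audiogram:
    """Generate a sloping high-frequency sensorineural audiogram.

    Thresholds below the loss onset sit near 8 dB HL (always ≤ 15 dB HL);
    from the onset they start at 20 dB HL and rise at the configured slope,
    capped at 90 dB HL unless ``profound``, which instead places the highest
    measured frequency near 95 dB HL.  Jitter is uniform ±``jitter_db``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    freqs = np.array(spec.ladder)
    jit = rng.uniform(-spec.jitter_db, spec.jitter_db, size=len(freqs))
    thr = np.where(
        freqs < spec.loss_onset_hz,
        8.0,
        20.0 + spec.slope_db_per_octave * np.log2(np.maximum(freqs, 1.0) / spec.loss_onset_hz),
    )
    thr = thr + jit
    below = freqs < spec.loss_onset_hz
    thr[below] = np.minimum(thr[below], NORMAL_CUTOFF_DB_HL)
    thr[~below] = np.clip(thr[~below], NORMAL_CUTOFF_DB_HL + 2.0, 90.0)
    if profound:
        thr[-1] = 95.0 + float(rng.uniform(-spec.jitter_db, spec.jitter_db))
    return Audiogram(ear, list(zip(freqs, np.round(thr, 1))))


def _qualifying_frequencies(a: Audiogram) -> np.ndarray:
    lo, hi = PITCH_THRESHOLD_WINDOW_DB_HL
    mask = (a.thresholds >= lo) & (a.thresholds <= hi)
    return a.frequencies[mask]


def gen_profile(
    a: Audiogram,
    spec: FixtureSpec,
    *,
    ri_negative: bool = False,
    pitch_out: bool = False,
    rng: np.random.Generator | None = None,
) -> TinnitusProfile:
    """Generate a tinnitus profile consistent with the audiogram.

    The pitch is placed at a measured frequency whose threshold lies in the
    45–55 dB HL window, chosen by ``pitch_quantile`` among the qualifying
    frequencies (with ``pitch_out`` it is instead placed at the lowest
    measured — normal-hearing — frequency).  TLL is the pitch-frequency
    threshold plus 5/10/15 dB; MML is at or one step below the TLL; the
    tinnitus is tonal and chronic.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    if pitch_out:
        pitch = float(a.frequencies[0])
    else:
        qualifying = _qualifying_frequencies(a)
        if qualifying.size == 0:
            raise ConfigurationError(
                "audiogram has no measured frequency with threshold in the 45-55 dB HL window"
            )
        idx = int(round(spec.pitch_quantile * (qualifying.size - 1)))
        pitch = float(qualifying[idx])
    thr = threshold_at(a, pitch)
    tll = min(thr + float(rng.choice([5.0, 10.0, 15.0])), 120.0)
    mml = tll - float(rng.choice([0.0, 5.0]))
    sides = (Laterality.RIGHT, Laterality.LEFT, Laterality.BILATERAL_OR_HEAD)
    laterality = sides[int(rng.choice(3, p=[0.25, 0.25, 0.5]))]
    return TinnitusProfile(
        laterality=laterality,
        pitch=pitch,
        tll=tll,
        mml=mml,
        ri=RIOutcome.NEGATIVE if ri_negative else RIOutcome.POSITIVE,
        duration_months=float(rng.integers(12, 49)),
        tonal=True,
    )


def gen_cohort(spec: FixtureSpec) -> list[CohortRecord]:
    """Generate a screening cohort with the prescribed category counts.

    Each record violates at most the single criterion defining its
    category; records are shuffled under the fixture seed and given
    sequential ids after shuffling.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple] = []
    for category in _CATEGORIES:
        for _ in range(int(spec.cohort_counts.get(category, 0))):
            a = gen_audiogram(spec, profound=(category == "profound"), rng=rng)
            p = gen_profile(
                a,
                spec,
                ri_negative=(category == "ri_negative"),
                pitch_out=(category == "pitch_out"),
                rng=rng,
            )
            records.append((p, a, category == "organic", category))
    rng.shuffle(records)
    return [
        CohortRecord(
            record_id=f"P{i + 1:03d}",
            profile=p,
            audiogram=a,
            organic_flag=organic,
            category=category,
        )
        for i, (p, a, organic, category) in enumerate(records)
    ]


# ---------------------------------------------------------------------------
# cohort interchange (CSV + per-record audiogram CSVs / profile JSONs)

def write_cohort(records: list[CohortRecord], outdir) -> Path:
    """Write a cohort to ``outdir``: one audiogram CSV and profile JSON per
    record plus a ``cohort.csv`` index.  Returns the cohort CSV path."""
    from .audiogram import write_audiogram

    outdir = Path(outdir)
    (outdir / "audiograms").mkdir(parents=True, exist_ok=True)
    (outdir / "profiles").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        agram_file = f"audiograms/{rec.record_id}.csv"
        write_audiogram(rec.audiogram, outdir / agram_file)
        with open(outdir / "profiles" / f"{rec.record_id}.json", "w") as fh:
            json.dump(rec.profile.to_dict(), fh, indent=2)
        rows.append(
            {
                "record_id": rec.record_id,
                **rec.profile.to_dict(),
                "organic_flag": rec.organic_flag,
                "audiogram_file": agram_file,
            }
        )
    path = outdir / "cohort.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cohort(cohort_csv) -> list[CohortRecord]:
    """Read a cohort written by :func:`write_cohort`; audiogram paths are
    resolved relative to the cohort CSV."""
    from .audiogram import read_audiogram

    cohort_csv = Path(cohort_csv)
    df = pd.read_csv(cohort_csv)
    records = []
    for _, row in df.iterrows():
        profile = TinnitusProfile(
            laterality=row["laterality"],
            pitch=row["pitch_hz"],
            tll=row["tll_db_hl"],
            mml=row["mml_db_hl"],
            ri=row["ri"],
            duration_months=row["duration_months"],
            tonal=bool(row["tonal"]),
        )
        audiogram = read_audiogram(cohort_csv.parent / row["audiogram_file"])
        records.append(
            CohortRecord(
                record_id=str(row["record_id"]),
                profile=profile,
                audiogram=audiogram,
                organic_flag=bool(row["organic_flag"]),
                category=str(row.get("category", "")),
            )
        )
    return records
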