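"""Pure-tone audiograms and hearing-loss-region extraction.

An audiogram is an ordered list of (frequency in Hz, threshold in dB HL)
points per ear, measured on the standard audiometric ladder (125 Hz – 8 kHz,
extendable to 20 kHz with high-frequency headphones).  The therapy-sound
pipeline needs three queries on it:

* the threshold at an arbitrary frequency (the matched tinnitus pitch rarely
  falls exactly on a measured frequency) — interpolated linearly in
  log2-frequency, the audiometric convention, since the ladder is
  octave-spaced and clinical charts are drawn per octave;
* the hearing-loss region: the closed frequency interval spanning every
  measured point whose threshold exceeds the normal-hearing cutoff
  (15 dB HL by default);
* the onset delta: how abruptly the loss begins, i.e. the threshold jump
  between the loss-onset frequency and the nearest measured frequency with a
  normal threshold.  This drives the spectral smoothing of the therapy sound
  (steep onset -> narrow filter transition, shallow onset -> wide).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AudiogramParseError,
    ConfigurationError,
    DomainError,
    NoHearingLossError,
    ValidationError,
)

#: Default normal-hearing cutoff in dB HL; thresholds at or below this are
#: considered normal, above it hearing loss.
NORMAL_CUTOFF_DB_HL = 15.0

#: Standard audiometric frequency ladder (Hz), conventional octave/half-octave
#: steps used by clinical audiometers up to 8 kHz.
STANDARD_FREQUENCIES_HZ = (125.0, 250.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0, 6000.0, 8000.0)

#: Extended high-frequency ladder (Hz) reachable with circumaural HF headphones.
EXTENDED_FREQUENCIES_HZ = STANDARD_FREQUENCIES_HZ + (10000.0, 12500.0, 16000.0, 20000.0)

FREQ_MIN_HZ = 125.0
FREQ_MAX_HZ = 20000.0
THRESHOLD_MIN_DB = -10.0
THRESHOLD_MAX_DB = 120.0


class Ear(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BINAURAL_MEAN = "binaural-mean"


@dataclass(frozen=True)
class Audiogram:
    """Per-ear pure-tone thresholds, ordered by frequency.

    Parameters
    ----------
    ear : Ear
        Which ear (or the binaural mean) the thresholds describe.
    points : sequence of (float, float)
        ``(frequency_hz, threshold_db_hl)`` pairs.  Frequencies must be
        strictly increasing within 125–20 000 Hz; thresholds within
        −10…120 dB HL; at least two points.
    """

    ear: Ear
    points: tuple[tuple[float, float], ...]

    def __init__(self, ear: Ear | str, points: Sequence[tuple[float, float]]):
        object.__setattr__(self, "ear", Ear(ear))
        pts = tuple((float(f), float(t)) for f, t in points)
        if len(pts) < 2:
            raise ValidationError("audiogram needs at least 2 points")
        freqs = [f for f, _ in pts]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValidationError("frequencies must be strictly increasing (no duplicates)")
        for f, t in pts:
            if not (FREQ_MIN_HZ <= f <= FREQ_MAX_HZ):
                raise ValidationError(f"frequency {f} Hz outside {FREQ_MIN_HZ}-{FREQ_MAX_HZ} Hz")
            if not (THRESHOLD_MIN_DB <= t <= THRESHOLD_MAX_DB):
                raise ValidationError(
                    f"threshold {t} dB HL outside {THRESHOLD_MIN_DB}-{THRESHOLD_MAX_DB} dB HL"
                )
        object.__setattr__(self, "points", pts)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for f, _ in self.points])

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([t for _, t in self.points])

    @property
    def span(self) -> tuple[float, float]:
        """(lowest, highest) measured frequency in Hz."""
        return self.points[0][0], self.points[-1][0]

    def max_threshold(self) -> float:
        return float(self.thresholds.max())


@dataclass(frozen=True)
class HearingLossRegion:
    """Closed frequency interval [f_start, f_end] of measured hearing loss.

    ``f_start`` is the lowest measured frequency whose threshold exceeds the
    normal cutoff, ``f_end`` the highest.  ``adjacent_normal_threshold`` is
    the threshold at the measured frequency nearest the onset (in octaves,
    either direction) that is still normal; ``None`` when the audiogram has
    no normal point at all.
    """

    f_start: float
    f_end: float
    onset_threshold: float
    adjacent_normal_threshold: float | None
    adjacent_normal_frequency: float | None = None
    normal_cutoff: float = NORMAL_CUTOFF_DB_HL

    def __post_init__(self):
        if not self.f_start <= self.f_end:
            raise ValidationError("f_start must be <= f_end")
        if self.onset_threshold <= self.normal_cutoff:
            raise ValidationError("onset threshold must exceed the normal cutoff")
        if (
            self.adjacent_normal_threshold is not None
            and self.adjacent_normal_threshold > self.normal_cutoff
        ):
            raise ValidationError("adjacent-normal threshold must be <= the normal cutoff")


def read_audiogram(source, ear: Ear | str | None = None) -> Audiogram:
    """Read an audiogram from CSV with columns ``ear,frequency_hz,threshold_db_hl``.

    ``source`` may be a path or an open text buffer.  If the file contains
    several ears, ``ear`` selects one; with a single ear it may be omitted.
    Rows are validated (range checks, duplicate frequencies) and returned
    sorted by frequency.
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AudiogramParseError(f"cannot parse audiogram CSV: {exc}") from exc
    required = {"ear", "frequency_hz", "threshold_db_hl"}
    missing = required - set(df.columns)
    if missing:
        raise AudiogramParseError(f"missing columns: {sorted(missing)}")
    for col in ("frequency_hz", "threshold_db_hl"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based + header
            raise AudiogramParseError(f"malformed value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    if df[["frequency_hz", "threshold_db_hl"]].isna().any().any():
        raise AudiogramParseError("empty numeric cell in audiogram CSV")

    ears = df["ear"].unique().tolist()
    if ear is None:
        if len(ears) != 1:
            raise AudiogramParseError(
                f"file contains ears {ears}; pass ear= to select one"
            )
        ear = ears[0]
    sel = df[df["ear"] == (ear.value if isinstance(ear, Ear) else ear)]
    if sel.empty:
        raise AudiogramParseError(f"no rows for ear {ear!r}")
    if sel["frequency_hz"].duplicated().any():
        dup = sel.loc[sel["frequency_hz"].duplicated(), "frequency_hz"].iloc[0]
        raise ValidationError(f"duplicate frequency {dup} Hz for ear {ear!r}")
    sel = sel.sort_values("frequency_hz")
    return Audiogram(ear, list(zip(sel["frequency_hz"], sel["threshold_db_hl"])))


def write_audiogram(a: Audiogram, path) -> None:
    """Write an audiogram back to the CSV interchange format."""
    df = pd.DataFrame(
        {
            "ear": a.ear.value,
            "frequency_hz": a.frequencies,
            "threshold_db_hl": a.thresholds,
        }
    )
    df.to_csv(path, index=False)


def threshold_at(a: Audiogram, f: float) -> float:
    """Hearing threshold (dB HL) at frequency ``f``.

    Exact at measured frequencies; between them, linear interpolation in
    log2-frequency.  Raises :class:`DomainError` outside the measured span —
    audiometric thresholds are not extrapolated.
    """
    lo, hi = a.span
    if not (lo <= f <= hi):
        raise DomainError(f"frequency {f} Hz outside measured span [{lo}, {hi}] Hz")
    return float(np.interp(math.log2(f), np.log2(a.frequencies), a.thresholds))


def loss_region(a: Audiogram, normal_cutoff: float = NORMAL_CUTOFF_DB_HL) -> HearingLossRegion:
    """Locate the hearing-loss region of an audiogram.

    The region spans the lowest to the highest measured frequency whose
    threshold exceeds ``normal_cutoff``.  Raises :class:`NoHearingLossError`
    if every threshold is normal.
    """
    freqs, thrs = a.frequencies, a.thresholds
    above = thrs > normal_cutoff
    if not above.any():
        raise NoHearingLossError(
            f"no threshold exceeds the normal cutoff of {normal_cutoff} dB HL"
        )
    idx = np.flatnonzero(above)
    i_start = int(idx[0])
    f_start, f_end = float(freqs[i_start]), float(freqs[int(idx[-1])])
    normal_idx = np.flatnonzero(~above)
    if normal_idx.size:
        # nearest normal point to the onset, measured in octaves either side
        dist = np.abs(np.log2(freqs[normal_idx] / f_start))
        j = int(normal_idx[int(np.argmin(dist))])
        adj_thr, adj_freq = float(thrs[j]), float(freqs[j])
    else:
        adj_thr = adj_freq = None
    return HearingLossRegion(
        f_start=f_start,
        f_end=f_end,
        onset_threshold=float(thrs[i_start]),
        adjacent_normal_threshold=adj_thr,
        adjacent_normal_frequency=adj_freq,
        normal_cutoff=normal_cutoff,
    )


def onset_delta(a: Audiogram, r: HearingLossRegion) -> float:
    """Threshold jump (dB) at the loss onset.

    The absolute difference between the threshold where the loss starts and
    the threshold at the nearest measured frequency with a normal threshold.
    Large delta = abrupt onset; it maps to a narrow filter transition in the
    therapy-sound envelope.  Raises :class:`ConfigurationError` when the
    audiogram has no normal point to compare against.
    """
    if r.adjacent_normal_threshold is None:
        raise ConfigurationError(
            "no measured frequency with a normal threshold adjacent to the loss onset"
        )
    return abs(r.onset_threshold - r.adjacent_normal_threshold)
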