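"""Eligibility screening for hearing-loss-related tinnitus.

The protocol targets patients whose tinnitus is most plausibly generated by
cochlear hearing loss.  Under the discordant-damage model, that corresponds
to a hearing threshold of roughly 45–55 dB HL at the tinnitus frequency, so
a candidate is eligible only when

* no organic cause (middle-ear pathology, demyelinating disease, brain
  lesion, ...) was found on medical work-up,
* the audiometric threshold at the matched tinnitus pitch lies in the
  45–55 dB HL window,
* residual inhibition (RI) is positive — tinnitus transiently decreases
  after 60 s of narrowband noise 10 dB above the minimum masking level,
* no measured threshold exceeds 90 dB HL (profound loss would defeat
  acoustic stimulation),
* the tinnitus is chronic (> 6 months) and tonal, and
* the audiogram actually shows a hearing-loss region.

Cohort screening tallies each excluded record under exactly one reason, the
first triggered in the clinical work-up order (organic → pitch-threshold →
RI → profound loss), so exclusion counts add up to admitted − included.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .audiogram import Audiogram, loss_region, threshold_at
from .errors import DomainError, NoHearingLossError, ValidationError

#: Closed dB HL window at the tinnitus pitch implicating hearing loss as the
#: tinnitus generator (discordant outer/inner hair-cell damage model).
PITCH_THRESHOLD_WINDOW_DB_HL = (45.0, 55.0)

#: Any measured threshold strictly above this excludes the candidate.
PROFOUND_LOSS_CUTOFF_DB_HL = 90.0

#: Tinnitus must have persisted strictly longer than this to count as chronic.
CHRONICITY_MONTHS = 6.0


class Laterality(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"
    BILATERAL_OR_HEAD = "bilateral_or_head"


class RIOutcome(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class ExclusionReason(str, enum.Enum):
    ORGANIC = "ORGANIC"
    PITCH_THRESHOLD_OUT_OF_RANGE = "PITCH_THRESHOLD_OUT_OF_RANGE"
    RI_NEGATIVE = "RI_NEGATIVE"
    PROFOUND_LOSS = "PROFOUND_LOSS"
    NOT_CHRONIC = "NOT_CHRONIC"
    NOT_TONAL = "NOT_TONAL"
    NO_LOSS = "NO_LOSS"


#: Clinical work-up order; a record failing several criteria is tallied under
#: the first reason in this order.
EXCLUSION_PRECEDENCE = (
    ExclusionReason.ORGANIC,
    ExclusionReason.PITCH_THRESHOLD_OUT_OF_RANGE,
    ExclusionReason.RI_NEGATIVE,
    ExclusionReason.PROFOUND_LOSS,
    ExclusionReason.NOT_CHRONIC,
    ExclusionReason.NOT_TONAL,
    ExclusionReason.NO_LOSS,
)


@dataclass(frozen=True)
class AssessmentConstants:
    """Fixed psychoacoustic assessment parameters.

    pitch_match_level_db_sl
        Contralateral pure tones for pitch matching are presented at
        30 dB sensation level.
    step_db
        Audiometer step for loudness (TLL) and masking (MML) matching: 5 dB.
    ri_level_above_mml_db
        The RI probe is narrowband noise 10 dB above the MML.
    ri_duration_s
        The RI probe lasts 60 s.
    """

    pitch_match_level_db_sl: float = 30.0
    step_db: float = 5.0
    ri_level_above_mml_db: float = 10.0
    ri_duration_s: float = 60.0

    def __post_init__(self):
        for name in ("pitch_match_level_db_sl", "step_db", "ri_level_above_mml_db", "ri_duration_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TinnitusProfile:
    """Psychoacoustic tinnitus profile of one candidate.

    pitch : Hz (matched tinnitus frequency); tll / mml : dB HL (tinnitus
    loudness level / minimum masking level); ri : RI outcome; duration in
    months; tonal : whether the tinnitus is tonal rather than noise-like.
    """

    laterality: Laterality
    pitch: float
    tll: float
    mml: float
    ri: RIOutcome
    duration_months: float
    tonal: bool = True

    def __post_init__(self):
        object.__setattr__(self, "laterality", Laterality(self.laterality))
        object.__setattr__(self, "ri", RIOutcome(self.ri))
        if not (125.0 <= self.pitch <= 20000.0):
            raise ValidationError(f"pitch {self.pitch} Hz outside 125-20000 Hz")
        for name in ("tll", "mml"):
            v = getattr(self, name)
            if not (0.0 <= v <= 120.0):
                raise ValidationError(f"{name}={v} outside 0-120 dB HL")
        if self.duration_months < 0:
            raise ValidationError("duration must be nonnegative")

    @property
    def bilateral_assessment(self) -> bool:
        """Whether masking/RI noise is presented to both ears."""
        return self.laterality is Laterality.BILATERAL_OR_HEAD

    @classmethod
    def from_json(cls, source) -> "TinnitusProfile":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(
            laterality=data["laterality"],
            pitch=data["pitch_hz"],
            tll=data["tll_db_hl"],
            mml=data["mml_db_hl"],
            ri=data["ri"],
            duration_months=data["duration_months"],
            tonal=data.get("tonal", True),
        )

    def to_dict(self) -> dict:
        return {
            "laterality": self.laterality.value,
            "pitch_hz": self.pitch,
            "tll_db_hl": self.tll,
            "mml_db_hl": self.mml,
            "ri": self.ri.value,
            "duration_months": self.duration_months,
            "tonal": self.tonal,
        }


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: frozenset[ExclusionReason]

    def __post_init__(self):
        if self.eligible != (len(self.reasons) == 0):
            raise ValidationError("eligible iff reasons empty")

    @property
    def primary_reason(self) -> ExclusionReason | None:
        """First triggered reason in clinical work-up order (None if eligible)."""
        for r in EXCLUSION_PRECEDENCE:
            if r in self.reasons:
                return r
        return None


@dataclass(frozen=True)
class CohortFlow:
    """Screening flow: admitted = included + sum of per-reason exclusions."""

    admitted: int
    excluded_by_reason: Mapping[ExclusionReason, int]
    included: int

    def __post_init__(self):
        if self.included != self.admitted - sum(self.excluded_by_reason.values()):
            raise ValidationError("flow counts do not conserve")

    def to_dict(self) -> dict:
        return {
            "admitted": self.admitted,
            "excluded": {r.value: n for r, n in self.excluded_by_reason.items() if n},
            "included": self.included,
        }


@dataclass(frozen=True)
class GroupAssignment:
    """Seeded random partition of eligible records into study and placebo."""

    assignment: Mapping[object, str]
    seed: int

    @property
    def study(self) -> list:
        return [k for k, g in self.assignment.items() if g == "study"]

    @property
    def placebo(self) -> list:
        return [k for k, g in self.assignment.items() if g == "placebo"]


def check_eligibility(
    p: TinnitusProfile,
    a: Audiogram,
    organic_flag: bool = False,
    constants: AssessmentConstants = AssessmentConstants(),
) -> EligibilityResult:
    """Screen one candidate against the full inclusion criteria.

    The audiogram must span the tinnitus pitch (else :class:`DomainError`).
    Returns every violated criterion, not just the first.
    """
    lo_w, hi_w = PITCH_THRESHOLD_WINDOW_DB_HL
    reasons: set[ExclusionReason] = set()
    if organic_flag:
        reasons.add(ExclusionReason.ORGANIC)
    thr_at_pitch = threshold_at(a, p.pitch)  # raises DomainError out of span
    if not (lo_w <= thr_at_pitch <= hi_w):
        reasons.add(ExclusionReason.PITCH_THRESHOLD_OUT_OF_RANGE)
    if p.ri is RIOutcome.NEGATIVE:
        reasons.add(ExclusionReason.RI_NEGATIVE)
    if a.max_threshold() > PROFOUND_LOSS_CUTOFF_DB_HL:
        reasons.add(ExclusionReason.PROFOUND_LOSS)
    if p.duration_months <= CHRONICITY_MONTHS:
        reasons.add(ExclusionReason.NOT_CHRONIC)
    if not p.tonal:
        reasons.add(ExclusionReason.NOT_TONAL)
    try:
        loss_region(a)
    except NoHearingLossError:
        reasons.add(ExclusionReason.NO_LOSS)
    return EligibilityResult(eligible=not reasons, reasons=frozenset(reasons))


def filter_cohort(
    records: Iterable[tuple[TinnitusProfile, Audiogram, bool]],
) -> CohortFlow:
    """Screen a whole cohort; tally exclusions by first triggered reason.

    Each record is ``(profile, audiogram, organic_flag)`` (or any object
    with an ``as_screen_input()`` method returning that triple).  Counts
    depend only on the record multiset, not their order.
    """
    excluded = {r: 0 for r in ExclusionReason}
    admitted = included = 0
    for rec in records:
        profile, audiogram, organic = (
            rec.as_screen_input() if hasattr(rec, "as_screen_input") else rec
        )
        admitted += 1
        result = check_eligibility(profile, audiogram, organic)
        if result.eligible:
            included += 1
        else:
            excluded[result.primary_reason] += 1
    return CohortFlow(admitted=admitted, excluded_by_reason=excluded, included=included)


def randomize(eligible_ids: Sequence, seed: int, ratio: float) -> GroupAssignment:
    """Deterministically assign eligible records to study vs placebo groups.

    ``ratio`` is the study-group fraction; split sizes are round(ratio·n)
    and the remainder.  The same ids and seed always give the same
    assignment regardless of input order.
    """
    ids = list(eligible_ids)
    if not ids:
        raise ValidationError("no eligible records to randomize")
    if not (0.0 <= ratio <= 1.0):
        raise ValidationError("ratio must be within [0, 1]")
    order = sorted(range(len(ids)), key=lambda i: str(ids[i]))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_study = int(round(ratio * len(ids)))
    assignment = {}
    for rank, j in enumerate(perm):
        assignment[ids[order[j]]] = "study" if rank < n_study else "placebo"
    return GroupAssignment(assignment=assignment, seed=seed)
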