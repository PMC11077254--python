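"""Phased dosing schedule for sound-enrichment treatment.

The six-month course de-escalates in three contiguous phases:

====== ========== ============ ==========================================
months hours/day  level rule   presentation level (anchor)
====== ========== ============ ==========================================
0–1    6          above the    one step above the tinnitus loudness
                  tinnitus,    level (TLL), capped by comfort on the
                  comfortable  playback device
1–3    3          just above   one step above the minimum masking
                  suppression  level (MML)
3–6    2          just below   one step below the TLL
                  the tinnitus
====== ========== ============ ==========================================

"Just above/below" is quantified as one audiometer step (5 dB, the
instrument's minimum).  Anchors are in dB HL at the tinnitus pitch; the
patient sets the actual device volume to the anchor at each follow-up and
may adapt it through the day — only the prescribed anchors are modeled.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .screening import TinnitusProfile

#: Days per month used to map an adherence log's day numbers onto phases.
DAYS_PER_MONTH = 30


class LevelRule(str, enum.Enum):
    ABOVE_TINNITUS_COMFORTABLE = "ABOVE_TINNITUS_COMFORTABLE"
    JUST_ABOVE_SUPPRESSION = "JUST_ABOVE_SUPPRESSION"
    JUST_BELOW_TINNITUS = "JUST_BELOW_TINNITUS"


@dataclass(frozen=True)
class ProtocolPhase:
    start_month: float
    end_month: float
    daily_hours: float
    level_rule: LevelRule
    level_anchor_db_hl: float

    def __post_init__(self):
        if not self.start_month < self.end_month:
            raise ValidationError("phase must have start < end")
        if self.daily_hours <= 0:
            raise ValidationError("daily_hours must be positive")

    @property
    def target_minutes(self) -> float:
        return self.daily_hours * 60.0

    def to_dict(self) -> dict:
        return {
            "start_month": self.start_month,
            "end_month": self.end_month,
            "daily_hours": self.daily_hours,
            "level_rule": self.level_rule.value,
            "level_anchor_db_hl": self.level_anchor_db_hl,
        }


def build_plan(p: TinnitusProfile, step: float = 5.0) -> list[ProtocolPhase]:
    """Build the three-phase listening plan from a tinnitus profile.

    Phases are contiguous over [0, 6] months with daily hours (6, 3, 2);
    anchors are TLL+step, MML+step and TLL−step.  ``step`` defaults to the
    5 dB audiometer step.
    """
    if p.tll is None or p.mml is None:
        raise ValidationError("profile must have tll and mml to build a plan")
    return [
        ProtocolPhase(0.0, 1.0, 6.0, LevelRule.ABOVE_TINNITUS_COMFORTABLE, p.tll + step),
        ProtocolPhase(1.0, 3.0, 3.0, LevelRule.JUST_ABOVE_SUPPRESSION, p.mml + step),
        ProtocolPhase(3.0, 6.0, 2.0, LevelRule.JUST_BELOW_TINNITUS, p.tll - step),
    ]


def write_plan(plan: Sequence[ProtocolPhase], path) -> None:
    with open(path, "w") as fh:
        json.dump([ph.to_dict() for ph in plan], fh, indent=2)


@dataclass(frozen=True)
class PhaseAdherence:
    phase: ProtocolPhase
    n_days_logged: int
    mean_daily_minutes: float
    fraction_days_meeting_target: float


def adherence_summary(
    plan: Sequence[ProtocolPhase],
    log: Iterable[tuple[int, float]],
    days_per_month: int = DAYS_PER_MONTH,
) -> list[PhaseAdherence]:
    """Summarize a usage log per phase.

    ``log`` is (day number, minutes listened) pairs; day 0 is the first
    treatment day and phases cover days [start·days_per_month,
    end·days_per_month).  Returns mean daily minutes and the fraction of
    logged days meeting the phase's daily target.
    """
    entries = [(int(d), float(m)) for d, m in log]
    for d, m in entries:
        if m < 0:
            raise ValidationError(f"negative minutes ({m}) on day {d}")
    out = []
    for phase in plan:
        lo = phase.start_month * days_per_month
        hi = phase.end_month * days_per_month
        minutes = [m for d, m in entries if lo <= d < hi]
        if minutes:
            mean = float(np.mean(minutes))
            frac = float(np.mean([m >= phase.target_minutes for m in minutes]))
        else:
            mean = frac = 0.0
        out.append(
            PhaseAdherence(
                phase=phase,
                n_days_logged=len(minutes),
                mean_daily_minutes=mean,
                fraction_days_meeting_target=frac,
            )
        )
    return out
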