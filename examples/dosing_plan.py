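"""Build a patient's six-month dosing plan and summarize an adherence log.

Listening time de-escalates 6 -> 3 -> 2 hours per day; the presentation
level steps down from above the tinnitus loudness level (TLL) to just above
the masking level (MML) and finally just below the tinnitus.
"""

from tinnisynth import TinnitusProfile, adherence_summary, build_plan

profile = TinnitusProfile(
    laterality="bilateral_or_head", pitch=4000, tll=60, mml=55,
    ri="positive", duration_months=24, tonal=True,
)

plan = build_plan(profile, step=5)
for ph in plan:
    print(f"months {ph.start_month:g}-{ph.end_month:g}: {ph.daily_hours:g} h/day, "
          f"{ph.level_rule.value} -> {ph.level_anchor_db_hl:g} dB HL")

# a log that meets the target in month 1 but halves it afterwards
log = [(d, 360.0) for d in range(30)] + [(d, 90.0) for d in range(30, 180)]
for s in adherence_summary(plan, log):
    print(f"phase {s.phase.start_month:g}-{s.phase.end_month:g} mo: "
          f"mean {s.mean_daily_minutes:.0f} min/day, "
          f"{s.fraction_days_meeting_target:.0%} of days met the target")
# The anchors never increase across phases and the listening dose shrinks:
# the treatment tapers as the auditory system adapts.
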