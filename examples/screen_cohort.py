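"""Screen a synthetic intake cohort and randomize the survivors.

Builds a 127-candidate cohort whose composition mirrors a realistic clinic
intake (6 organic findings, 11 with a pitch-frequency threshold outside
45-55 dB HL, 10 with negative residual inhibition, 4 with profound loss),
applies the eligibility rules, and splits the included patients into study
and placebo groups.
"""

from tinnisynth import FixtureSpec, filter_cohort, gen_cohort, randomize

records = gen_cohort(FixtureSpec(seed=1))
flow = filter_cohort(records)

print(f"admitted : {flow.admitted}")
for reason, n in flow.excluded_by_reason.items():
    if n:
        print(f"excluded : {n:3d}  {reason.value}")
print(f"included : {flow.included}")

eligible_ids = [
    r.record_id for r in records
    if r.category == "eligible"
]
groups = randomize(eligible_ids, seed=1, ratio=52 / 96)
print(f"study group  : {len(groups.study)} participants")
print(f"placebo group: {len(groups.placebo)} participants")
# Every admitted record is accounted for exactly once: the exclusion counts
# plus the included survivors sum back to the intake.
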