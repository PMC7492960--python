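"""Hour-level clinical scoring: identification, false detections, ASM audit.

The cot-side team marks an hourly form and records antiseizure medication
(ASM).  A gold seizure hour counts as identified if the form is marked or
ASM given in that hour or the next; a marked hour with no seizure in it or
the hour before is a false detection; an ASM dose with no seizure in its
hour or the hour before is inappropriate.
"""

from neoseize import (
    HourRecord,
    NeonateRecord,
    hour_detection_summary,
    inappropriate_asm_events,
    score_hours,
)

# an 8-hour record: marks at hours 2 and 6, ASM at hours 2 and 5
flags = {2: (True, True), 5: (False, True), 6: (True, False)}
record = NeonateRecord(
    neonate_id="baby02",
    hospital="H3",
    group="algorithm",
    recording_duration_h=8.0,
    hours=[
        HourRecord(k, *flags.get(k, (False, False))) for k in range(8)
    ],
)
gold_hours = {1, 4}  # expert-confirmed seizure hours

scores = score_hours(record, gold_hours)
for s in scores:
    print(
        f"hour {s.hour_index}: gold={s.gold_seizure_hour!s:5} "
        f"identified={str(s.identified):5} false_detection={s.false_detection}"
    )
summary = hour_detection_summary(scores)
print(f"\n{summary.n_identified} of {summary.n_gold_hours} gold hours identified; "
      f"{summary.n_false_detections} of {summary.n_marked_hours} marked hours were false")
asm = inappropriate_asm_events(record, gold_hours)
print(f"inappropriate ASM doses at hours {list(asm.inappropriate_hours)}")

# Hour 1 is identified by the hour-after mark at 2; hour 4 by the ASM at 5.
# The mark at hour 6 has no seizure at 5 or 6, so it is a false detection,
# and the ASM at hour 2 (seizure was at hour 1) is appropriate while any
# dose far from a seizure would be flagged.
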