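"""Dual-expert consensus: from two annotation sets to gold-standard seizures.

Two expert neurophysiologists annotate the same recording.  Only periods
where both annotations overlap by at least 30 s become confirmed
electrographic seizures; everything else (including genuine short seizures
on which experts agree poorly) is excluded from the gold standard.
"""

from neoseize import (
    AnnotationSet,
    build_consensus,
    burden_summary,
    seizure_hours,
)

# expert 1 sees three seizures; expert 2 misses the short one and disagrees
# slightly on the boundaries of the others
expert1 = AnnotationSet("baby01", "E1", [(120, 300), (3550, 3720), (5000, 5020)])
expert2 = AnnotationSet("baby01", "E2", [(140, 290), (3540, 3700), (6000, 6015)])

consensus = build_consensus(expert1, expert2, recording_duration_h=2.0)

print("confirmed seizures (start_s, end_s):")
for ev in consensus.confirmed_events:
    print(f"  ({ev.start_s:7.1f}, {ev.end_s:7.1f})  duration {ev.duration_s:5.1f} s")

print("seizure hours:", sorted(seizure_hours(consensus)))
b = burden_summary(consensus)
print(f"total burden      {b.total_burden_min:.2f} min")
print(f"max hourly burden {b.max_hourly_burden_min_per_h:.2f} min/h")
print(f"median duration   {b.median_duration_s:.0f} s over {b.n_events} events")

# The (140, 290) and (3550, 3700) overlaps exceed 30 s and survive; the
# 20 s and 15 s events never overlap between experts and are excluded.
# The second seizure crosses the 3600 s boundary, so hours 0 and 1 are both
# seizure hours.
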