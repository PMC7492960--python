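"""Hour-level and neonate-level clinical seizure-recognition scoring.

During monitoring the cot-side clinical team completes an hourly seizure
record form and may administer antiseizure medication (ASM).  The
evaluation's decision rules, applied here against the expert gold standard:

* A neonate is *clinically identified* as a seizure neonate if at least one
  hour is marked on the form or at least one therapeutic ASM dose is given.
* A gold seizure hour H is *identified* if the form is marked or ASM is
  given in H or in H+1 (the hour-after window absorbs charting delay).
* A form-marked hour is a *false detection* if the experts annotated no
  seizure in that hour or the hour before.
* An ASM administration at hour H is *inappropriate* if there is no
  confirmed electrographic seizure in H or H-1 (the hour-before window
  allows for drug preparation time).

All rules work at hour granularity; sub-hour timing is floored to its bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, NamedTuple, Sequence

from .consensus import ConsensusAnnotation, is_seizure_neonate

__all__ = [
    "HourRecord",
    "NeonateRecord",
    "HourScore",
    "ConfusionCounts",
    "HourSummary",
    "AsmAssessment",
    "classify_neonate_clinical",
    "neonate_confusion",
    "score_hours",
    "hour_detection_summary",
    "inappropriate_asm_events",
    "hour_strata",
    "stratify_hours",
]


@dataclass(frozen=True)
class HourRecord:
    """One row of the hourly seizure record form."""

    hour_index: int
    form_marked: bool
    asm_given: bool
    asm_therapeutic: bool = True


@dataclass
class NeonateRecord:
    """Metadata plus the hourly clinical record for one neonate.

    ``hours`` must be contiguous from index 0; a missing hour is treated as
    blank (see :func:`neoseize.io.read_clinical`, which warns about gaps).
    ``start_datetime`` is only required for weekday/shift stratification.
    """

    neonate_id: str
    hospital: str
    group: str
    recording_duration_h: float
    hours: list[HourRecord] = field(default_factory=list)
    start_datetime: datetime | None = None

    def __post_init__(self) -> None:
        for i, h in enumerate(self.hours):
            if h.hour_index != i:
                raise ValueError(
                    f"neonate {self.neonate_id}: hour records must be contiguous "
                    f"from 0 (got index {h.hour_index} at position {i})"
                )


@dataclass(frozen=True)
class HourScore:
    """Joint gold/clinical classification of one recorded hour.

    ``identified`` is ``None`` for non-gold hours (identification is only
    defined for gold seizure hours).
    """

    neonate_id: str
    hour_index: int
    gold_seizure_hour: bool
    identified: bool | None
    false_detection: bool
    form_marked: bool
    asm_given: bool


@dataclass(frozen=True)
class ConfusionCounts:
    """Neonate-level confusion counts for one randomisation group."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class HourSummary(NamedTuple):
    """Aggregated hour-level counts (sensitivity and false-detection numerators/denominators)."""

    n_gold_hours: int
    n_identified: int
    n_marked_hours: int
    n_false_detections: int


@dataclass(frozen=True)
class AsmAssessment:
    """Per-neonate assessment of antiseizure-medication appropriateness."""

    neonate_id: str
    n_inappropriate: int
    any_inappropriate: bool
    inappropriate_hours: tuple[int, ...]


def classify_neonate_clinical(r: NeonateRecord) -> bool:
    """True iff the clinical team identified this neonate as having seizures.

    Positive if any hour is form-marked or any therapeutic ASM dose is
    recorded.
    """
    return any(
        h.form_marked or (h.asm_given and h.asm_therapeutic) for h in r.hours
    )


def neonate_confusion(
    cohort: Iterable[tuple[NeonateRecord, ConsensusAnnotation]],
) -> ConfusionCounts:
    """Cross the gold seizure-neonate flag with the clinical classification."""
    tp = tn = fp = fn = 0
    seen: set[str] = set()
    for rec, cons in cohort:
        if rec.neonate_id in seen:
            raise ValueError(f"duplicate neonate_id {rec.neonate_id!r} in cohort")
        seen.add(rec.neonate_id)
        gold = is_seizure_neonate(cons)
        clin = classify_neonate_clinical(rec)
        if gold and clin:
            tp += 1
        elif gold:
            fn += 1
        elif clin:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def score_hours(r: NeonateRecord, gold_hours: set[int]) -> list[HourScore]:
    """Score every recorded hour against the gold seizure-hour set.

    For a gold hour H, ``identified`` is true when the form is marked or ASM
    given in H, or in H+1 when H+1 exists (no padding past the record).  A
    form-marked hour H is a ``false_detection`` when neither H nor H-1 is a
    gold hour (the H-1 clause is skipped at H=0).
    """
    n = len(r.hours)

    def flagged(k: int) -> bool:
        return 0 <= k < n and (r.hours[k].form_marked or r.hours[k].asm_given)

    scores: list[HourScore] = []
    for h in r.hours:
        k = h.hour_index
        gold = k in gold_hours
        identified = (flagged(k) or flagged(k + 1)) if gold else None
        false_det = h.form_marked and k not in gold_hours and (k - 1) not in gold_hours
        scores.append(
            HourScore(
                neonate_id=r.neonate_id,
                hour_index=k,
                gold_seizure_hour=gold,
                identified=identified,
                false_detection=false_det,
                form_marked=h.form_marked,
                asm_given=h.asm_given,
            )
        )
    return scores


def hour_detection_summary(scores: Iterable[HourScore]) -> HourSummary:
    """Aggregate hour scores (possibly pooled over a group of neonates).

    ``n_marked_hours`` counts form-marked hours only: medication-only events
    contribute to identification but not to the false-detection denominator.
    """
    n_gold = n_ident = n_marked = n_false = 0
    for s in scores:
        if s.gold_seizure_hour:
            n_gold += 1
            if s.identified:
                n_ident += 1
        if s.form_marked:
            n_marked += 1
        if s.false_detection:
            n_false += 1
    return HourSummary(n_gold, n_ident, n_marked, n_false)


def inappropriate_asm_events(r: NeonateRecord, gold_hours: set[int]) -> AsmAssessment:
    """Flag ASM administrations with no confirmed seizure in their hour or the hour before."""
    bad: list[int] = []
    for h in r.hours:
        if h.asm_given and h.asm_therapeutic:
            k = h.hour_index
            if k not in gold_hours and (k - 1) not in gold_hours:
                bad.append(k)
    return AsmAssessment(
        neonate_id=r.neonate_id,
        n_inappropriate=len(bad),
        any_inappropriate=bool(bad),
        inappropriate_hours=tuple(bad),
    )


def hour_strata(
    start: datetime, n_hours: int
) -> list[tuple[str, str]]:
    """Calendar strata (day-of-week, shift) for each hour bin of a recording.

    Each hour bin is classified by the wall clock at its start: weekday
    (Monday-Friday) vs weekend (Saturday-Sunday), and day shift (08:00-20:00)
    vs night shift (20:00-08:00).
    """
    out: list[tuple[str, str]] = []
    for k in range(n_hours):
        t = start + timedelta(hours=k)
        day = "weekend" if t.weekday() >= 5 else "weekday"
        shift = "day" if 8 <= t.hour < 20 else "night"
        out.append((day, shift))
    return out


def stratify_hours(
    scored: Sequence[tuple[NeonateRecord, list[HourScore]]],
) -> dict[str, HourSummary]:
    """Hour-detection summaries within weekday/weekend and day/night strata.

    Returns summaries keyed ``"overall"``, ``"weekday"``, ``"weekend"``,
    ``"day_shift"``, ``"night_shift"``.

    Raises
    ------
    ValueError
        If any neonate lacks a recording-start timestamp.
    """
    buckets: dict[str, list[HourScore]] = {
        "overall": [],
        "weekday": [],
        "weekend": [],
        "day_shift": [],
        "night_shift": [],
    }
    for rec, scores in scored:
        if rec.start_datetime is None:
            raise ValueError(
                f"neonate {rec.neonate_id}: start_datetime required for stratification"
            )
        strata = hour_strata(rec.start_datetime, len(rec.hours))
        for s in scores:
            day, shift = strata[s.hour_index]
            buckets["overall"].append(s)
            buckets[day].append(s)
            buckets[f"{shift}_shift"].append(s)
    return {k: hour_detection_summary(v) for k, v in buckets.items()}
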