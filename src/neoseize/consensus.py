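"""Dual-expert seizure-annotation consensus.

Two independent expert neurophysiologists each annotate a neonate's
continuous EEG with seizure intervals (an electrographic seizure being at
least 10 s of evolving, repetitive stereotyped waveforms).  Because
inter-expert agreement on very short seizures is poor, an event only enters
the gold standard when the two annotations overlap by at least 30 s: the
confirmed events are the maximal segments of the intersection of the two
annotations that last >= 30 s.

This module implements that rule as interval algebra on [start, end)
segments in seconds from recording start, plus the derived per-neonate
quantities the evaluation needs: the seizure-neonate flag, the set of
seizure hours (consecutive 60-min bins anchored at recording start), and
seizure-burden summaries (total burden, maximum hourly burden, median
seizure duration).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

__all__ = [
    "TOL_S",
    "SeizureInterval",
    "AnnotationSet",
    "ConsensusAnnotation",
    "BurdenSummary",
    "InvalidIntervalError",
    "PairingError",
    "normalize_annotation",
    "intersect_annotations",
    "confirm_seizures",
    "is_seizure_neonate",
    "seizure_hours",
    "burden_summary",
]

#: Tolerance for touching / degenerate segments (1 ms).  Two segments whose
#: gap is below this are treated as touching; intersection segments shorter
#: than this are discarded as floating-point dust.
TOL_S = 1e-3

HOUR_S = 3600.0


class InvalidIntervalError(ValueError):
    """An annotated event with non-positive duration."""


class PairingError(ValueError):
    """Two annotation sets that do not belong to the same neonate."""


@dataclass(frozen=True, order=True)
class SeizureInterval:
    """A half-open seizure interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise InvalidIntervalError(
                f"interval end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.start_s < 0:
            raise InvalidIntervalError(f"interval start ({self.start_s}) is negative")


@dataclass
class AnnotationSet:
    """One expert's seizure events for one neonate (normalized on build)."""

    neonate_id: str
    annotator_id: str
    events: list[SeizureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = normalize_annotation(self.events)


@dataclass
class ConsensusAnnotation:
    """Confirmed (gold standard) seizure events for one neonate."""

    neonate_id: str
    confirmed_events: list[SeizureInterval]
    recording_duration_h: float

    def __post_init__(self) -> None:
        if self.recording_duration_h <= 0:
            raise ValueError("recording_duration_h must be positive")


@dataclass
class BurdenSummary:
    """Seizure-burden summary measures for one neonate.

    ``median_duration_s`` is ``None`` when there are no confirmed events.
    """

    neonate_id: str
    total_burden_min: float
    max_hourly_burden_min_per_h: float
    median_duration_s: float | None
    n_events: int


def normalize_annotation(
    events: Iterable[SeizureInterval | tuple[float, float]],
) -> list[SeizureInterval]:
    """Sort events and merge overlapping or touching ones into maximal intervals.

    Accepts either :class:`SeizureInterval` objects or ``(start, end)`` pairs.
    Total covered time is preserved; intervals whose gap is below :data:`TOL_S`
    are considered touching and merged.

    Raises
    ------
    InvalidIntervalError
        If any event has ``end_s <= start_s`` (the message names the
        offending row index).
    """
    parsed: list[SeizureInterval] = []
    for i, ev in enumerate(events):
        if not isinstance(ev, SeizureInterval):
            start, end = ev
            if not (end > start):
                raise InvalidIntervalError(
                    f"row {i}: interval end ({end}) must exceed start ({start})"
                )
            ev = SeizureInterval(float(start), float(end))
        parsed.append(ev)
    parsed.sort()
    merged: list[list[float]] = []
    for ev in parsed:
        if merged and ev.start_s <= merged[-1][1] + TOL_S:
            merged[-1][1] = max(merged[-1][1], ev.end_s)
        else:
            merged.append([ev.start_s, ev.end_s])
    return [SeizureInterval(s, e) for s, e in merged]


def intersect_annotations(
    a: AnnotationSet, b: AnnotationSet
) -> list[SeizureInterval]:
    """Set-intersection of two experts' annotation coverage.

    Returns the maximal disjoint segments covered by *both* annotation sets,
    sorted by start.  Segments shorter than :data:`TOL_S` are dropped.

    Raises
    ------
    PairingError
        If the two sets belong to different neonates.
    """
    if a.neonate_id != b.neonate_id:
        raise PairingError(
            f"annotation sets for different neonates: {a.neonate_id!r} vs {b.neonate_id!r}"
        )
    out: list[SeizureInterval] = []
    i = j = 0
    ea, eb = a.events, b.events
    while i < len(ea) and j < len(eb):
        lo = max(ea[i].start_s, eb[j].start_s)
        hi = min(ea[i].end_s, eb[j].end_s)
        if hi - lo > TOL_S:
            out.append(SeizureInterval(lo, hi))
        # advance the interval that ends first
        if ea[i].end_s <= eb[j].end_s:
            i += 1
        else:
            j += 1
    return out


def confirm_seizures(
    intersections: Sequence[SeizureInterval],
    *,
    neonate_id: str,
    recording_duration_h: float,
    min_overlap_s: float = 30.0,
) -> ConsensusAnnotation:
    """Apply the dual-overlap confirmation rule to intersection segments.

    A segment is a confirmed electrographic seizure iff its duration is at
    least ``min_overlap_s`` (inclusive; default 30 s).  The confirmed events
    are the gold standard annotation.

    Raises
    ------
    ValueError
        If ``min_overlap_s`` is negative.
    """
    if min_overlap_s < 0:
        raise ValueError("min_overlap_s must be non-negative")
    kept = [
        seg for seg in intersections if seg.duration_s >= min_overlap_s - TOL_S
    ]
    return ConsensusAnnotation(
        neonate_id=neonate_id,
        confirmed_events=list(kept),
        recording_duration_h=recording_duration_h,
    )


def is_seizure_neonate(c: ConsensusAnnotation) -> bool:
    """True iff the neonate has at least one confirmed electrographic seizure."""
    return len(c.confirmed_events) > 0


def _clip_events(c: ConsensusAnnotation) -> list[SeizureInterval]:
    """Clip confirmed events to the recording span, warning on overruns."""
    rec_end = c.recording_duration_h * HOUR_S
    out: list[SeizureInterval] = []
    for ev in c.confirmed_events:
        if ev.end_s > rec_end + TOL_S:
            warnings.warn(
                f"neonate {c.neonate_id}: event ({ev.start_s}, {ev.end_s}) extends "
                f"beyond recording end ({rec_end:.1f} s); clipped",
                stacklevel=3,
            )
        s = min(ev.start_s, rec_end)
        e = min(ev.end_s, rec_end)
        if e - s > TOL_S:
            out.append(SeizureInterval(s, e))
    return out


def seizure_hours(c: ConsensusAnnotation, *, bin_offset_s: float = 0.0) -> set[int]:
    """Hour bins containing at least one confirmed seizure.

    Hours are consecutive 60-min windows ``[3600*k, 3600*(k+1))`` measured
    from recording start (shifted by ``bin_offset_s`` for wall-clock
    alignment if desired).  Hour ``k`` is a seizure hour iff some confirmed
    event overlaps bin ``k`` with positive duration (> :data:`TOL_S`).
    Events extending past the recording end are clipped with a warning.
    """
    hours: set[int] = set()
    n_bins = math.ceil(c.recording_duration_h - 1e-12)
    for ev in _clip_events(c):
        k0 = max(0, math.floor((ev.start_s - bin_offset_s) / HOUR_S))
        k1 = math.floor((ev.end_s - bin_offset_s - TOL_S) / HOUR_S)
        for k in range(k0, min(k1, n_bins - 1) + 1):
            bin_lo = bin_offset_s + k * HOUR_S
            bin_hi = bin_lo + HOUR_S
            if min(ev.end_s, bin_hi) - max(ev.start_s, bin_lo) > TOL_S:
                hours.add(k)
    return hours


def hourly_burden_s(c: ConsensusAnnotation, *, bin_offset_s: float = 0.0) -> list[float]:
    """Seconds of confirmed seizure in each hour bin of the recording."""
    n_bins = math.ceil(c.recording_duration_h - 1e-12)
    burden = [0.0] * n_bins
    for ev in _clip_events(c):
        k0 = max(0, math.floor((ev.start_s - bin_offset_s) / HOUR_S))
        for k in range(k0, n_bins):
            bin_lo = bin_offset_s + k * HOUR_S
            if bin_lo >= ev.end_s:
                break
            overlap = min(ev.end_s, bin_lo + HOUR_S) - max(ev.start_s, bin_lo)
            if overlap > 0:
                burden[k] += overlap
    return burden


def burden_summary(c: ConsensusAnnotation) -> BurdenSummary:
    """Total, maximum hourly, and median-duration burden summaries.

    Total seizure burden is the summed duration of confirmed events in
    minutes; maximum hourly burden is the within-bin seizure time of the
    worst hour in min/h (a trailing partial hour is a valid bin and is not
    rescaled); median seizure duration is over confirmed events in seconds,
    the midpoint of the central pair for even counts.
    """
    events = _clip_events(c)
    durations = [ev.duration_s for ev in events]
    total_min = sum(durations) / 60.0
    per_hour = hourly_burden_s(c)
    max_hourly_min = max(per_hour) / 60.0 if per_hour else 0.0
    return BurdenSummary(
        neonate_id=c.neonate_id,
        total_burden_min=total_min,
        max_hourly_burden_min_per_h=max_hourly_min,
        median_duration_s=median(durations) if durations else None,
        n_events=len(events),
    )


def build_consensus(
    a: AnnotationSet,
    b: AnnotationSet,
    *,
    recording_duration_h: float,
    min_overlap_s: float = 30.0,
) -> ConsensusAnnotation:
    """Convenience: intersect two annotation sets and confirm seizures."""
    segs = intersect_annotations(a, b)
    return confirm_seizures(
        segs,
        neonate_id=a.neonate_id,
        recording_duration_h=recording_duration_h,
        min_overlap_s=min_overlap_s,
    )
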