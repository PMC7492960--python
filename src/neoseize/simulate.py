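"""Synthetic two-arm seizure-monitoring cohort generator.

The evaluation pipeline needs multicentre trial data that cannot be shared,
so this module generates complete synthetic cohorts with the same structure:
two arms of ~130 neonates block-randomised within 8 hospitals, a seizure
prevalence of roughly a quarter per arm, bout-structured seizure event
trains whose burden summaries resemble typical reported marginals (median
total burden a few tens of minutes, median event duration ~105 s), two
imperfect expert annotators (boundary jitter, misses of short events,
spurious short events), and a cot-side clinical team whose chance of
marking a seizure hour rises with the seizure burden in that hour
(a logistic curve in log hourly burden, with an optional weekend deficit).

Ground truth (true events, hourly burden, latent detection probabilities)
is emitted alongside the data and is never consumed by the pipeline, so
parameter-recovery experiments can compare pipeline estimates with what
was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .consensus import normalize_annotation

__all__ = [
    "DurationModel",
    "BurdenModel",
    "AnnotatorModel",
    "DetectionModel",
    "CohortConfig",
    "SyntheticTruth",
    "CohortData",
    "GenerationError",
    "CalibrationError",
    "generate_cohort",
    "plant_group_effect",
]

GROUPS = ("algorithm", "non_algorithm")
HOUR_S = 3600.0
MIN_EVENT_S = 10.0  # electrographic seizure definition: >= 10 s


class GenerationError(ValueError):
    """Infeasible generator configuration."""


class CalibrationError(RuntimeError):
    """A planted sensitivity target that the detection model cannot reach."""


@dataclass(frozen=True)
class DurationModel:
    """Log-normal recording duration in hours, clipped to a plausible range.

    Default targets a median near 50 h of monitoring, with recordings
    between the 2 h minimum and the 100 h evaluation cap.
    """

    median_h: float = 50.0
    sigma: float = 0.6
    min_h: float = 2.0
    max_h: float = 100.0


@dataclass(frozen=True)
class BurdenModel:
    """Bout-structured seizure event trains for seizure neonates.

    Seizures arrive in bouts: bout starts form a homogeneous Poisson process
    over the recording (at least one bout is guaranteed), each bout holds a
    geometric number of seizures separated by exponential gaps, and event
    durations are log-normal.  Defaults target a median event duration of
    ~105 s and median total burden of a few tens of minutes over a ~50 h
    recording.
    """

    bout_rate_per_h: float = 0.09
    events_per_bout_mean: float = 5.0
    gap_mean_s: float = 300.0
    dur_median_s: float = 105.0
    dur_sigma: float = 0.7
    severity_sigma: float = 0.8  # per-neonate log-normal multiplier on bout rate


@dataclass(frozen=True)
class AnnotatorModel:
    """Imperfect expert annotation of the true events.

    Each annotator independently jitters event boundaries (Gaussian, sd in
    seconds), misses short events (< ``short_cutoff_s``) with probability
    ``miss_prob_short``, and adds spurious short events at a Poisson rate
    per hour.  Jitter occasionally shrinks true ~30-60 s events below the
    30 s consensus window, exercising the confirmation rule.
    """

    jitter_sd_s: float = 5.0
    miss_prob_short: float = 0.3
    short_cutoff_s: float = 60.0
    spurious_rate_per_h: float = 0.1
    spurious_dur_s: tuple[float, float] = (10.0, 25.0)


@dataclass(frozen=True)
class DetectionModel:
    """Burden-dependent clinical recognition for one randomisation arm.

    In an hour with true seizure burden b minutes, the form is marked with
    probability ``expit(intercept + slope * log(b))`` (plus
    ``weekend_logodds_offset`` when the hour starts on a weekend).  False
    marks cluster within neonates: with probability ``p_false_marker`` a
    neonate is prone to suspicious non-seizure movements and its
    seizure-free hours are marked at ``false_mark_rate_per_h``; other
    neonates produce no false marks.  ASM is given with probability
    ``p_asm_on_mark`` in any marked hour; after the first identified hour,
    further doses (maintenance dosing) arrive at ``asm_repeat_rate_per_h``;
    a small background rate generates sporadic administrations in any
    neonate.
    """

    intercept: float
    slope: float = 0.9
    weekend_logodds_offset: float = 0.0
    p_false_marker: float = 0.13
    false_mark_rate_per_h: float = 0.08
    p_asm_on_mark: float = 0.3
    asm_repeat_rate_per_h: float = 0.01
    background_asm_rate_per_h: float = 0.001


def _default_detection() -> dict[str, DetectionModel]:
    # algorithm arm: decision support raises the log-odds of recognising a
    # seizure hour; non-algorithm arm additionally loses ground at weekends
    # when neurophysiology expertise is scarcer.  Intercepts target overall
    # hour-level sensitivities of roughly two thirds vs under a half.
    return {
        "algorithm": DetectionModel(intercept=-1.5, weekend_logodds_offset=0.0),
        "non_algorithm": DetectionModel(intercept=-2.3, weekend_logodds_offset=-0.4),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic two-arm cohort."""

    n_per_group: int = 130
    n_hospitals: int = 8
    seizure_prevalence: tuple[float, float] = (0.25, 0.29)  # (algorithm, non_algorithm)
    duration: DurationModel = field(default_factory=DurationModel)
    burden: BurdenModel = field(default_factory=BurdenModel)
    annotator: AnnotatorModel = field(default_factory=AnnotatorModel)
    detection: dict[str, DetectionModel] = field(default_factory=_default_detection)
    min_overlap_s: float = 30.0
    start_date: datetime = datetime(2015, 2, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.seizure_prevalence:
            if not (0 <= p <= 1):
                raise GenerationError(f"seizure_prevalence {p} outside [0, 1]")
        b = self.burden
        if b.bout_rate_per_h < 0 or b.gap_mean_s < 0:
            raise GenerationError("burden rates must be non-negative")
        mean_burden_h = (
            max(b.bout_rate_per_h * self.duration.median_h, 1.0)
            * b.events_per_bout_mean
            * b.dur_median_s
            * math.exp(b.dur_sigma**2 / 2)
            / HOUR_S
        )
        if mean_burden_h > 0.5 * self.duration.median_h:
            raise GenerationError(
                "burden_model: expected seizure burden exceeds half the median "
                "recording length; reduce bout_rate_per_h or events_per_bout_mean"
            )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data (never consumed by the pipeline)."""

    true_events: dict[str, list[tuple[float, float]]]
    hourly_burden_min: dict[str, list[float]]
    detect_prob: dict[str, list[float]]
    planted_sensitivity: dict[str, float] | None = None


@dataclass
class CohortData:
    """A generated cohort: the pipeline's input tables plus ground truth."""

    annotations: pd.DataFrame  # neonate_id, annotator_id, start_s, end_s
    clinical: pd.DataFrame  # neonate_id, hour_index, form_marked, asm_given, asm_therapeutic
    metadata: pd.DataFrame  # neonate_id, hospital, group, recording_duration_h, start_datetime
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# event-train and annotation machinery
# ---------------------------------------------------------------------------

def _simulate_events(
    rng: np.random.Generator, duration_h: float, model: BurdenModel
) -> list[tuple[float, float]]:
    """True seizure events for one seizure neonate (merged, within recording)."""
    rec_s = duration_h * HOUR_S
    severity = rng.lognormal(-model.severity_sigma**2 / 2, model.severity_sigma)
    n_bouts = max(1, rng.poisson(model.bout_rate_per_h * severity * duration_h))
    mu = math.log(model.dur_median_s)
    events: list[tuple[float, float]] = []
    for start in np.sort(rng.uniform(0.0, rec_s, size=n_bouts)):
        t = float(start)
        n_ev = 1 + rng.geometric(1.0 / model.events_per_bout_mean)
        for _ in range(n_ev):
            dur = float(np.clip(rng.lognormal(mu, model.dur_sigma), MIN_EVENT_S, HOUR_S))
            end = min(t + dur, rec_s)
            if end - t >= MIN_EVENT_S:
                events.append((t, end))
            t = end + float(rng.exponential(model.gap_mean_s))
            if t >= rec_s:
                break
    merged = normalize_annotation(events)
    return [(ev.start_s, ev.end_s) for ev in merged]


def _annotate(
    rng: np.random.Generator,
    true_events: list[tuple[float, float]],
    duration_h: float,
    model: AnnotatorModel,
) -> list[tuple[float, float]]:
    """One expert's imperfect annotation of the true events."""
    rec_s = duration_h * HOUR_S
    out: list[tuple[float, float]] = []
    for s, e in true_events:
        if (e - s) < model.short_cutoff_s and rng.random() < model.miss_prob_short:
            continue
        js = s + rng.normal(0.0, model.jitter_sd_s)
        je = e + rng.normal(0.0, model.jitter_sd_s)
        js = float(np.clip(js, 0.0, rec_s))
        je = float(np.clip(je, 0.0, rec_s))
        if je - js < MIN_EVENT_S:  # annotators only report >= 10 s events
            mid = (js + je) / 2.0
            js = float(np.clip(mid - MIN_EVENT_S / 2, 0.0, rec_s - MIN_EVENT_S))
            je = js + MIN_EVENT_S
        out.append((js, je))
    n_spur = rng.poisson(model.spurious_rate_per_h * duration_h)
    lo, hi = model.spurious_dur_s
    for _ in range(n_spur):
        dur = float(rng.uniform(lo, hi))
        s = float(rng.uniform(0.0, max(rec_s - dur, 0.0)))
        out.append((s, s + dur))
    merged = normalize_annotation(out)
    return [(ev.start_s, ev.end_s) for ev in merged]


def _hourly_burden_min(
    events: Iterable[tuple[float, float]], n_hours: int
) -> np.ndarray:
    """Minutes of true seizure per hour bin."""
    burden = np.zeros(n_hours)
    for s, e in events:
        k0 = max(0, int(s // HOUR_S))
        for k in range(k0, n_hours):
            lo = k * HOUR_S
            if lo >= e:
                break
            burden[k] += max(0.0, min(e, lo + HOUR_S) - max(s, lo)) / 60.0
    return burden


def _mark_probs(
    burden_min: np.ndarray,
    weekend: np.ndarray,
    det: DetectionModel,
    false_marker: bool,
) -> np.ndarray:
    """Per-hour probability that the form is marked."""
    false_rate = det.false_mark_rate_per_h if false_marker else 0.0
    p = np.where(
        burden_min > 0,
        expit(
            det.intercept
            + det.slope * np.log(np.maximum(burden_min, 1e-9))
            + det.weekend_logodds_offset * weekend
        ),
        false_rate,
    )
    return p


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _allocate(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    """Block-randomised 1:1 allocation within hospitals (blocks of 2 or 4)."""
    total = 2 * config.n_per_group
    base, extra = divmod(total, config.n_hospitals)
    rows = []
    counter = 0
    deficit = {g: config.n_per_group for g in GROUPS}
    for h in range(config.n_hospitals):
        n_h = base + (1 if h < extra else 0)
        assigned: list[str] = []
        while len(assigned) < n_h:
            bs = int(rng.choice([2, 4]))
            block = [GROUPS[0]] * (bs // 2) + [GROUPS[1]] * (bs // 2)
            rng.shuffle(block)
            assigned.extend(block)
        assigned = assigned[:n_h]
        for g in assigned:
            # keep the 1:1 arm totals exact despite truncated final blocks
            if deficit[g] == 0:
                g = GROUPS[0] if deficit[GROUPS[0]] > 0 else GROUPS[1]
            deficit[g] -= 1
            counter += 1
            rows.append({"neonate_id": f"N{counter:04d}", "hospital": f"H{h + 1}", "group": g})
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Generate a full synthetic cohort, deterministically from ``config.seed``.

    Returns the two-annotator event table, the hourly clinical record, the
    cohort metadata, and the ground truth.  In the perfect-annotator limit
    (zero jitter, zero miss probability, zero spurious rate) both annotation
    sets equal the true events exactly.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    alloc = _allocate(rng, config)
    prev = dict(zip(GROUPS, config.seizure_prevalence))

    ann_rows: list[dict] = []
    clin_rows: list[dict] = []
    meta_rows: list[dict] = []
    truth = SyntheticTruth(true_events={}, hourly_burden_min={}, detect_prob={})

    dmod, bmod, amod = config.duration, config.burden, config.annotator
    mu_dur = math.log(dmod.median_h)
    for row in alloc.itertuples(index=False):
        nid, hosp, group = row.neonate_id, row.hospital, row.group
        duration_h = float(
            np.clip(rng.lognormal(mu_dur, dmod.sigma), dmod.min_h, dmod.max_h)
        )
        n_hours = math.ceil(duration_h - 1e-9)
        start = config.start_date + timedelta(
            days=int(rng.integers(0, 700)), hours=int(rng.integers(0, 24))
        )
        is_sz = rng.random() < prev[group]
        events = _simulate_events(rng, duration_h, bmod) if is_sz else []
        for ann_id in ("E1", "E2"):
            for s, e in _annotate(rng, events, duration_h, amod):
                ann_rows.append(
                    {"neonate_id": nid, "annotator_id": ann_id, "start_s": s, "end_s": e}
                )
        burden = _hourly_burden_min(events, n_hours)
        weekend = np.array(
            [1.0 if (start + timedelta(hours=k)).weekday() >= 5 else 0.0 for k in range(n_hours)]
        )
        det = config.detection[group]
        false_marker = rng.random() < det.p_false_marker
        p = _mark_probs(burden, weekend, det, false_marker)
        marked = rng.random(n_hours) < p
        asm = (marked & (rng.random(n_hours) < det.p_asm_on_mark)) | (
            rng.random(n_hours) < det.background_asm_rate_per_h
        )
        # maintenance dosing after the first recognised seizure hour
        sz_marked = np.flatnonzero(marked & (burden > 0))
        if len(sz_marked) and det.asm_repeat_rate_per_h > 0:
            first = int(sz_marked[0])
            asm[first + 1:] |= (
                rng.random(n_hours - first - 1) < det.asm_repeat_rate_per_h
            )
        for k in range(n_hours):
            clin_rows.append(
                {
                    "neonate_id": nid,
                    "hour_index": k,
                    "form_marked": int(marked[k]),
                    "asm_given": int(asm[k]),
                    "asm_therapeutic": 1,
                }
            )
        meta_rows.append(
            {
                "neonate_id": nid,
                "hospital": hosp,
                "group": group,
                "recording_duration_h": math.ceil(duration_h * 1000) / 1000,
                "start_datetime": start.isoformat(),
            }
        )
        truth.true_events[nid] = events
        truth.hourly_burden_min[nid] = burden.tolist()
        truth.detect_prob[nid] = p.tolist()

    annotations = pd.DataFrame(
        ann_rows, columns=["neonate_id", "annotator_id", "start_s", "end_s"]
    )
    clinical = pd.DataFrame(
        clin_rows,
        columns=["neonate_id", "hour_index", "form_marked", "asm_given", "asm_therapeutic"],
    )
    metadata = pd.DataFrame(
        meta_rows,
        columns=["neonate_id", "hospital", "group", "recording_duration_h", "start_datetime"],
    )
    return CohortData(annotations=annotations, clinical=clinical, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# planting a group effect
# ---------------------------------------------------------------------------

def _expected_sensitivity_fn(
    config: CohortConfig, group: str, n_sim: int, cal_seed: int
):
    """Deterministic map intercept -> expected hour-level sensitivity.

    Simulates ``n_sim`` seizure neonates' event trains once (common random
    numbers), then evaluates, for any candidate intercept, the fraction of
    gold seizure hours identified under the hour-or-hour-after rule when
    each seizure hour is marked with probability expit(intercept +
    slope*log(burden)).  Because the same uniforms are reused for every
    candidate, the map is monotone in the intercept and bisection applies.
    """
    rng = np.random.default_rng(cal_seed)
    det = config.detection[group]
    dmod, bmod = config.duration, config.burden
    mu_dur = math.log(dmod.median_h)
    sims: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for _ in range(n_sim):
        duration_h = float(np.clip(rng.lognormal(mu_dur, dmod.sigma), dmod.min_h, dmod.max_h))
        n_hours = math.ceil(duration_h - 1e-9)
        events = _simulate_events(rng, duration_h, bmod)
        burden = _hourly_burden_min(events, n_hours)
        gold = np.zeros(n_hours, dtype=bool)
        for s, e in events:  # gold hours: >= min_overlap events (ideal annotators)
            if e - s >= config.min_overlap_s:
                k0, k1 = int(s // HOUR_S), int(min(e, n_hours * HOUR_S) // HOUR_S)
                for k in range(k0, min(k1, n_hours - 1) + 1):
                    if min(e, (k + 1) * HOUR_S) - max(s, k * HOUR_S) > 0:
                        gold[k] = True
        u = rng.random(n_hours)
        sims.append((burden, gold, u))

    def expected(intercept: float) -> float:
        n_gold = n_ident = 0
        for burden, gold, u in sims:
            logit = intercept + det.slope * np.log(np.maximum(burden, 1e-9))
            marked = (burden > 0) & (u < expit(logit))
            nxt = np.zeros_like(marked)
            nxt[:-1] = marked[1:]
            ident = gold & (marked | nxt)
            n_gold += int(gold.sum())
            n_ident += int(ident.sum())
        return n_ident / n_gold if n_gold else float("nan")

    return expected


def plant_group_effect(
    config: CohortConfig,
    sens_a: float,
    sens_b: float,
    *,
    n_sim: int = 3000,
    cal_seed: int = 12345,
) -> CohortConfig:
    """Calibrate the detection model so each arm's expected hour sensitivity hits a target.

    Returns a new config with ideal annotators, no false marks, no
    background ASM and no weekend effect, in which the detection intercept
    of each arm is found by bisection so that the expected fraction of gold
    seizure hours identified equals ``sens_a`` (algorithm arm) and
    ``sens_b`` (non-algorithm arm).  The planted targets then refer to the
    burden-dependent detection channel alone, giving parameter-recovery
    experiments a well-defined truth.

    Raises
    ------
    CalibrationError
        If a target is unattainable for the burden distribution.
    """
    for s in (sens_a, sens_b):
        if not (0 <= s < 1):
            raise CalibrationError(f"target sensitivity {s} outside [0, 1)")
    clean = replace(
        config,
        annotator=AnnotatorModel(
            jitter_sd_s=0.0, miss_prob_short=0.0, spurious_rate_per_h=0.0
        ),
    )
    targets = dict(zip(GROUPS, (sens_a, sens_b)))
    new_det: dict[str, DetectionModel] = {}
    for group, target in targets.items():
        det = replace(
            config.detection[group],
            weekend_logodds_offset=0.0,
            p_false_marker=0.0,
            false_mark_rate_per_h=0.0,
            asm_repeat_rate_per_h=0.0,
            background_asm_rate_per_h=0.0,
        )
        probe = replace(clean, detection={**config.detection, group: det})
        expected = _expected_sensitivity_fn(probe, group, n_sim, cal_seed)
        lo, hi = -12.0, 12.0
        f_lo, f_hi = expected(lo) - target, expected(hi) - target
        if f_lo > 0 or f_hi < 0:
            raise CalibrationError(
                f"target sensitivity {target} unattainable for group {group!r} "
                f"(reachable range [{expected(lo):.3f}, {expected(hi):.3f}])"
            )
        intercept = brentq(lambda a: expected(a) - target, lo, hi, xtol=1e-4)
        new_det[group] = replace(det, intercept=float(intercept))
    planted = replace(clean, detection=new_det)
    return planted
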