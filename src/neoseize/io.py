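"""CSV readers/writers and input validation for the evaluation pipeline.

All files are comma-separated UTF-8 with a header row, '.' decimal point and
ISO-8601 timestamps.

Schemas
-------
annotations.csv : neonate_id, annotator_id, start_s, end_s
clinical.csv    : neonate_id, hour_index, form_marked, asm_given[, asm_therapeutic]
metadata.csv    : neonate_id, hospital, group, recording_duration_h[, start_datetime]
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from .consensus import AnnotationSet, BurdenSummary, ConsensusAnnotation, SeizureInterval
from .scoring import HourRecord, HourScore, NeonateRecord

__all__ = [
    "SchemaError",
    "ValidationReport",
    "read_annotations",
    "read_clinical",
    "read_metadata",
    "load_cohort",
    "write_consensus",
    "write_burden",
    "write_hour_scores",
    "validate_inputs",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLS = ["neonate_id", "annotator_id", "start_s", "end_s"]
CLINICAL_COLS = ["neonate_id", "hour_index", "form_marked", "asm_given"]
METADATA_COLS = ["neonate_id", "hospital", "group", "recording_duration_h"]


class SchemaError(ValueError):
    """An input file that does not match its schema."""


@dataclass
class ValidationReport:
    """Errors (fatal) and warnings (tolerated) found in the input files."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_annotations(path: str | Path) -> dict[tuple[str, str], AnnotationSet]:
    """Read an annotations CSV into per-(neonate, annotator) annotation sets."""
    df = pd.read_csv(path, dtype={"neonate_id": str, "annotator_id": str})
    _require_columns(df, ANNOTATION_COLS, path)
    out: dict[tuple[str, str], AnnotationSet] = {}
    for (nid, aid), sub in df.groupby(["neonate_id", "annotator_id"], sort=True):
        events = [
            SeizureInterval(float(r.start_s), float(r.end_s))
            for r in sub.itertuples(index=False)
        ]
        out[(nid, aid)] = AnnotationSet(neonate_id=nid, annotator_id=aid, events=events)
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"neonate_id": str})
    _require_columns(df, CLINICAL_COLS, path)
    if "asm_therapeutic" not in df.columns:
        df["asm_therapeutic"] = 1
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"neonate_id": str, "hospital": str, "group": str})
    _require_columns(df, METADATA_COLS, path)
    if "start_datetime" not in df.columns:
        df["start_datetime"] = None
    return df


def _hours_from_frame(nid: str, n_hours: int, sub: pd.DataFrame) -> list[HourRecord]:
    """Build a contiguous hour list, treating missing rows as blank (warned)."""
    by_idx = {int(r.hour_index): r for r in sub.itertuples(index=False)}
    hours: list[HourRecord] = []
    missing: list[int] = []
    for k in range(n_hours):
        r = by_idx.get(k)
        if r is None:
            missing.append(k)
            hours.append(HourRecord(hour_index=k, form_marked=False, asm_given=False))
        else:
            hours.append(
                HourRecord(
                    hour_index=k,
                    form_marked=bool(int(r.form_marked)),
                    asm_given=bool(int(r.asm_given)),
                    asm_therapeutic=bool(int(getattr(r, "asm_therapeutic", 1))),
                )
            )
    if missing:
        logger.warning(
            "neonate %s: %d missing hour row(s) treated as blank (e.g. hour %d)",
            nid, len(missing), missing[0],
        )
    return hours


def load_cohort(
    clinical: pd.DataFrame, metadata: pd.DataFrame
) -> list[NeonateRecord]:
    """Join the clinical record and metadata tables into NeonateRecord objects."""
    clin_by_nid = dict(tuple(clinical.groupby("neonate_id", sort=True)))
    records: list[NeonateRecord] = []
    for r in metadata.sort_values("neonate_id").itertuples(index=False):
        nid = r.neonate_id
        n_hours = math.ceil(float(r.recording_duration_h) - 1e-9)
        sub = clin_by_nid.get(nid, pd.DataFrame(columns=clinical.columns))
        start = None
        raw_start = getattr(r, "start_datetime", None)
        if isinstance(raw_start, str) and raw_start:
            start = datetime.fromisoformat(raw_start)
        records.append(
            NeonateRecord(
                neonate_id=nid,
                hospital=str(r.hospital),
                group=str(r.group),
                recording_duration_h=float(r.recording_duration_h),
                hours=_hours_from_frame(nid, n_hours, sub),
                start_datetime=start,
            )
        )
    return records


def write_consensus(consensus: list[ConsensusAnnotation], path: str | Path) -> None:
    rows = [
        {
            "neonate_id": c.neonate_id,
            "event_index": i,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_s": ev.duration_s,
        }
        for c in consensus
        for i, ev in enumerate(c.confirmed_events)
    ]
    pd.DataFrame(
        rows, columns=["neonate_id", "event_index", "start_s", "end_s", "duration_s"]
    ).to_csv(path, index=False)


def write_burden(summaries: list[BurdenSummary], path: str | Path) -> None:
    rows = [
        {
            "neonate_id": b.neonate_id,
            "total_burden_min": b.total_burden_min,
            "max_hourly_burden_min_per_h": b.max_hourly_burden_min_per_h,
            "median_duration_s": b.median_duration_s,
            "n_events": b.n_events,
        }
        for b in summaries
    ]
    pd.DataFrame(
        rows,
        columns=[
            "neonate_id",
            "total_burden_min",
            "max_hourly_burden_min_per_h",
            "median_duration_s",
            "n_events",
        ],
    ).to_csv(path, index=False)


def write_hour_scores(scores: list[HourScore], path: str | Path) -> None:
    rows = [
        {
            "neonate_id": s.neonate_id,
            "hour_index": s.hour_index,
            "gold_seizure_hour": int(s.gold_seizure_hour),
            "identified": "" if s.identified is None else int(s.identified),
            "false_detection": int(s.false_detection),
            "form_marked": int(s.form_marked),
            "asm_given": int(s.asm_given),
        }
        for s in scores
    ]
    pd.DataFrame(
        rows,
        columns=[
            "neonate_id",
            "hour_index",
            "gold_seizure_hour",
            "identified",
            "false_detection",
            "form_marked",
            "asm_given",
        ],
    ).to_csv(path, index=False)


def validate_inputs(
    annotations_path: str | Path,
    clinical_path: str | Path,
    metadata_path: str | Path,
) -> ValidationReport:
    """Check the three input files for schema and consistency problems.

    Errors: unreadable files, missing columns, non-positive intervals,
    duplicate (neonate, hour) rows, neonates annotated but absent from the
    metadata, annotation sets without exactly two annotators.
    Warnings: hour gaps (treated as blank downstream), events extending past
    the recording end (clipped downstream).
    """
    rep = ValidationReport()
    try:
        ann = pd.read_csv(annotations_path, dtype={"neonate_id": str, "annotator_id": str})
        clin = pd.read_csv(clinical_path, dtype={"neonate_id": str})
        meta = pd.read_csv(metadata_path, dtype={"neonate_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        rep.errors.append(f"unreadable input: {exc}")
        return rep
    for df, cols, path in (
        (ann, ANNOTATION_COLS, annotations_path),
        (clin, CLINICAL_COLS, clinical_path),
        (meta, METADATA_COLS, metadata_path),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            rep.errors.append(f"{path}: missing column(s) {missing}")
    if rep.errors:
        return rep

    bad = ann[ann["end_s"] <= ann["start_s"]]
    for i in bad.index:
        rep.errors.append(
            f"{annotations_path}: row {i}: end_s <= start_s "
            f"({ann.loc[i, 'start_s']}, {ann.loc[i, 'end_s']})"
        )
    if meta["neonate_id"].duplicated().any():
        dups = meta.loc[meta["neonate_id"].duplicated(), "neonate_id"].tolist()
        rep.errors.append(f"{metadata_path}: duplicate neonate_id(s) {dups}")
    unknown = set(ann["neonate_id"]) - set(meta["neonate_id"])
    if unknown:
        rep.errors.append(
            f"neonate(s) present in annotations but absent from metadata: {sorted(unknown)}"
        )
    unknown_clin = set(clin["neonate_id"]) - set(meta["neonate_id"])
    if unknown_clin:
        rep.errors.append(
            f"neonate(s) present in clinical record but absent from metadata: "
            f"{sorted(unknown_clin)}"
        )
    if ann["annotator_id"].nunique() > 2:
        rep.errors.append(
            f"{annotations_path}: more than two annotator ids present "
            f"({sorted(ann['annotator_id'].unique())}); exactly two are supported"
        )
    n_annot = ann.groupby("neonate_id")["annotator_id"].nunique()
    for nid, n in n_annot.items():
        if n < 2:
            rep.warnings.append(
                f"neonate {nid}: events from only {n} annotator(s); the other "
                f"annotation is treated as empty"
            )
    if clin.duplicated(subset=["neonate_id", "hour_index"]).any():
        rep.errors.append(f"{clinical_path}: duplicate (neonate_id, hour_index) rows")

    durations = meta.set_index("neonate_id")["recording_duration_h"]
    for nid, sub in clin.groupby("neonate_id"):
        if nid not in durations.index:
            continue
        n_hours = math.ceil(float(durations[nid]) - 1e-9)
        present = set(sub["hour_index"].astype(int))
        gaps = sorted(set(range(n_hours)) - present)
        if gaps:
            rep.warnings.append(
                f"neonate {nid}: {len(gaps)} hour gap(s) in clinical record "
                f"(first at hour {gaps[0]}); treated as blank"
            )
    for nid, sub in ann.groupby("neonate_id"):
        if nid not in durations.index:
            continue
        rec_end = float(durations[nid]) * 3600.0
        over = sub[sub["end_s"] > rec_end + 1e-3]
        if len(over):
            rep.warnings.append(
                f"neonate {nid}: {len(over)} annotated event(s) extend past the "
                f"recording end; clipped downstream"
            )
    return rep
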