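"""End-to-end evaluation pipeline and report assembly.

Ties the stages together: expert-annotation consensus -> hour/neonate
scoring -> cluster bootstrap accuracy statistics -> tidy result tables.
The three tables mirror the design's standard reporting: neonate-level diagnostic
accuracy (confusion counts, sensitivity, specificity, false-detection
rate), hour-level sensitivity overall and by weekday/weekend and shift, and
secondary outcomes (burden summaries, inappropriate antiseizure-medication
proportions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .consensus import (
    AnnotationSet,
    ConsensusAnnotation,
    SeizureInterval,
    build_consensus,
    burden_summary,
    is_seizure_neonate,
    seizure_hours,
)
from .io import load_cohort, read_clinical, read_metadata
from .scoring import (
    HourScore,
    classify_neonate_clinical,
    hour_strata,
    inappropriate_asm_events,
    score_hours,
)
from .stats import (
    AccuracyResult,
    BootstrapConfig,
    bc_bootstrap_ci,
    difference_ci,
    round_pct,
)

__all__ = [
    "PipelineConfig",
    "TrialReport",
    "score_cohort",
    "run_pipeline",
    "run_pipeline_files",
]

logger = logging.getLogger(__name__)

GROUPS = ("algorithm", "non_algorithm")


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration: consensus threshold, bootstrap settings, toggles."""

    min_overlap_s: float = 30.0
    n_iter: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    stratify: bool = True  # weekday/weekend and shift breakdowns (needs start times)
    bootstrap: bool = True  # compute CIs (point estimates only when off)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class TrialReport:
    """Tidy result tables plus run metadata."""

    table2: pd.DataFrame  # neonate-level accuracy
    table3: pd.DataFrame  # hour-level sensitivity, overall and stratified
    table4: pd.DataFrame  # burden summaries and inappropriate-ASM proportions
    neonates: pd.DataFrame  # one row per neonate: all scored quantities
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scoring the cohort into a per-neonate table
# ---------------------------------------------------------------------------

def _consensus_from_frame(
    annotations: pd.DataFrame, metadata: pd.DataFrame, min_overlap_s: float
) -> dict[str, ConsensusAnnotation]:
    annotator_ids = sorted(annotations["annotator_id"].unique()) if len(annotations) else []
    if len(annotator_ids) > 2:
        raise ValueError(
            f"more than two annotators present: {annotator_ids}; exactly two are supported"
        )
    while len(annotator_ids) < 2:
        annotator_ids.append(f"__empty{len(annotator_ids)}")
    by_key: dict[tuple[str, str], list[SeizureInterval]] = {}
    for r in annotations.itertuples(index=False):
        by_key.setdefault((r.neonate_id, r.annotator_id), []).append(
            SeizureInterval(float(r.start_s), float(r.end_s))
        )
    out: dict[str, ConsensusAnnotation] = {}
    for r in metadata.itertuples(index=False):
        nid = r.neonate_id
        a = AnnotationSet(nid, annotator_ids[0], by_key.get((nid, annotator_ids[0]), []))
        b = AnnotationSet(nid, annotator_ids[1], by_key.get((nid, annotator_ids[1]), []))
        out[nid] = build_consensus(
            a,
            b,
            recording_duration_h=float(r.recording_duration_h),
            min_overlap_s=min_overlap_s,
        )
    return out


def score_cohort(
    annotations: pd.DataFrame,
    clinical: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    min_overlap_s: float = 30.0,
) -> tuple[pd.DataFrame, dict[str, ConsensusAnnotation], list[HourScore]]:
    """Score every neonate, returning the per-neonate table used by the bootstrap.

    The table has one row per neonate with the gold and clinical
    classifications, hour-level counts (overall and per calendar stratum
    when a start time is known), burden summaries and the
    inappropriate-ASM assessment.  Resampling rows of this table therefore
    resamples whole neonates, which is what the cluster bootstrap requires.
    """
    consensus = _consensus_from_frame(annotations, metadata, min_overlap_s)
    records = load_cohort(clinical, metadata)
    rows: list[dict] = []
    all_scores: list[HourScore] = []
    for rec in records:
        cons = consensus[rec.neonate_id]
        gold_hours = seizure_hours(cons)
        scores = score_hours(rec, gold_hours)
        all_scores.extend(scores)
        burden = burden_summary(cons)
        asm = inappropriate_asm_events(rec, gold_hours)
        strata = (
            hour_strata(rec.start_datetime, len(rec.hours))
            if rec.start_datetime is not None
            else None
        )
        counts = {
            f"{pre}_{key}": 0
            for pre in ("n_gold", "n_ident", "n_marked", "n_false")
            for key in ("all", "weekday", "weekend", "day", "night")
        }
        for s in scores:
            keys = ["all"]
            if strata is not None:
                day, shift = strata[s.hour_index]
                keys += [day, shift]
            for key in keys:
                if s.gold_seizure_hour:
                    counts[f"n_gold_{key}"] += 1
                    if s.identified:
                        counts[f"n_ident_{key}"] += 1
                if s.form_marked:
                    counts[f"n_marked_{key}"] += 1
                if s.false_detection:
                    counts[f"n_false_{key}"] += 1
        rows.append(
            {
                "neonate_id": rec.neonate_id,
                "group": rec.group,
                "hospital": rec.hospital,
                "gold": int(is_seizure_neonate(cons)),
                "clin": int(classify_neonate_clinical(rec)),
                **counts,
                "any_inappropriate_asm": int(asm.any_inappropriate),
                "n_inappropriate_asm": asm.n_inappropriate,
                "total_burden_min": burden.total_burden_min,
                "max_hourly_burden_min_per_h": burden.max_hourly_burden_min_per_h,
                "median_duration_s": burden.median_duration_s,
                "n_events": burden.n_events,
                "has_start_datetime": int(rec.start_datetime is not None),
            }
        )
    return pd.DataFrame(rows), consensus, all_scores


# ---------------------------------------------------------------------------
# per-neonate-table statistics (each total on any resample, None if undefined)
# ---------------------------------------------------------------------------

def stat_sensitivity(df: pd.DataFrame) -> float | None:
    d = int((df["gold"] == 1).sum())
    return None if d == 0 else 100.0 * int(((df["gold"] == 1) & (df["clin"] == 1)).sum()) / d


def stat_specificity(df: pd.DataFrame) -> float | None:
    d = int((df["gold"] == 0).sum())
    return None if d == 0 else 100.0 * int(((df["gold"] == 0) & (df["clin"] == 0)).sum()) / d


def stat_false_detection_rate(df: pd.DataFrame) -> float | None:
    d = int((df["clin"] == 1).sum())
    return None if d == 0 else 100.0 * int(((df["clin"] == 1) & (df["gold"] == 0)).sum()) / d


def make_hour_sensitivity_stat(stratum: str = "all"):
    """Hour-level sensitivity (ratio of pooled counts) within a calendar stratum."""

    num, den = f"n_ident_{stratum}", f"n_gold_{stratum}"

    def stat(df: pd.DataFrame) -> float | None:
        d = int(df[den].sum())
        return None if d == 0 else 100.0 * int(df[num].sum()) / d

    return stat


def make_form_fdr_stat(stratum: str = "all"):
    num, den = f"n_false_{stratum}", f"n_marked_{stratum}"

    def stat(df: pd.DataFrame) -> float | None:
        d = int(df[den].sum())
        return None if d == 0 else 100.0 * int(df[num].sum()) / d

    return stat


def stat_inappropriate_asm(df: pd.DataFrame) -> float | None:
    return None if len(df) == 0 else 100.0 * int(df["any_inappropriate_asm"].sum()) / len(df)


def _median_stat(col: str):
    def stat(df: pd.DataFrame) -> float | None:
        vals = df[col].dropna()
        return None if len(vals) == 0 else float(np.median(vals))

    return stat


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _ci_or_point(
    stat_fn, df: pd.DataFrame, config: PipelineConfig, label: str, seed_offset: int
) -> AccuracyResult:
    if config.bootstrap:
        bcfg = BootstrapConfig(
            n_iter=config.n_iter, alpha=config.alpha, seed=config.seed + seed_offset
        )
        return bc_bootstrap_ci(stat_fn, df, bcfg, label=label)
    v = stat_fn(df)
    if v is None:
        v = float("nan")
    return AccuracyResult(label=label, estimate=float(v), ci_low=float("nan"), ci_high=float("nan"))


def _diff_or_point(
    stat_fn, df_a: pd.DataFrame, df_b: pd.DataFrame, config: PipelineConfig,
    label: str, seed_offset: int,
) -> AccuracyResult:
    if config.bootstrap:
        bcfg = BootstrapConfig(
            n_iter=config.n_iter, alpha=config.alpha, seed=config.seed + seed_offset
        )
        return difference_ci(stat_fn, df_a, df_b, bcfg, label=label)
    va, vb = stat_fn(df_a), stat_fn(df_b)
    est = float("nan") if va is None or vb is None else float(va) - float(vb)
    return AccuracyResult(label=label, estimate=est, ci_low=float("nan"), ci_high=float("nan"))


def _result_row(res: AccuracyResult, group: str, num=None, den=None) -> dict:
    return {
        "metric": res.label,
        "group": group,
        "estimate": round_pct(res.estimate),
        "ci_low": round_pct(res.ci_low) if np.isfinite(res.ci_low) else None,
        "ci_high": round_pct(res.ci_high) if np.isfinite(res.ci_high) else None,
        "n_num": num,
        "n_den": den,
    }


def run_pipeline(
    annotations: pd.DataFrame,
    clinical: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> TrialReport:
    """Run consensus, scoring and statistics on in-memory input tables."""
    config = config or PipelineConfig()
    neonates, _, _ = score_cohort(
        annotations, clinical, metadata, min_overlap_s=config.min_overlap_s
    )
    by_group = {g: neonates[neonates["group"] == g].reset_index(drop=True) for g in GROUPS}
    for g, df in by_group.items():
        if len(df) == 0:
            raise ValueError(f"no neonates in group {g!r}")

    # --- neonate-level accuracy ------------------------------------------
    t2_rows: list[dict] = []
    offset = 0
    for g, df in by_group.items():
        tp = int(((df["gold"] == 1) & (df["clin"] == 1)).sum())
        fn = int(((df["gold"] == 1) & (df["clin"] == 0)).sum())
        tn = int(((df["gold"] == 0) & (df["clin"] == 0)).sum())
        fp = int(((df["gold"] == 0) & (df["clin"] == 1)).sum())
        for name, n in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
            t2_rows.append({"metric": name, "group": g, "estimate": n,
                            "ci_low": None, "ci_high": None, "n_num": None, "n_den": None})
        for stat, label, num, den in (
            (stat_sensitivity, "sensitivity", tp, tp + fn),
            (stat_specificity, "specificity", tn, tn + fp),
            (stat_false_detection_rate, "false_detection_rate", fp, fp + tp),
        ):
            offset += 1
            res = _ci_or_point(stat, df, config, label, offset)
            t2_rows.append(_result_row(res, g, num, den))
    for stat, label in (
        (stat_sensitivity, "sensitivity"),
        (stat_specificity, "specificity"),
        (stat_false_detection_rate, "false_detection_rate"),
    ):
        offset += 1
        res = _diff_or_point(stat, by_group[GROUPS[0]], by_group[GROUPS[1]],
                             config, f"{label}_difference", offset)
        t2_rows.append(_result_row(res, "difference"))
    table2 = pd.DataFrame(t2_rows)

    # --- hour-level sensitivity, overall and stratified ------------------
    strata = ["all"]
    if config.stratify and bool(neonates["has_start_datetime"].all()):
        strata += ["weekday", "weekend", "day", "night"]
    elif config.stratify:
        logger.warning("start_datetime missing for some neonates; skipping stratification")
    t3_rows: list[dict] = []
    for stratum in strata:
        stat = make_hour_sensitivity_stat(stratum)
        for g, df in by_group.items():
            offset += 1
            res = _ci_or_point(stat, df, config, f"hour_sensitivity_{stratum}", offset)
            t3_rows.append(
                _result_row(res, g, int(df[f"n_ident_{stratum}"].sum()),
                            int(df[f"n_gold_{stratum}"].sum()))
            )
        offset += 1
        res = _diff_or_point(stat, by_group[GROUPS[0]], by_group[GROUPS[1]],
                             config, f"hour_sensitivity_{stratum}_difference", offset)
        t3_rows.append(_result_row(res, "difference"))
    fdr_stat = make_form_fdr_stat("all")
    for g, df in by_group.items():
        offset += 1
        res = _ci_or_point(fdr_stat, df, config, "form_false_detection_rate", offset)
        t3_rows.append(
            _result_row(res, g, int(df["n_false_all"].sum()), int(df["n_marked_all"].sum()))
        )
    offset += 1
    res = _diff_or_point(fdr_stat, by_group[GROUPS[0]], by_group[GROUPS[1]],
                         config, "form_false_detection_rate_difference", offset)
    t3_rows.append(_result_row(res, "difference"))
    table3 = pd.DataFrame(t3_rows)

    # --- secondary outcomes ----------------------------------------------
    t4_rows: list[dict] = []
    for g, df in by_group.items():
        sz = df[df["gold"] == 1].reset_index(drop=True)
        nsz = df[df["gold"] == 0].reset_index(drop=True)
        for col, label in (
            ("total_burden_min", "median_total_burden_min"),
            ("max_hourly_burden_min_per_h", "median_max_hourly_burden_min_per_h"),
            ("median_duration_s", "median_seizure_duration_s"),
        ):
            offset += 1
            if len(sz):
                res = _ci_or_point(_median_stat(col), sz, config, label, offset)
                row = _result_row(res, g, None, len(sz))
                row["estimate"] = res.estimate  # medians reported unrounded
                row["ci_low"], row["ci_high"] = res.ci_low, res.ci_high
                t4_rows.append(row)
        for sub, label in (
            (sz, "inappropriate_asm_seizure_neonates"),
            (nsz, "inappropriate_asm_non_seizure_neonates"),
        ):
            offset += 1
            if len(sub):
                res = _ci_or_point(stat_inappropriate_asm, sub, config, label, offset)
                t4_rows.append(
                    _result_row(res, g, int(sub["any_inappropriate_asm"].sum()), len(sub))
                )
    table4 = pd.DataFrame(t4_rows)

    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_iter": config.n_iter if config.bootstrap else 0,
        "version": __version__,
        "n_neonates": {g: int(len(df)) for g, df in by_group.items()},
        "interaction_caveat": (
            "hour-level models treat hours as independent; within-infant "
            "clustering is handled by the cluster bootstrap, not the interaction fit"
        ),
    }
    return TrialReport(table2=table2, table3=table3, table4=table4,
                       neonates=neonates, metadata=meta)


def run_pipeline_files(
    annotations_path: str | Path,
    clinical_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> TrialReport:
    """Run the pipeline from CSV files, optionally writing the report tables.

    Writes ``table2.csv``, ``table3.csv``, ``table4.csv``, ``neonates.csv``
    and ``report.json`` under ``out_dir`` when given.
    """
    annotations = pd.read_csv(annotations_path, dtype={"neonate_id": str, "annotator_id": str})
    clinical = read_clinical(clinical_path)
    metadata = read_metadata(metadata_path)
    report = run_pipeline(annotations, clinical, metadata, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.table2.to_csv(out / "table2.csv", index=False)
        report.table3.to_csv(out / "table3.csv", index=False)
        report.table4.to_csv(out / "table4.csv", index=False)
        report.neonates.to_csv(out / "neonates.csv", index=False)
        payload = {
            "metadata": report.metadata,
            "table2": report.table2.to_dict(orient="records"),
            "table3": report.table3.to_dict(orient="records"),
            "table4": report.table4.to_dict(orient="records"),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=str))
        logger.info("report written to %s (config %s, seed %d)",
                    out, report.metadata["config_hash"], report.metadata["seed"])
    return report
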