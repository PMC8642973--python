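"""End-to-end orchestration: parse -> harmonize -> overlap -> reconcile ->
prioritize -> filter/rescue -> annotate -> report.

Runs are incremental: each successfully parsed caller file is cached as a
canonical unified-calls TSV under ``<out_dir>/unified/``, and the overlap
always consumes every cached caller.  Re-running with only a newly
finished caller's file therefore updates the consensus exactly as if all
callers had been supplied at once.  A caller file that fails to parse is
skipped with a warning and the run continues on the remaining callers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

from . import caller_io
from .ensemble import overlap_calls, prioritize, reconcile_breakpoints
from .filters import FilterConfig, FilterDecision, apply_filters
from .freqdb import CohortFrequencyStore
from .harmonize import harmonize_calls, load_alias_table
from .knowledgebase import (
    KnownFusionList,
    annotate_known,
    extract_singletons,
    load_known_list,
)
from .models import (
    CALLERS,
    ConfigurationError,
    FusembleError,
    OverlapRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Documented column order of the filtered/unfiltered report TSVs.
REPORT_COLUMNS = [
    "pair",
    "gene5",
    "gene3",
    "caller_count",
    "callers",
    "max_reads",
    "per_caller_reads",
    "chrom5",
    "pos5",
    "strand5",
    "chrom3",
    "pos3",
    "strand3",
    "breakpoint_distance",
    "junction_seq",
    "frame",
    "orientations",
    "cohort_frequency",
    "known_pair",
    "partner5_known",
    "partner5_score",
    "partner5_type",
    "partner3_known",
    "partner3_score",
    "partner3_type",
]

SINGLETON_COLUMNS = REPORT_COLUMNS + ["channel"]

AUDIT_COLUMNS = [
    "pair",
    "caller_count",
    "max_reads",
    "kept",
    "reasons",
    "rescued_by_known_list",
]


@dataclass
class PipelineConfig:
    caller_files: Mapping[str, PathLike]
    out_dir: PathLike
    sample_id: str = "sample"
    filters: FilterConfig = field(default_factory=FilterConfig)
    known_list: Optional[PathLike] = None
    alias_table: Optional[PathLike] = None
    freq_db: Optional[PathLike] = None


@dataclass
class EnsembleReport:
    filtered: List[OverlapRecord]
    unfiltered: List[OverlapRecord]
    singletons: List[OverlapRecord]
    audit: List[FilterDecision]


def run_pipeline(config: PipelineConfig) -> EnsembleReport:
    out_dir = Path(config.out_dir)
    unified_dir = out_dir / "unified"
    unified_dir.mkdir(parents=True, exist_ok=True)

    for caller in config.caller_files:
        if caller not in CALLERS:
            raise ConfigurationError(f"unknown caller {caller!r} in config")
    if not config.caller_files and not any(unified_dir.glob("*.tsv")):
        raise ConfigurationError("at least one caller file is required")

    for caller, path in sorted(config.caller_files.items()):
        try:
            calls = caller_io.parse_caller_output(path, caller)
        except (FusembleError, OSError) as exc:
            logger.warning("skipping %s output %s: %s", caller, path, exc)
            continue
        caller_io.write_unified_calls(calls, unified_dir / f"{caller}.tsv")
        logger.info("%s: parsed %d call(s)", caller, len(calls))

    calls_by_caller: Dict[str, List] = {}
    for path in sorted(unified_dir.glob("*.tsv")):
        calls_by_caller[path.stem] = caller_io.read_unified_calls(path)
    if not calls_by_caller:
        raise ConfigurationError("no caller output could be parsed")
    if config.filters.min_callers > len(calls_by_caller):
        raise ConfigurationError(
            f"min_callers={config.filters.min_callers} exceeds the "
            f"{len(calls_by_caller)} available caller(s)"
        )

    table = load_alias_table(config.alias_table)
    known = load_known_list(config.known_list)
    if config.freq_db and Path(config.freq_db).exists():
        store = CohortFrequencyStore.load(config.freq_db)
    else:
        store = CohortFrequencyStore()

    harmonized = {
        caller: harmonize_calls(calls, table)
        for caller, calls in calls_by_caller.items()
    }
    records = prioritize(
        [reconcile_breakpoints(r) for r in overlap_calls(harmonized)]
    )
    for record in records:
        record.annotations["cohort_frequency"] = store.frequency(record.key)
    annotate_known(records, known)

    kept, decisions = apply_filters(records, store, known, config.filters)
    kept_keys = {r.key for r in kept}
    singletons = [
        r for r in extract_singletons(records, known) if r.key not in kept_keys
    ]

    logger.info(
        "sample %s: %d consensus record(s), %d kept, %d rescued, %d singleton(s)",
        config.sample_id,
        len(records),
        len(kept),
        sum(1 for d in decisions if d.rescued_by_known_list and d.kept),
        len(singletons),
    )
    report = EnsembleReport(
        filtered=kept, unfiltered=records, singletons=singletons, audit=decisions
    )
    write_report(report, out_dir)
    return report


def registration_pairs(report: EnsembleReport, min_callers: int = 2) -> List:
    """Pairs to feed the cohort frequency store for one sample: the
    unfiltered consensus at the given caller threshold (artifact
    filtering must get to see artifacts, so this is pre-filter)."""
    return [r.key for r in report.unfiltered if r.caller_count >= min_callers]


def write_report(report: EnsembleReport, outdir: PathLike) -> Dict[str, Path]:
    """Write the four report TSVs; byte-stable for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "filtered": outdir / "filtered.tsv",
        "unfiltered": outdir / "unfiltered.tsv",
        "singletons": outdir / "singletons.tsv",
        "audit": outdir / "audit.tsv",
    }
    _write_records(report.filtered, paths["filtered"], REPORT_COLUMNS)
    _write_records(report.unfiltered, paths["unfiltered"], REPORT_COLUMNS)
    _write_records(
        report.singletons, paths["singletons"], SINGLETON_COLUMNS, channel="singleton"
    )
    with paths["audit"].open("w", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=AUDIT_COLUMNS, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for decision in report.audit:
            writer.writerow(
                {
                    "pair": decision.record.label,
                    "caller_count": decision.record.caller_count,
                    "max_reads": decision.record.max_reads,
                    "kept": str(decision.kept).lower(),
                    "reasons": ",".join(sorted(decision.reasons)),
                    "rescued_by_known_list": str(decision.rescued_by_known_list).lower(),
                }
            )
    return paths


def _write_records(
    records: Sequence[OverlapRecord],
    path: Path,
    columns: Sequence[str],
    channel: Optional[str] = None,
) -> None:
    with path.open("w", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=list(columns), delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for record in records:
            row = _record_row(record)
            if channel is not None:
                row["channel"] = channel
            writer.writerow(row)


def _record_row(record: OverlapRecord) -> Dict[str, str]:
    best = record.best_call
    if best is None:
        raise ValueError(f"record {record.label} was not reconciled")
    distance = (
        str(abs(best.pos5 - best.pos3)) if best.chrom5 == best.chrom3 else ""
    )
    per_caller_reads = ";".join(
        f"{caller}:{max(c.reads for c in record.per_caller[caller])}"
        for caller in sorted(record.per_caller)
    )
    partners = record.annotations.get("partners", {})
    p5 = partners.get(best.gene5)
    p3 = partners.get(best.gene3)
    freq = record.annotations.get("cohort_frequency", 0.0)
    return {
        "pair": record.label,
        "gene5": best.gene5,
        "gene3": best.gene3,
        "caller_count": str(record.caller_count),
        "callers": ",".join(sorted(record.per_caller)),
        "max_reads": str(record.max_reads),
        "per_caller_reads": per_caller_reads,
        "chrom5": best.chrom5,
        "pos5": str(best.pos5),
        "strand5": best.strand5,
        "chrom3": best.chrom3,
        "pos3": str(best.pos3),
        "strand3": best.strand3,
        "breakpoint_distance": distance,
        "junction_seq": best.junction_seq or "",
        "frame": best.frame or "",
        "orientations": "|".join(
            f"{g5}>{g3}" for g5, g3 in sorted(record.orientations)
        ),
        "cohort_frequency": f"{freq:.6g}",
        "known_pair": str(bool(record.annotations.get("known_pair", False))).lower(),
        "partner5_known": _fmt(p5, "is_known_partner"),
        "partner5_score": _fmt(p5, "frequency_score"),
        "partner5_type": _fmt(p5, "gene_type"),
        "partner3_known": _fmt(p3, "is_known_partner"),
        "partner3_score": _fmt(p3, "frequency_score"),
        "partner3_type": _fmt(p3, "gene_type"),
    }


def _fmt(annotation, attr: str) -> str:
    if annotation is None:
        return ""
    value = getattr(annotation, attr)
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    return str(value)
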