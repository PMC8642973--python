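"""Scoring pipeline output against a truth set, and consensus-threshold
ablation sweeps.

Sensitivity is true pairs recovered over all true pairs; precision is
true pairs recovered over all pairs reported.  Matching is by unordered
gene pair after harmonization — counts are per fusion, not per isoform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Union

from .ensemble import overlap_calls, prioritize, reconcile_breakpoints
from .filters import FilterConfig, apply_filters
from .freqdb import CohortFrequencyStore
from .knowledgebase import KnownFusionList
from .models import FormatError, GenePairKey, OverlapRecord, pair_key

PathLike = Union[str, Path]


@dataclass(frozen=True)
class TruthSet:
    true_pairs: FrozenSet[GenePairKey]
    label: str = "truth"

    @classmethod
    def from_pairs(cls, pairs: Sequence, label: str = "truth") -> "TruthSet":
        return cls(frozenset(pair_key(a, b) for a, b in pairs), label=label)


def load_truth_set(path: PathLike, label: Optional[str] = None) -> TruthSet:
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("gene_a\t"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        if len(fields) < 2:
            raise FormatError(f"truth set line {lineno}: expected two genes")
        pairs.append((fields[0].strip(), fields[1].strip()))
    return TruthSet.from_pairs(pairs, label=label or Path(path).stem)


@dataclass(frozen=True)
class BenchmarkResult:
    n_total_identified: float
    n_true_identified: float
    sensitivity: float
    precision: float
    precision_defined: bool = True


def sensitivity(n_true_identified: float, n_possible: float) -> float:
    if n_possible <= 0:
        raise ValueError("sensitivity undefined for an empty truth set")
    return n_true_identified / n_possible


def precision(n_true_identified: float, n_total_identified: float) -> float:
    """True identified over total identified; 0 when nothing was identified
    (callers must check ``n_total_identified > 0`` for definedness)."""
    if n_total_identified <= 0:
        return 0.0
    return n_true_identified / n_total_identified


def score_against_truth(
    identified: Sequence[OverlapRecord], truth: TruthSet
) -> BenchmarkResult:
    """Score a set of consensus records against the truth pairs."""
    if not truth.true_pairs:
        raise ValueError("truth set must be non-empty")
    found = {r.key for r in identified}
    n_true = len(truth.true_pairs & found)
    n_total = len(found)
    return BenchmarkResult(
        n_total_identified=n_total,
        n_true_identified=n_true,
        sensitivity=sensitivity(n_true, len(truth.true_pairs)),
        precision=precision(n_true, n_total),
        precision_defined=n_total > 0,
    )


def consensus_sweep(
    replicates: Sequence[Dict[str, Sequence]],
    store: CohortFrequencyStore,
    known: KnownFusionList,
    thresholds: Sequence[int],
    truth: TruthSet,
    base_cfg: Optional[FilterConfig] = None,
) -> List[dict]:
    """Ablation grid over consensus thresholds x {no filter, filter,
    filter + known list}, per replicate plus replicate means.

    ``replicates`` is a list of caller->calls mappings (one per technical
    replicate); the mean rows average total/true counts across replicates.
    """
    base_cfg = base_cfg or FilterConfig()
    empty_known = KnownFusionList.from_pairs([])
    rows: List[dict] = []

    per_rep_records = []
    for calls_by_caller in replicates:
        records = prioritize(
            [reconcile_breakpoints(r) for r in overlap_calls(calls_by_caller)]
        )
        per_rep_records.append(records)

    for t in thresholds:
        for filtering, use_known in ((False, False), (True, False), (True, True)):
            config_label = f"consensus>={t}"
            if filtering:
                config_label += "+filter"
            if use_known:
                config_label += "+known-list"
            rep_results: List[BenchmarkResult] = []
            for rep_idx, records in enumerate(per_rep_records, start=1):
                if filtering:
                    cfg = FilterConfig(
                        min_callers=t,
                        readthrough_max_distance=base_cfg.readthrough_max_distance,
                        max_cohort_frequency=base_cfg.max_cohort_frequency,
                        min_reads=base_cfg.min_reads,
                        known_list_min_callers=min(
                            base_cfg.known_list_min_callers, t
                        ),
                    )
                    identified, _ = apply_filters(
                        records, store, known if use_known else empty_known, cfg
                    )
                else:
                    identified = [r for r in records if r.caller_count >= t]
                result = score_against_truth(identified, truth)
                rep_results.append(result)
                rows.append(_sweep_row(config_label, str(rep_idx), result))
            if len(rep_results) > 1:
                n = len(rep_results)
                mean_total = sum(r.n_total_identified for r in rep_results) / n
                mean_true = sum(r.n_true_identified for r in rep_results) / n
                mean = BenchmarkResult(
                    n_total_identified=mean_total,
                    n_true_identified=mean_true,
                    sensitivity=sensitivity(mean_true, len(truth.true_pairs)),
                    precision=precision(mean_true, mean_total),
                    precision_defined=mean_total > 0,
                )
                rows.append(_sweep_row(config_label, "mean", mean))
    return rows


def _sweep_row(config: str, replicate: str, result: BenchmarkResult) -> dict:
    return {
        "configuration": config,
        "replicate": replicate,
        "n_total_identified": result.n_total_identified,
        "n_true_identified": result.n_true_identified,
        "sensitivity": result.sensitivity,
        "precision": result.precision,
    }


def write_sweep(rows: Sequence[dict], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    columns = [
        "configuration",
        "replicate",
        "n_total_identified",
        "n_true_identified",
        "sensitivity",
        "precision",
    ]
    with path.open("w", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=columns, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for row in rows:
            out = dict(row)
            out["sensitivity"] = f"{row['sensitivity']:.4f}"
            out["precision"] = f"{row['precision']:.4f}"
            writer.writerow(out)
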