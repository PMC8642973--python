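"""Knowledge-based filtering of consensus fusion records.

Three removal rules plus the consensus threshold, with known-fusion-list
rescue layered on top:

* read-through: same chromosome, same (known) strand, breakpoints fewer
  than 200 kb apart — classic transcription read-through artifacts;
* high cohort frequency: the pair was called in more than 10% of cohort
  samples — recurrent artifacts and benign events;
* low evidence: no contributing caller supplies at least four reads.

All thresholds are literal strict comparisons.  A pair on the known
fusion list is kept despite any failed rule as long as at least
``known_list_min_callers`` callers support it; every removal records its
reasons for the audit channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

from .freqdb import CohortFrequencyStore
from .knowledgebase import KnownFusionList
from .models import STRAND_UNKNOWN, ConfigurationError, OverlapRecord

REASON_BELOW_CONSENSUS = "below-consensus"
REASON_READTHROUGH = "read-through"
REASON_HIGH_FREQUENCY = "high-frequency"
REASON_LOW_EVIDENCE = "low-evidence"


@dataclass(frozen=True)
class FilterConfig:
    min_callers: int = 3
    readthrough_max_distance: int = 200_000
    max_cohort_frequency: float = 0.10
    min_reads: int = 4
    known_list_min_callers: int = 2

    def __post_init__(self) -> None:
        for name in (
            "min_callers",
            "readthrough_max_distance",
            "max_cohort_frequency",
            "min_reads",
            "known_list_min_callers",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.known_list_min_callers > self.min_callers:
            raise ConfigurationError(
                "known_list_min_callers must not exceed min_callers"
            )


@dataclass
class FilterDecision:
    """Audit-trail entry for one record: kept or removed, and why."""

    record: OverlapRecord
    kept: bool
    reasons: Set[str] = field(default_factory=set)
    rescued_by_known_list: bool = False


def is_readthrough(record: OverlapRecord, cfg: FilterConfig) -> bool:
    """True iff the reconciled breakpoints look like a read-through event.

    Unknown strand on either side can never assert "same strand", so it
    conservatively retains the record.
    """
    bp = record.best_breakpoints
    if bp is None:
        raise ValueError("record breakpoints not reconciled")
    chrom5, pos5, chrom3, pos3, strand5, strand3 = bp
    if chrom5 != chrom3:
        return False
    if STRAND_UNKNOWN in (strand5, strand3) or strand5 != strand3:
        return False
    return abs(pos5 - pos3) < cfg.readthrough_max_distance


def is_high_frequency(
    record: OverlapRecord, store: CohortFrequencyStore, cfg: FilterConfig
) -> bool:
    """True iff cohort detection frequency strictly exceeds the threshold
    (a pair at exactly the threshold is retained; unseen pairs are 0)."""
    return store.frequency(record.key) > cfg.max_cohort_frequency


def is_low_evidence(record: OverlapRecord, cfg: FilterConfig) -> bool:
    """True iff no contributing caller supplies at least ``min_reads`` reads."""
    return record.max_reads < cfg.min_reads


def apply_filters(
    records: Sequence[OverlapRecord],
    store: CohortFrequencyStore,
    known: KnownFusionList,
    cfg: FilterConfig,
) -> Tuple[List[OverlapRecord], List[FilterDecision]]:
    """Partition records into kept and removed, with full audit decisions.

    kept iff (enough callers AND no removal rule fires) OR (pair on the
    known list AND callers >= known_list_min_callers).  Rescue overrides
    every rule, including the consensus threshold.
    """
    kept: List[OverlapRecord] = []
    decisions: List[FilterDecision] = []
    for record in records:
        reasons: Set[str] = set()
        if record.caller_count < cfg.min_callers:
            reasons.add(REASON_BELOW_CONSENSUS)
        if is_readthrough(record, cfg):
            reasons.add(REASON_READTHROUGH)
        if is_high_frequency(record, store, cfg):
            reasons.add(REASON_HIGH_FREQUENCY)
        if is_low_evidence(record, cfg):
            reasons.add(REASON_LOW_EVIDENCE)

        rescued = bool(reasons) and known.contains(record.key) and (
            record.caller_count >= cfg.known_list_min_callers
        )
        keep = not reasons or rescued
        decisions.append(
            FilterDecision(
                record=record, kept=keep, reasons=reasons, rescued_by_known_list=rescued
            )
        )
        if keep:
            kept.append(record)
    return kept, decisions
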