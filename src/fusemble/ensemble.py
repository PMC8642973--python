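"""Overlap harmonized calls across callers on unordered gene pairs.

Keying on the unordered pair lets the same fusion match even when callers
disagree on breakpoints, and merges reciprocal orientations into one
consensus record.  Discordant breakpoints are reconciled by read support,
with a deterministic tie-break cascade so output is reproducible
byte-for-byte.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

from .models import (
    ConfigurationError,
    FusionCall,
    OverlapRecord,
    pair_key,
)

CallsByCaller = Union[
    Mapping[str, Sequence[FusionCall]],
    Iterable[Tuple[str, Sequence[FusionCall]]],
]


def overlap_calls(calls_by_caller: CallsByCaller) -> List[OverlapRecord]:
    """Group all calls into one record per distinct unordered gene pair.

    A caller contributing several isoform calls for the same pair keeps
    all of them in ``per_caller`` but counts once toward the consensus.
    Output order is deterministic (sorted by pair key) regardless of the
    order of the input mapping or rows.
    """
    items = (
        list(calls_by_caller.items())
        if isinstance(calls_by_caller, Mapping)
        else list(calls_by_caller)
    )
    seen = set()
    for caller, _ in items:
        if caller in seen:
            raise ConfigurationError(f"duplicate caller key {caller!r} in input")
        seen.add(caller)

    records: Dict[Tuple[str, ...], OverlapRecord] = {}
    for caller, calls in sorted(items):
        for call in calls:
            if call.caller != caller:
                raise ConfigurationError(
                    f"call by {call.caller!r} filed under caller key {caller!r}"
                )
            key = pair_key(call.gene5, call.gene3)
            rec = records.setdefault(key, OverlapRecord(key=key))
            rec.per_caller.setdefault(caller, []).append(call)
            rec.orientations.add((call.gene5, call.gene3))
    return [records[k] for k in sorted(records)]


def reconcile_breakpoints(record: OverlapRecord) -> OverlapRecord:
    """Choose the record's best breakpoint pair by read support.

    Among the calls with maximal reads, prefer the breakpoint pair backed
    by the most distinct callers (counted over all calls in the record);
    remaining ties fall to the lexicographically smallest
    (chrom5, pos5, chrom3, pos3, strand5, strand3).  All candidate
    breakpoints stay available in ``per_caller``.
    """
    calls = list(record.calls())
    if not calls:
        raise ValueError("cannot reconcile an empty record")

    supporters: Dict[Tuple, set] = {}
    for call in calls:
        supporters.setdefault(_bp(call), set()).add(call.caller)

    best_reads = max(c.reads for c in calls)
    candidates = [c for c in calls if c.reads == best_reads]
    record.best_call = min(
        candidates, key=lambda c: (-len(supporters[_bp(c)]), c.breakpoints)
    )
    return record


def _bp(call: FusionCall) -> Tuple[str, int, str, int]:
    return (call.chrom5, call.pos5, call.chrom3, call.pos3)


def prioritize(records: Sequence[OverlapRecord]) -> List[OverlapRecord]:
    """Stable sort: callers desc, then max reads desc, then pair key asc."""
    return sorted(records, key=lambda r: (-r.caller_count, -r.max_reads, r.key))
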