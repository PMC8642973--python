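"""Core domain model shared by every stage of the ensemble pipeline.

A :class:`FusionCall` is one caller's prediction of one fusion, already
normalized to a single coordinate and chromosome namespace.  An
:class:`OverlapRecord` is the consensus view of one unordered gene pair
across callers.  Both are plain dataclasses so they stay cheap to copy,
hash and compare in tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

#: Callers whose native output dialects are supported, in canonical order.
CALLERS: Tuple[str, ...] = (
    "arriba",
    "cicero",
    "fusioncatcher",
    "fusionmap",
    "jaffa",
    "mapsplice",
    "starfusion",
)

STRAND_UNKNOWN = "."
STRANDS: Tuple[str, ...] = ("+", "-", STRAND_UNKNOWN)

FRAME_IN = "in-frame"
FRAME_OUT = "out-of-frame"
FRAME_UNKNOWN = "unknown"
FRAMES: Tuple[str, ...] = (FRAME_IN, FRAME_OUT, FRAME_UNKNOWN)


class FusembleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FusembleError):
    """Invalid configuration: unknown caller, inconsistent thresholds, ..."""


class FormatError(FusembleError):
    """A file does not match its declared dialect or schema."""


_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


def normalize_chrom(raw: str) -> str:
    """Map chromosome names onto a single namespace: no ``chr`` prefix,
    mitochondrial as ``MT``, sex chromosomes upper-case."""
    c = _CHR_PREFIX.sub("", str(raw).strip())
    if c.upper() in ("M", "MT"):
        return "MT"
    if c.lower() in ("x", "y"):
        return c.upper()
    return c


GenePairKey = Tuple[str, ...]


def pair_key(gene_a: str, gene_b: str) -> GenePairKey:
    """Unordered gene-pair key: ``pair_key(a, b) == pair_key(b, a)``.

    Self-fusions collapse to a singleton tuple.
    """
    return tuple(sorted({gene_a, gene_b}))


def pair_label(key: GenePairKey) -> str:
    return "--".join(key)


# (chrom5, pos5, chrom3, pos3, strand5, strand3)
Breakpoints = Tuple[str, int, str, int, str, str]


@dataclass(frozen=True)
class FusionCall:
    """One caller's prediction of one fusion.

    Coordinates are 1-based, fully closed; chromosomes are normalized.
    ``reads`` is the caller's primary evidence count; when the dialect
    distinguishes split reads and spanning pairs, ``reads`` is their sum.
    """

    caller: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    reads: int
    split_reads: Optional[int] = None
    spanning_pairs: Optional[int] = None
    junction_seq: Optional[str] = None
    frame: Optional[str] = None

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ConfigurationError(f"unknown caller {self.caller!r}")
        if self.reads < 0:
            raise ValueError(f"reads must be >= 0, got {self.reads}")
        if self.pos5 < 1 or self.pos3 < 1:
            raise ValueError("breakpoint positions are 1-based (>= 1)")
        if self.strand5 not in STRANDS or self.strand3 not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.split_reads is not None and self.split_reads < 0:
            raise ValueError("split_reads must be >= 0")
        if self.spanning_pairs is not None and self.spanning_pairs < 0:
            raise ValueError("spanning_pairs must be >= 0")
        if (
            self.split_reads is not None
            and self.spanning_pairs is not None
            and self.reads != self.split_reads + self.spanning_pairs
        ):
            raise ValueError(
                "reads must equal split_reads + spanning_pairs when both are present"
            )
        if self.frame is not None and self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}")

    @property
    def key(self) -> GenePairKey:
        return pair_key(self.gene5, self.gene3)

    @property
    def breakpoints(self) -> Breakpoints:
        return (
            self.chrom5,
            self.pos5,
            self.chrom3,
            self.pos3,
            self.strand5,
            self.strand3,
        )


@dataclass
class OverlapRecord:
    """Consensus record for one unordered gene pair across callers.

    ``caller_count`` and ``max_reads`` are derived from ``per_caller`` so
    they can never drift out of sync with the contained calls.
    """

    key: GenePairKey
    per_caller: Dict[str, List[FusionCall]] = field(default_factory=dict)
    best_call: Optional[FusionCall] = None
    orientations: Set[Tuple[str, str]] = field(default_factory=set)
    annotations: Dict[str, object] = field(default_factory=dict)

    @property
    def caller_count(self) -> int:
        return len(self.per_caller)

    @property
    def max_reads(self) -> int:
        return max(c.reads for c in self.calls())

    @property
    def best_breakpoints(self) -> Optional[Breakpoints]:
        return self.best_call.breakpoints if self.best_call is not None else None

    def calls(self) -> Iterator[FusionCall]:
        for caller in sorted(self.per_caller):
            yield from self.per_caller[caller]

    @property
    def label(self) -> str:
        return pair_label(self.key)
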