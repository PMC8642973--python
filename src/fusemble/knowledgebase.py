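"""Known-fusion list management: rescue membership, the singleton channel,
and the gene-partner pathogenicity frequency score.

The list is a curated set of unordered gene-symbol pairs.  Each gene's
partner frequency ``f`` counts the list pairs containing it; genes with
``f >= 3`` are "common partners" and receive an integer 1-10 frequency
score.  Pair-level membership drives filter rescue; partner-level
membership drives annotation only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

from .models import FormatError, GenePairKey, OverlapRecord, pair_key

PathLike = Union[str, Path]

#: Minimum partner frequency for a gene to count as a common partner.
COMMON_PARTNER_MIN = 3


@dataclass(frozen=True)
class PartnerAnnotation:
    gene: str
    is_known_partner: bool
    frequency_score: Optional[int] = None
    gene_type: Optional[str] = None


@dataclass
class KnownFusionList:
    pairs: FrozenSet[GenePairKey] = frozenset()
    gene_types: Dict[str, str] = field(default_factory=dict)
    score_method: str = "ratio"

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[Tuple[str, str]],
        gene_types: Optional[Dict[str, str]] = None,
        score_method: str = "ratio",
    ) -> "KnownFusionList":
        keys = frozenset(pair_key(a, b) for a, b in pairs)
        return cls(pairs=keys, gene_types=dict(gene_types or {}), score_method=score_method)

    def contains(self, key: GenePairKey) -> bool:
        return tuple(key) in self.pairs

    @property
    def partner_frequency(self) -> Dict[str, int]:
        freq: Dict[str, int] = {}
        for key in self.pairs:
            for gene in key:
                freq[gene] = freq.get(gene, 0) + 1
        return freq

    @property
    def f_max(self) -> int:
        freqs = self.partner_frequency
        return max(freqs.values()) if freqs else 0

    @property
    def common_partners(self) -> Dict[str, int]:
        return {
            g: f for g, f in self.partner_frequency.items() if f >= COMMON_PARTNER_MIN
        }

    def annotate_partner(self, gene: str) -> PartnerAnnotation:
        f = self.partner_frequency.get(gene, 0)
        score = None
        if f >= COMMON_PARTNER_MIN:
            score = pathogenic_frequency_score(f, self.f_max, method=self.score_method)
        return PartnerAnnotation(
            gene=gene,
            is_known_partner=f > 0,
            frequency_score=score,
            gene_type=self.gene_types.get(gene) if f >= COMMON_PARTNER_MIN else None,
        )


def load_known_list(
    path: Optional[PathLike] = None,
    gene_types: Optional[Dict[str, str]] = None,
    score_method: str = "ratio",
) -> KnownFusionList:
    """Load a known-fusion list: one unordered pair per row, tab- or
    comma-delimited.  Pairs are deduplicated under order swap.  The
    bundled seed list (with its gene-type table) is the default."""
    if path is None:
        text = resources.files("fusemble.data").joinpath("known_fusions.tsv").read_text()
        if gene_types is None:
            gene_types = load_gene_types()
    else:
        text = Path(path).read_text()
    pairs: List[Tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) != 2:
            raise FormatError(
                f"known fusion list line {lineno}: expected two gene symbols, got {line!r}"
            )
        pairs.append((fields[0], fields[1]))
    return KnownFusionList.from_pairs(pairs, gene_types=gene_types, score_method=score_method)


def load_gene_types(path: Optional[PathLike] = None) -> Dict[str, str]:
    """Gene -> free-text type descriptor table (bundled default)."""
    if path is None:
        text = resources.files("fusemble.data").joinpath("gene_types.tsv").read_text()
    else:
        text = Path(path).read_text()
    types: Dict[str, str] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        types[row["gene"].strip()] = row["gene_type"].strip()
    return types


def pathogenic_frequency_score(
    f: int, f_max: int, method: str = "ratio"
) -> Optional[int]:
    """Integer 1-10 score for a known partner's list frequency.

    Absent (``None``) below the >=3 gate.  The default ``ratio`` mapping
    is ``clamp(round(10 * f / f_max), 1, 10)``: 10 at ``f == f_max``,
    1 at ``f == 3`` when ``f_max`` is large, monotone in ``f``.  The
    alternative ``inverse`` mapping ``10 / (f_max - f)`` is provided for
    comparison; it is undefined at ``f == f_max``, where it is pinned to
    10 (the score of the most frequent partner).
    """
    if f < 0:
        raise ValueError("partner frequency must be >= 0")
    if f_max < COMMON_PARTNER_MIN:
        raise ValueError(f"f_max must be >= {COMMON_PARTNER_MIN}")
    if f > f_max:
        raise ValueError(f"f ({f}) exceeds f_max ({f_max})")
    if f < COMMON_PARTNER_MIN:
        return None
    if method == "ratio":
        raw = round(10 * f / f_max)
    elif method == "inverse":
        raw = 10 if f == f_max else round(10 / (f_max - f))
    else:
        raise ValueError(f"unknown score method {method!r}")
    return max(1, min(10, int(raw)))


def annotate_known(
    records: Sequence[OverlapRecord], known: KnownFusionList
) -> List[OverlapRecord]:
    """Attach pair-level and partner-level known-list annotations in place.

    Never alters record order, evidence fields, or breakpoints.
    """
    for record in records:
        record.annotations["known_pair"] = known.contains(record.key)
        record.annotations["partners"] = {
            gene: known.annotate_partner(gene) for gene in record.key
        }
    return list(records)


def extract_singletons(
    records: Sequence[OverlapRecord], known: KnownFusionList
) -> List[OverlapRecord]:
    """Supplementary channel: single-caller records whose pair is on the
    known list.  Disjoint from the filtered output by construction (the
    filtered output requires at least two callers even under rescue)."""
    return [r for r in records if r.caller_count == 1 and known.contains(r.key)]
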