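"""Gene-symbol harmonization against an HGNC-style alias table.

Callers built on different annotation releases may report the same gene
under different symbols.  Every reported symbol is mapped to its approved
symbol; when an alias maps to several approved symbols, the candidate
whose cytogenetic band agrees with the call's breakpoint chromosome (and
arm, when both are known) wins.  Symbols that cannot be resolved pass
through unchanged — dropping them would silently destroy sensitivity.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .models import FormatError, FusionCall

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

STATUS_APPROVED = "approved"
STATUS_ALIAS = "alias"
STATUS_BAND_RESOLVED = "band-resolved"
STATUS_UNRESOLVED = "unresolved"

_BAND_RE = re.compile(r"^(\d+|X|Y|MT)([pq])?", re.IGNORECASE)


@dataclass(frozen=True)
class BandLocus:
    """A breakpoint's cytogenetic context: chromosome plus optional band."""

    chrom: str
    band: Optional[str] = None

    @property
    def arm(self) -> Optional[str]:
        if not self.band:
            return None
        m = _BAND_RE.match(self.band)
        return m.group(2) if m and m.group(2) else (
            self.band[0] if self.band[0] in "pq" else None
        )


def band_chrom_arm(cytoband: str) -> Tuple[Optional[str], Optional[str]]:
    """Split ``7q34`` into chromosome ``7`` and arm ``q``."""
    m = _BAND_RE.match(cytoband.strip())
    if not m:
        return None, None
    return m.group(1).upper() if m.group(1).upper() in ("X", "Y", "MT") else m.group(1), (
        m.group(2).lower() if m.group(2) else None
    )


@dataclass
class AliasTable:
    """alias symbol -> candidate (approved symbol, cytoband) mappings."""

    aliases: Dict[str, List[Tuple[str, str]]]
    approved: Dict[str, str]  # approved symbol -> cytoband

    @classmethod
    def from_rows(cls, rows: Sequence[Tuple[str, str, str]]) -> "AliasTable":
        """Build from (approved_symbol, alias, cytoband) rows.

        Every approved symbol maps to itself, whether or not a self row
        is present.
        """
        aliases: Dict[str, List[Tuple[str, str]]] = {}
        approved: Dict[str, str] = {}
        for sym, alias, band in rows:
            approved.setdefault(sym, band)
            if alias and alias != sym:
                cands = aliases.setdefault(alias, [])
                if (sym, band) not in cands:
                    cands.append((sym, band))
        for sym, band in approved.items():
            aliases.setdefault(sym, []).insert(0, (sym, band))
        return cls(aliases=aliases, approved=approved)


def load_alias_table(path: Optional[PathLike] = None) -> AliasTable:
    """Load a TSV of approved_symbol / alias / cytoband rows (bundled default)."""
    if path is None:
        text = resources.files("fusemble.data").joinpath("alias_table.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows: List[Tuple[str, str, str]] = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"approved_symbol", "alias", "cytoband"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise FormatError(
            f"alias table needs columns {sorted(required)}, got {reader.fieldnames}"
        )
    for row in reader:
        rows.append(
            (row["approved_symbol"].strip(), row["alias"].strip(), row["cytoband"].strip())
        )
    return AliasTable.from_rows(rows)


def normalize_symbol(
    symbol: str, locus: Optional[BandLocus], table: AliasTable
) -> Tuple[str, str]:
    """Map a reported symbol to its approved symbol.

    Returns ``(symbol, status)`` with status one of ``approved``,
    ``alias`` (unambiguous), ``band-resolved`` or ``unresolved``.
    Unresolvable symbols are returned unchanged, never dropped.
    """
    if symbol in table.approved:
        return symbol, STATUS_APPROVED

    candidates = table.aliases.get(symbol, [])
    targets = sorted({sym for sym, _ in candidates})
    if len(targets) == 1:
        return targets[0], STATUS_ALIAS
    if not targets:
        logger.debug("symbol %s not in alias table; passing through", symbol)
        return symbol, STATUS_UNRESOLVED

    if locus is not None:
        matches = []
        for sym, band in candidates:
            chrom, arm = band_chrom_arm(band)
            if chrom != locus.chrom:
                continue
            if arm is not None and locus.arm is not None and arm != locus.arm:
                continue
            matches.append(sym)
        matches = sorted(set(matches))
        if len(matches) == 1:
            return matches[0], STATUS_BAND_RESOLVED
    logger.warning(
        "ambiguous alias %s (candidates: %s) could not be band-resolved; kept as-is",
        symbol,
        ", ".join(targets),
    )
    return symbol, STATUS_UNRESOLVED


def harmonize_calls(calls: Sequence[FusionCall], table: AliasTable) -> List[FusionCall]:
    """Apply :func:`normalize_symbol` to both partners of every call.

    The call's own breakpoint chromosome serves as the disambiguating
    locus; all non-gene fields are left untouched.  Idempotent.
    """
    out: List[FusionCall] = []
    for call in calls:
        gene5, _ = normalize_symbol(call.gene5, BandLocus(call.chrom5), table)
        gene3, _ = normalize_symbol(call.gene3, BandLocus(call.chrom3), table)
        if gene5 != call.gene5 or gene3 != call.gene3:
            call = replace(call, gene5=gene5, gene3=gene3)
        out.append(call)
    return out
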