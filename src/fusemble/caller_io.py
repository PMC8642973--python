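"""Readers/writers for the native output dialects of the supported callers.

Dialects are declarative: ``data/dialects.yaml`` describes each caller's
columns, gene-pair encoding, breakpoint encoding, coordinate convention and
evidence columns, and this module interprets that description in both
directions (parse and write).  The same machinery also implements the
canonical unified-calls TSV used between pipeline stages.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import yaml

from .models import (
    CALLERS,
    STRAND_UNKNOWN,
    ConfigurationError,
    FormatError,
    FusionCall,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Column order of the canonical unified-calls TSV.
UNIFIED_COLUMNS = [
    "caller",
    "gene5",
    "gene3",
    "chrom5",
    "pos5",
    "strand5",
    "chrom3",
    "pos3",
    "strand3",
    "reads",
    "split_reads",
    "spanning_pairs",
    "junction_seq",
    "frame",
]


@dataclass(frozen=True)
class CallerDialect:
    """Declarative description of one caller's tab-delimited output."""

    caller: str
    spec: dict

    @property
    def columns(self) -> List[str]:
        return list(self.spec["columns"])

    @property
    def coordinate_convention(self) -> str:
        return self.spec.get("coordinate_convention", "1-based")

    @property
    def has_split_spanning(self) -> bool:
        return "total" not in self.spec["reads"]

    @property
    def has_frame(self) -> bool:
        return "frame" in self.spec

    @property
    def has_junction_seq(self) -> bool:
        return "junction_seq" in self.spec

    def required_columns(self) -> List[str]:
        """Columns the parser actually needs (inert columns may be absent)."""
        req: List[str] = []
        genes = self.spec["genes"]
        if "pair" in genes:
            req.append(genes["pair"])
        else:
            req += [genes["gene5"], genes["gene3"]]
        for side in ("breakpoint5", "breakpoint3"):
            bp = self.spec[side]
            if "combined" in bp:
                req.append(bp["combined"])
            else:
                req += [bp["chrom"], bp["pos"]]
        strands = self.spec.get("strands", {})
        req += [v for v in strands.values()]
        reads = self.spec["reads"]
        if "total" in reads:
            req.append(reads["total"])
        else:
            split = reads["split"]
            req += list(split) if isinstance(split, list) else [split]
            req.append(reads["spanning"])
        if self.has_frame:
            req.append(self.spec["frame"]["column"])
        if self.has_junction_seq:
            req.append(self.spec["junction_seq"])
        return req

    # -- parsing -----------------------------------------------------------

    def _to_one_based(self, pos: int) -> int:
        return pos + 1 if self.coordinate_convention == "0-based" else pos

    def _from_one_based(self, pos: int) -> int:
        return pos - 1 if self.coordinate_convention == "0-based" else pos

    def parse_row(self, row: Dict[str, str]) -> FusionCall:
        """Convert one native row to a :class:`FusionCall`.

        Raises ``ValueError`` on unparseable fields; callers of this method
        decide whether to drop the row or abort.
        """
        genes = self.spec["genes"]
        if "pair" in genes:
            raw = (row[genes["pair"]] or "").strip()
            sep = genes["separator"]
            if sep not in raw:
                raise ValueError(f"gene pair {raw!r} lacks separator {sep!r}")
            gene5, gene3 = (g.strip() for g in raw.split(sep, 1))
        else:
            gene5 = (row[genes["gene5"]] or "").strip()
            gene3 = (row[genes["gene3"]] or "").strip()
        if not gene5 or not gene3:
            raise ValueError("empty gene symbol")

        sides = {}
        for side, tag in (("breakpoint5", "5"), ("breakpoint3", "3")):
            bp = self.spec[side]
            strand = None
            if "combined" in bp:
                parts = (row[bp["combined"]] or "").strip().split(":")
                fmt = bp["format"].split(":")
                if len(parts) != len(fmt):
                    raise ValueError(f"malformed breakpoint {row[bp['combined']]!r}")
                chrom = parts[fmt.index("chrom")]
                pos = int(parts[fmt.index("pos")])
                if "strand" in fmt:
                    strand = parts[fmt.index("strand")]
            else:
                chrom = row[bp["chrom"]]
                pos = int(row[bp["pos"]])
            sides[tag] = [normalize_chrom(chrom), self._to_one_based(pos), strand]

        strands = self.spec.get("strands", {})
        if "joint" in strands:
            joint = (row[strands["joint"]] or "").strip()
            if len(joint) == 2:
                sides["5"][2], sides["3"][2] = joint[0], joint[1]
        else:
            if "strand5" in strands:
                sides["5"][2] = (row[strands["strand5"]] or "").strip()
            if "strand3" in strands:
                sides["3"][2] = (row[strands["strand3"]] or "").strip()

        def norm_strand(s: Optional[str]) -> str:
            return s if s in ("+", "-") else STRAND_UNKNOWN

        reads_cfg = self.spec["reads"]
        split_reads: Optional[int] = None
        spanning: Optional[int] = None
        if "total" in reads_cfg:
            reads = int(row[reads_cfg["total"]])
        else:
            split_cols = reads_cfg["split"]
            if not isinstance(split_cols, list):
                split_cols = [split_cols]
            split_reads = sum(int(row[c]) for c in split_cols)
            spanning = int(row[reads_cfg["spanning"]])
            reads = split_reads + spanning

        frame = None
        if self.has_frame:
            fr = self.spec["frame"]
            frame = fr["values"].get((row[fr["column"]] or "").strip(), "unknown")

        junction_seq = None
        if self.has_junction_seq:
            raw_seq = (row[self.spec["junction_seq"]] or "").strip()
            junction_seq = raw_seq if raw_seq and raw_seq != "." else None

        return FusionCall(
            caller=self.caller,
            gene5=gene5,
            gene3=gene3,
            chrom5=sides["5"][0],
            pos5=sides["5"][1],
            strand5=norm_strand(sides["5"][2]),
            chrom3=sides["3"][0],
            pos3=sides["3"][1],
            strand3=norm_strand(sides["3"][2]),
            reads=reads,
            split_reads=split_reads,
            spanning_pairs=spanning,
            junction_seq=junction_seq,
            frame=frame,
        )

    # -- writing -----------------------------------------------------------

    def format_row(self, call: FusionCall) -> Dict[str, str]:
        row = dict(self.spec.get("defaults", {}))
        row = {k: str(v) for k, v in row.items()}

        genes = self.spec["genes"]
        if "pair" in genes:
            row[genes["pair"]] = f"{call.gene5}{genes['separator']}{call.gene3}"
        else:
            row[genes["gene5"]] = call.gene5
            row[genes["gene3"]] = call.gene3

        for side, chrom, pos, strand in (
            ("breakpoint5", call.chrom5, call.pos5, call.strand5),
            ("breakpoint3", call.chrom3, call.pos3, call.strand3),
        ):
            bp = self.spec[side]
            out_pos = self._from_one_based(pos)
            if "combined" in bp:
                fmt = bp["format"].split(":")
                fields = {"chrom": chrom, "pos": str(out_pos), "strand": strand}
                row[bp["combined"]] = ":".join(fields[f] for f in fmt)
            else:
                row[bp["chrom"]] = chrom
                row[bp["pos"]] = str(out_pos)

        strands = self.spec.get("strands", {})
        if "joint" in strands:
            row[strands["joint"]] = f"{call.strand5}{call.strand3}"
        else:
            if "strand5" in strands:
                row[strands["strand5"]] = call.strand5
            if "strand3" in strands:
                row[strands["strand3"]] = call.strand3

        reads_cfg = self.spec["reads"]
        if "total" in reads_cfg:
            row[reads_cfg["total"]] = str(call.reads)
        else:
            split_cols = reads_cfg["split"]
            if not isinstance(split_cols, list):
                split_cols = [split_cols]
            split = call.split_reads if call.split_reads is not None else call.reads
            spanning = call.spanning_pairs if call.spanning_pairs is not None else 0
            row[split_cols[0]] = str(split)
            for extra in split_cols[1:]:
                row[extra] = "0"
            row[reads_cfg["spanning"]] = str(spanning)

        if self.has_frame:
            fr = self.spec["frame"]
            reverse = {}
            for native, internal in fr["values"].items():
                reverse.setdefault(internal, native)
            row[fr["column"]] = reverse.get(call.frame or "unknown", ".")

        if self.has_junction_seq:
            row[self.spec["junction_seq"]] = call.junction_seq or "."

        return {col: row.get(col, ".") for col in self.columns}


_DIALECTS: Optional[Dict[str, CallerDialect]] = None


def load_dialects(path: Optional[PathLike] = None) -> Dict[str, CallerDialect]:
    """Load dialect definitions; the bundled config is cached."""
    global _DIALECTS
    if path is None and _DIALECTS is not None:
        return _DIALECTS
    if path is None:
        text = resources.files("fusemble.data").joinpath("dialects.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    dialects = {name: CallerDialect(name, spec) for name, spec in raw.items()}
    if path is None:
        _DIALECTS = dialects
    return dialects


def get_dialect(caller: str) -> CallerDialect:
    dialects = load_dialects()
    if caller not in dialects:
        raise ConfigurationError(
            f"unknown caller {caller!r}; supported: {', '.join(sorted(dialects))}"
        )
    return dialects[caller]


def parse_caller_output(path: PathLike, caller: str) -> List[FusionCall]:
    """Parse one caller's native output file into unified calls.

    Zero-fusion files (empty, or header-only) yield an empty list.  Rows
    with unparseable gene or coordinate fields are dropped with a warning;
    a header that does not match the dialect raises :class:`FormatError`
    naming the missing columns.
    """
    dialect = get_dialect(caller)
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return []  # a caller may legitimately report zero fusions
        missing = [c for c in dialect.required_columns() if c not in reader.fieldnames]
        if missing:
            raise FormatError(
                f"{path} does not match the {caller} dialect; "
                f"missing columns: {', '.join(missing)}"
            )
        calls: List[FusionCall] = []
        dropped = 0
        for lineno, row in enumerate(reader, start=2):
            try:
                calls.append(dialect.parse_row(row))
            except (ValueError, KeyError, TypeError) as exc:
                dropped += 1
                logger.warning("%s line %d dropped: %s", path, lineno, exc)
    if dropped:
        logger.warning("%s: dropped %d unparseable row(s)", path, dropped)
    return calls


def write_caller_file(calls: Sequence[FusionCall], caller: str, path: PathLike) -> None:
    """Write calls in the caller's native dialect (inverse of parsing)."""
    dialect = get_dialect(caller)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=dialect.columns, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for call in calls:
            writer.writerow(dialect.format_row(call))


def write_unified_calls(calls: Sequence[FusionCall], path: PathLike) -> None:
    """Write the canonical unified-calls TSV (absent optionals serialize empty)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(UNIFIED_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.caller,
                    c.gene5,
                    c.gene3,
                    c.chrom5,
                    c.pos5,
                    c.strand5,
                    c.chrom3,
                    c.pos3,
                    c.strand3,
                    c.reads,
                    "" if c.split_reads is None else c.split_reads,
                    "" if c.spanning_pairs is None else c.spanning_pairs,
                    c.junction_seq or "",
                    c.frame or "",
                ]
            )


def read_unified_calls(path: PathLike) -> List[FusionCall]:
    """Read the canonical unified-calls TSV back into calls."""
    path = Path(path)
    calls: List[FusionCall] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in UNIFIED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing unified columns {missing}")
        for row in reader:
            calls.append(
                FusionCall(
                    caller=row["caller"],
                    gene5=row["gene5"],
                    gene3=row["gene3"],
                    chrom5=row["chrom5"],
                    pos5=int(row["pos5"]),
                    strand5=row["strand5"],
                    chrom3=row["chrom3"],
                    pos3=int(row["pos3"]),
                    strand3=row["strand3"],
                    reads=int(row["reads"]),
                    split_reads=int(row["split_reads"]) if row["split_reads"] else None,
                    spanning_pairs=(
                        int(row["spanning_pairs"]) if row["spanning_pairs"] else None
                    ),
                    junction_seq=row["junction_seq"] or None,
                    frame=row["frame"] or None,
                )
            )
    return calls


def group_by_caller(calls: Iterable[FusionCall]) -> Dict[str, List[FusionCall]]:
    grouped: Dict[str, List[FusionCall]] = {}
    for call in calls:
        grouped.setdefault(call.caller, []).append(call)
    return {caller: grouped[caller] for caller in CALLERS if caller in grouped}
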