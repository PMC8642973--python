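"""Deterministic synthetic fixture generator.

Emits per-caller output files in each caller's native dialect with planted
truth: true fusions (some or all drawn from the known-fusion list),
read-through artifacts, recurrent cohort artifacts, low-evidence fusions,
and per-caller unique false positives.  Every planted row is recorded in a
manifest so the pipeline's behaviour can be checked against an independent
rule evaluator, and the same seed always yields byte-identical files.

Gene symbols and coordinates come from a small bundled mock annotation
(symbol, chromosome, strand, cytoband, span) plus deterministically
placed synthetic filler genes, so distances and bands are well defined
without any genome download.
"""

from __future__ import annotations

import csv
import json
import math
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from . import caller_io
from .benchmark import TruthSet
from .freqdb import CohortFrequencyStore
from .knowledgebase import KnownFusionList, load_known_list
from .models import (
    CALLERS,
    ConfigurationError,
    FusionCall,
    GenePairKey,
    pair_key,
)

PathLike = Union[str, Path]

CATEGORY_TRUE = "true"
CATEGORY_READTHROUGH = "readthrough"
CATEGORY_RECURRENT = "recurrent"
CATEGORY_LOW_EVIDENCE = "low-evidence"
CATEGORY_FALSE_POSITIVE = "false-positive"

#: Per-caller false-positive burden, shaped like the callers' relative
#: noise levels (noisy: cicero/jaffa/fusioncatcher; quiet: arriba/mapsplice).
DEFAULT_PER_CALLER_FP: Dict[str, int] = {
    "arriba": 3,
    "mapsplice": 3,
    "fusionmap": 4,
    "starfusion": 5,
    "fusioncatcher": 12,
    "jaffa": 12,
    "cicero": 15,
}

_FP_READS = [1, 2, 3, 4, 5, 8]
_FP_WEIGHTS = [32, 24, 18, 12, 9, 5]


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    strand: str
    band: str
    start: int
    end: int


def load_gene_annotation(path: Optional[PathLike] = None) -> Dict[str, GeneModel]:
    """Bundled mock gene annotation: symbol -> model."""
    if path is None:
        text = resources.files("fusemble.data").joinpath("gene_annotation.tsv").read_text()
    else:
        text = Path(path).read_text()
    genes: Dict[str, GeneModel] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        genes[row["symbol"]] = GeneModel(
            symbol=row["symbol"],
            chrom=row["chrom"],
            strand=row["strand"],
            band=row["band"],
            start=int(row["start"]),
            end=int(row["end"]),
        )
    return genes


def background_genes(n: int = 80) -> Dict[str, GeneModel]:
    """Deterministic filler genes for artifacts and false positives.

    Laid out 2 Mb apart per chromosome so no two filler genes are ever
    within read-through distance of each other.
    """
    chroms = [str(c) for c in range(1, 23)]
    genes: Dict[str, GeneModel] = {}
    for i in range(n):
        chrom = chroms[i % len(chroms)]
        lane = i // len(chroms)
        start = 3_000_000 + lane * 2_000_000
        symbol = f"SYN{i + 1:03d}"
        genes[symbol] = GeneModel(
            symbol=symbol,
            chrom=chrom,
            strand="+" if i % 2 == 0 else "-",
            band=f"{chrom}q{11 + lane}",
            start=start,
            end=start + 50_000,
        )
    return genes


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_true: int = 14
    true_caller_counts: Dict[int, int] = field(
        default_factory=lambda: {3: 2, 4: 2, 5: 3, 6: 3, 7: 4}
    )
    n_readthrough: int = 3
    n_recurrent: int = 3
    n_low_evidence: int = 2
    per_caller_fp: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PER_CALLER_FP)
    )
    known_list_fraction: float = 1.0
    low_evidence_on_known_list: bool = False
    alias_rate: float = 0.0
    cohort_size: int = 20
    recurrent_rate: float = 0.30

    def validate(self, known: KnownFusionList) -> None:
        for name in ("n_true", "n_readthrough", "n_recurrent", "n_low_evidence"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.known_list_fraction <= 1.0:
            raise ConfigurationError("known_list_fraction must be in [0, 1]")
        if self.known_list_fraction > 0 and self.n_true > 0 and not known.pairs:
            raise ConfigurationError(
                "known_list_fraction > 0 requires a non-empty known fusion list"
            )
        if any(c not in CALLERS for c in self.per_caller_fp):
            raise ConfigurationError("per_caller_fp names an unknown caller")
        if any(n < 0 for n in self.per_caller_fp.values()):
            raise ConfigurationError("per_caller_fp counts must be >= 0")
        if any(k < 1 or k > len(CALLERS) for k in self.true_caller_counts):
            raise ConfigurationError("true_caller_counts keys must be in 1..7")
        if self.recurrent_rate <= 0.10 and self.n_recurrent > 0:
            raise ConfigurationError(
                "recurrent_rate must exceed the 10% filter threshold"
            )
        if self.cohort_size < 1:
            raise ConfigurationError("cohort_size must be >= 1")


@dataclass
class FixtureBundle:
    caller_files: Dict[str, Path]
    truth: TruthSet
    store: CohortFrequencyStore
    known_list: KnownFusionList
    manifest: List[dict]
    out_dir: Path
    store_path: Path
    known_list_path: Path
    truth_path: Path


def generate_fixture(
    spec: FixtureSpec,
    out_dir: PathLike,
    known_list: Optional[KnownFusionList] = None,
    annotation: Optional[Dict[str, GeneModel]] = None,
    aliases: Optional[Dict[str, str]] = None,
    true_read_scale: float = 1.0,
) -> FixtureBundle:
    """Generate one deterministic fixture bundle under ``out_dir``.

    ``true_read_scale`` scales the read counts of planted true fusions
    (rounded down; a caller's row is dropped when its scaled reads reach
    zero) and is the mechanism behind :func:`dilution_series`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    known = known_list if known_list is not None else load_known_list()
    spec.validate(known)
    if not 0.0 < true_read_scale <= 1.0:
        raise ConfigurationError("true_read_scale must be in (0, 1]")

    rng = random.Random(spec.seed)
    ann = dict(annotation) if annotation is not None else load_gene_annotation()
    fillers = background_genes()
    used_pairs: Set[GenePairKey] = set()
    manifest: List[dict] = []

    # --- true fusions ---------------------------------------------------
    n_known = round(spec.n_true * spec.known_list_fraction)
    eligible_known = sorted(
        k for k in known.pairs if len(k) == 2 and all(g in ann for g in k)
    )
    if n_known > len(eligible_known):
        raise ConfigurationError(
            f"need {n_known} known-list pairs with annotation, "
            f"only {len(eligible_known)} available"
        )
    true_keys = rng.sample(eligible_known, n_known)
    used_pairs.update(true_keys)
    while len(true_keys) < spec.n_true:
        key = _random_cross_chrom_pair(rng, ann, used_pairs, known)
        true_keys.append(key)
        used_pairs.add(key)

    counts, weights = zip(*sorted(spec.true_caller_counts.items()))
    for key in true_keys:
        n_callers = rng.choices(counts, weights=weights, k=1)[0]
        manifest.append(
            _plant(
                rng,
                CATEGORY_TRUE,
                key,
                ann,
                n_callers=n_callers,
                reads_range=(5, 60),
                read_scale=true_read_scale,
            )
        )

    # --- read-through artifacts (same chrom/strand, < 200 kb apart) -----
    for j in range(spec.n_readthrough):
        chrom = str(rng.randint(1, 22))
        strand = rng.choice("+-")
        base = 80_000_000 + j * 1_000_000
        gap = rng.randint(20_000, 170_000)
        gene_a = GeneModel(f"RTG{j:02d}A", chrom, strand, f"{chrom}q21", base, base + 8_000)
        gene_b = GeneModel(
            f"RTG{j:02d}B", chrom, strand, f"{chrom}q21", base + gap, base + gap + 8_000
        )
        ann[gene_a.symbol] = gene_a
        ann[gene_b.symbol] = gene_b
        key = pair_key(gene_a.symbol, gene_b.symbol)
        used_pairs.add(key)
        manifest.append(
            _plant(
                rng,
                CATEGORY_READTHROUGH,
                key,
                ann,
                n_callers=rng.randint(3, 6),
                reads_range=(5, 30),
            )
        )

    # --- recurrent cohort artifacts -------------------------------------
    store = CohortFrequencyStore()
    recurrent_keys: List[GenePairKey] = []
    for _ in range(spec.n_recurrent):
        key = _random_cross_chrom_pair(rng, fillers, used_pairs, known)
        used_pairs.add(key)
        recurrent_keys.append(key)
        manifest.append(
            _plant(
                rng,
                CATEGORY_RECURRENT,
                key,
                {**ann, **fillers},
                n_callers=rng.randint(3, 6),
                reads_range=(5, 30),
            )
        )
    n_obs = max(
        math.ceil(spec.recurrent_rate * spec.cohort_size),
        math.floor(0.10 * spec.cohort_size) + 1,
    )
    for i in range(spec.cohort_size):
        sample_id = f"cohort{i + 1:03d}"
        store.register_sample(sample_id, recurrent_keys if i < n_obs else [])

    # --- low-evidence fusions (all reads below the evidence threshold) --
    low_evidence_pool = [k for k in eligible_known if k not in used_pairs]
    for _ in range(spec.n_low_evidence):
        if spec.low_evidence_on_known_list and low_evidence_pool:
            key = low_evidence_pool.pop(rng.randrange(len(low_evidence_pool)))
        else:
            key = _random_cross_chrom_pair(rng, fillers, used_pairs, known)
        used_pairs.add(key)
        manifest.append(
            _plant(
                rng,
                CATEGORY_LOW_EVIDENCE,
                key,
                {**ann, **fillers},
                n_callers=rng.randint(3, 5),
                reads_range=(1, 3),
            )
        )

    # --- per-caller unique false positives ------------------------------
    for caller in sorted(spec.per_caller_fp):
        for _ in range(spec.per_caller_fp[caller]):
            key = _random_cross_chrom_pair(rng, fillers, used_pairs, known)
            used_pairs.add(key)
            reads = rng.choices(_FP_READS, weights=_FP_WEIGHTS, k=1)[0]
            entry = _plant(
                rng,
                CATEGORY_FALSE_POSITIVE,
                key,
                fillers,
                callers=[caller],
                reads_range=None,
                fixed_reads=reads,
            )
            manifest.append(entry)

    manifest.sort(key=lambda e: (e["category"], e["gene5"], e["gene3"]))

    # --- materialize per-caller files -----------------------------------
    calls_by_caller: Dict[str, List[FusionCall]] = {c: [] for c in CALLERS}
    for entry in manifest:
        for caller, obs in entry["per_caller"].items():
            calls_by_caller[caller].append(_to_call(caller, entry, obs, aliases, rng, spec))

    caller_files: Dict[str, Path] = {}
    for caller in CALLERS:
        calls = sorted(
            calls_by_caller[caller], key=lambda c: (c.gene5, c.gene3, c.pos5, c.pos3)
        )
        path = out_dir / f"{caller}.tsv"
        caller_io.write_caller_file(calls, caller, path)
        caller_files[caller] = path

    truth = TruthSet.from_pairs([tuple(k) for k in true_keys], label=f"seed{spec.seed}")

    store_path = out_dir / "freqdb.json"
    store.save(store_path)
    known_list_path = out_dir / "known_fusions.tsv"
    _write_pair_file(known_list_path, sorted(known.pairs))
    truth_path = out_dir / "truth.tsv"
    _write_pair_file(truth_path, sorted(truth.true_pairs))
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )

    return FixtureBundle(
        caller_files=caller_files,
        truth=truth,
        store=store,
        known_list=known,
        manifest=manifest,
        out_dir=out_dir,
        store_path=store_path,
        known_list_path=known_list_path,
        truth_path=truth_path,
    )


def dilution_series(
    spec: FixtureSpec,
    dilution_factors: Sequence[float],
    out_root: PathLike,
    known_list: Optional[KnownFusionList] = None,
) -> List[FixtureBundle]:
    """One bundle per dilution factor: true-fusion reads scaled by the
    factor (floored), caller rows dropped when scaled reads hit zero."""
    for d in dilution_factors:
        if not 0.0 < d <= 1.0:
            raise ConfigurationError("dilution factors must be in (0, 1]")
    out_root = Path(out_root)
    return [
        generate_fixture(
            spec,
            out_root / f"dilution_{i:02d}",
            known_list=known_list,
            true_read_scale=d,
        )
        for i, d in enumerate(dilution_factors)
    ]


# -- internals -------------------------------------------------------------


def _random_cross_chrom_pair(
    rng: random.Random,
    pool: Dict[str, GeneModel],
    used: Set[GenePairKey],
    known: KnownFusionList,
    max_tries: int = 1000,
) -> GenePairKey:
    symbols = sorted(pool)
    for _ in range(max_tries):
        a, b = rng.sample(symbols, 2)
        if pool[a].chrom == pool[b].chrom:
            continue
        key = pair_key(a, b)
        if key in used or known.contains(key):
            continue
        return key
    raise ConfigurationError("gene pool exhausted while sampling unique pairs")


def _plant(
    rng: random.Random,
    category: str,
    key: GenePairKey,
    ann: Dict[str, GeneModel],
    n_callers: Optional[int] = None,
    callers: Optional[List[str]] = None,
    reads_range: Optional[Tuple[int, int]] = None,
    fixed_reads: Optional[int] = None,
    read_scale: float = 1.0,
) -> dict:
    gene5, gene3 = (key[0], key[1]) if len(key) == 2 else (key[0], key[0])
    g5, g3 = ann[gene5], ann[gene3]
    pos5 = rng.randint(g5.start, g5.end)
    pos3 = rng.randint(g3.start, g3.end)
    if callers is None:
        callers = sorted(rng.sample(CALLERS, n_callers))
    per_caller: Dict[str, dict] = {}
    for caller in callers:
        reads = fixed_reads if fixed_reads is not None else rng.randint(*reads_range)
        jitter5 = rng.randint(-2, 2)
        jitter3 = rng.randint(-2, 2)
        scaled = math.floor(reads * read_scale)
        if scaled <= 0:
            continue
        per_caller[caller] = {
            "reads": scaled,
            "pos5": max(1, pos5 + jitter5),
            "pos3": max(1, pos3 + jitter3),
        }
    return {
        "category": category,
        "gene5": gene5,
        "gene3": gene3,
        "chrom5": g5.chrom,
        "strand5": g5.strand,
        "chrom3": g3.chrom,
        "strand3": g3.strand,
        "per_caller": per_caller,
    }


_BASES = "ACGT"


def _to_call(
    caller: str,
    entry: dict,
    obs: dict,
    aliases: Optional[Dict[str, str]],
    rng: random.Random,
    spec: FixtureSpec,
) -> FusionCall:
    dialect = caller_io.get_dialect(caller)
    gene5, gene3 = entry["gene5"], entry["gene3"]
    if aliases and spec.alias_rate > 0:
        if gene5 in aliases and rng.random() < spec.alias_rate:
            gene5 = aliases[gene5]
        if gene3 in aliases and rng.random() < spec.alias_rate:
            gene3 = aliases[gene3]
    reads = obs["reads"]
    split = spanning = None
    if dialect.has_split_spanning:
        spanning = reads // 3
        split = reads - spanning
    frame = None
    if dialect.has_frame:
        frame = "in-frame" if entry["category"] == CATEGORY_TRUE else "unknown"
    junction = None
    if dialect.has_junction_seq:
        junction = "".join(rng.choice(_BASES) for _ in range(20))
    return FusionCall(
        caller=caller,
        gene5=gene5,
        gene3=gene3,
        chrom5=entry["chrom5"],
        pos5=obs["pos5"],
        strand5=entry["strand5"],
        chrom3=entry["chrom3"],
        pos3=obs["pos3"],
        strand3=entry["strand3"],
        reads=reads,
        split_reads=split,
        spanning_pairs=spanning,
        junction_seq=junction,
        frame=frame,
    )


def _write_pair_file(path: Path, keys: Sequence[GenePairKey]) -> None:
    lines = ["gene_a\tgene_b"]
    for key in keys:
        a = key[0]
        b = key[1] if len(key) == 2 else key[0]
        lines.append(f"{a}\t{b}")
    path.write_text("\n".join(lines) + "\n")


def expected_kept_pairs(
    manifest: Sequence[dict],
    known: KnownFusionList,
    store: CohortFrequencyStore,
    min_callers: int = 3,
    min_reads: int = 4,
    known_list_min_callers: int = 2,
    readthrough_max_distance: int = 200_000,
    max_cohort_frequency: float = 0.10,
) -> Set[GenePairKey]:
    """Independent rule evaluator: which planted pairs should survive
    filtering, computed directly from the manifest (never via the
    pipeline).  Used as the oracle for end-to-end recovery tests."""
    kept: Set[GenePairKey] = set()
    for entry in manifest:
        per_caller = entry["per_caller"]
        if not per_caller:
            continue
        key = pair_key(entry["gene5"], entry["gene3"])
        n_callers = len(per_caller)
        max_reads = max(o["reads"] for o in per_caller.values())
        best = max(
            per_caller.values(),
            key=lambda o: (o["reads"], -o["pos5"], -o["pos3"]),
        )
        readthrough = (
            entry["chrom5"] == entry["chrom3"]
            and entry["strand5"] == entry["strand3"]
            and entry["strand5"] in "+-"
            and abs(best["pos5"] - best["pos3"]) < readthrough_max_distance
        )
        high_freq = store.frequency(key) > max_cohort_frequency
        ok = (
            n_callers >= min_callers
            and not readthrough
            and not high_freq
            and max_reads >= min_reads
        )
        rescued = known.contains(key) and n_callers >= known_list_min_callers
        if ok or rescued:
            kept.add(key)
    return kept
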