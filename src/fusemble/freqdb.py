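"""Cohort detection-frequency store.

Tracks, per unordered gene pair, the set of cohort samples in which the
pair was called; ``frequency`` is observed samples over all registered
samples.  The store persists to a single JSON file so the artifact stays
self-contained (no database server), and can dump a TSV snapshot for
inspection.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Sequence, Set, Union

from .models import ConfigurationError, GenePairKey, pair_key

PathLike = Union[str, Path]


@dataclass
class CohortFrequencyStore:
    samples: Set[str] = field(default_factory=set)
    observations: Dict[GenePairKey, Set[str]] = field(default_factory=dict)

    def register_sample(self, sample_id: str, pairs: Iterable[GenePairKey]) -> None:
        """Record one sample's called pairs.

        Re-registering the same sample replaces its observations rather
        than double-counting; registering with an empty pair list still
        grows the denominator.
        """
        if not sample_id:
            raise ConfigurationError("sample_id must be non-empty")
        if sample_id in self.samples:
            for seen in self.observations.values():
                seen.discard(sample_id)
        self.samples.add(sample_id)
        for pair in pairs:
            key = pair_key(*pair) if len(pair) == 2 else tuple(pair)
            self.observations.setdefault(key, set()).add(sample_id)

    def frequency(self, pair: GenePairKey) -> float:
        """Fraction of registered samples in which the pair was called.

        Symmetric under pair order; 0 for unseen pairs or an empty store.
        """
        if not self.samples:
            return 0.0
        key = pair_key(*pair) if len(pair) == 2 else tuple(pair)
        return len(self.observations.get(key, ())) / len(self.samples)

    # -- persistence -------------------------------------------------------

    def save(self, path: PathLike) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "samples": sorted(self.samples),
            "observations": [
                {"pair": list(key), "samples": sorted(seen)}
                for key, seen in sorted(self.observations.items())
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: PathLike) -> "CohortFrequencyStore":
        payload = json.loads(Path(path).read_text())
        store = cls(samples=set(payload["samples"]))
        for obs in payload["observations"]:
            store.observations[tuple(obs["pair"])] = set(obs["samples"])
        return store

    def dump_frequencies(self, path: PathLike) -> None:
        """TSV snapshot: pair, samples observed, samples total, frequency."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["gene_a", "gene_b", "n_samples_observed", "n_samples_total", "frequency"]
            )
            total = len(self.samples)
            for key in sorted(self.observations):
                n_obs = len(self.observations[key])
                gene_a = key[0]
                gene_b = key[1] if len(key) == 2 else key[0]
                freq = n_obs / total if total else 0.0
                writer.writerow([gene_a, gene_b, n_obs, total, f"{freq:.6g}"])


def round_half_up_percent(fraction: float, digits: int = 1) -> float:
    """Percentage rounding used in reports (0.318181... -> 31.8)."""
    scale = 10**digits
    return math.floor(fraction * 100 * scale + 0.5) / scale
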