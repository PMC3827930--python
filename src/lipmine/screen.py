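"""Proteome screening: keyword harvest, de-duplication, motif filtering.

Mirrors a portal-style mining run: records whose header matches a keyword
are harvested, exact duplicate sequences are collapsed, and only records
containing every required conserved motif (default GESAG and GGGF) as an
exact substring survive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .records import STANDARD_AA, ProteinRecord
from .synthetic import find_occurrences

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "keyword_harvest",
    "deduplicate",
    "motif_filter",
    "run_screen",
    "genome_of",
]

_GENOME_RE = re.compile(r"\[genome=([^\]]+)\]")


def genome_of(record: ProteinRecord) -> str:
    """Genome tag from a ``[genome=...]`` token in the description, else 'unknown'."""
    m = _GENOME_RE.search(record.description)
    return m.group(1) if m else "unknown"


@dataclass(frozen=True)
class ScreenConfig:
    keywords: tuple[str, ...] = ("esterase", "lipase")
    motifs: tuple[str, ...] = ("GESAG", "GGGF")
    require_all_motifs: bool = True
    dedup: bool = True
    dedup_before_motif: bool = True  # order of the last two stages is debated

    def __post_init__(self):
        object.__setattr__(self, "keywords", tuple(k.lower() for k in self.keywords))
        motifs = tuple(m.upper() for m in self.motifs)
        if not motifs:
            raise ConfigurationError("motifs must be non-empty")
        for m in motifs:
            if not m or any(c not in STANDARD_AA for c in m):
                raise ConfigurationError(
                    f"motif {m!r} must use the 20 standard amino-acid letters"
                )
        object.__setattr__(self, "motifs", motifs)


@dataclass
class ScreenResult:
    survivors: list[ProteinRecord]
    hits: dict[str, dict[str, list[int]]]      # id -> motif -> 1-based starts
    tallies: dict[str, int]                    # stage -> record count
    genome_tallies: pd.DataFrame               # per-genome stage counts
    dedup_map: dict[str, str]                  # removed id -> kept representative

    def to_frame(self) -> pd.DataFrame:
        """One row per (survivor, motif, position)."""
        rows = []
        for rec in self.survivors:
            for motif, positions in self.hits[rec.id].items():
                for pos in positions:
                    rows.append({"id": rec.id, "genome": genome_of(rec),
                                 "motif": motif, "position": pos})
        return pd.DataFrame(rows, columns=["id", "genome", "motif", "position"])

    def summary_json(self) -> str:
        return json.dumps({
            "tallies": self.tallies,
            "n_survivors": len(self.survivors),
            "dedup_removed": len(self.dedup_map),
        }, indent=2, sort_keys=True)


def keyword_harvest(records: list[ProteinRecord],
                    config: ScreenConfig) -> list[ProteinRecord]:
    """Keep records whose description contains any keyword (case-insensitive
    substring on the full header), preserving input order."""
    if not config.keywords:
        raise ConfigurationError("keyword list is empty")
    kept = []
    for rec in records:
        text = rec.header.lower()
        if any(k in text for k in config.keywords):
            kept.append(rec)
    return kept


def deduplicate(records: list[ProteinRecord]) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Drop records with identical residue strings, keeping first occurrence.

    Returns the survivors and a map from each removed id to its kept
    representative.
    """
    seen: dict[str, str] = {}
    kept, removed = [], {}
    for rec in records:
        if rec.seq in seen:
            removed[rec.id] = seen[rec.seq]
        else:
            seen[rec.seq] = rec.id
            kept.append(rec)
    return kept, removed


def motif_filter(records: list[ProteinRecord], config: ScreenConfig
                 ) -> tuple[list[ProteinRecord], dict[str, dict[str, list[int]]]]:
    """Keep records containing the required motifs as exact substrings.

    With ``require_all_motifs`` every motif must occur at least once; all
    occurrence positions (1-based starts, overlaps allowed) are recorded.
    """
    survivors, hits = [], {}
    for rec in records:
        found = {m: find_occurrences(rec.seq, m) for m in config.motifs}
        ok = (all(found[m] for m in config.motifs) if config.require_all_motifs
              else any(found[m] for m in config.motifs))
        if ok:
            survivors.append(rec)
            hits[rec.id] = found
    return survivors, hits


def run_screen(records: list[ProteinRecord],
               config: ScreenConfig | None = None) -> ScreenResult:
    """Full screening chain: keywords -> dedup -> motifs (order per config)."""
    config = config or ScreenConfig()
    stage_sets: list[tuple[str, list[ProteinRecord]]] = [("scanned", list(records))]

    harvested = keyword_harvest(records, config)
    stage_sets.append(("keyword", harvested))

    dedup_map: dict[str, str] = {}
    current = harvested
    if config.dedup and config.dedup_before_motif:
        current, dedup_map = deduplicate(current)
        stage_sets.append(("dedup", current))
    survivors, hits = motif_filter(current, config)
    stage_sets.append(("motif", survivors))
    if config.dedup and not config.dedup_before_motif:
        survivors, dedup_map = deduplicate(survivors)
        hits = {rid: h for rid, h in hits.items() if rid in {r.id for r in survivors}}
        stage_sets.append(("dedup", survivors))

    tallies = {name: len(recs) for name, recs in stage_sets}
    genome_rows = []
    for name, recs in stage_sets:
        counts: dict[str, int] = {}
        for rec in recs:
            g = genome_of(rec)
            counts[g] = counts.get(g, 0) + 1
        for g, c in sorted(counts.items()):
            genome_rows.append({"stage": name, "genome": g, "count": c})
    return ScreenResult(
        survivors=survivors,
        hits=hits,
        tallies=tallies,
        genome_tallies=pd.DataFrame(genome_rows, columns=["stage", "genome", "count"]),
        dedup_map=dedup_map,
    )
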