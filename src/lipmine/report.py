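"""Final per-candidate substrate-preference report.

Combines the stage outputs (screening, placement, sequence features,
tunnel scores) into one deterministic table.  Affinity classes follow the
configured lid-count thresholds; the efficiency flag follows the tunnel
shape class.  The two calls are reported side by side - no merged score
is defined.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import ConfigurationError, JoinError

__all__ = [
    "AffinityThresholds",
    "classify_affinity",
    "classify_efficiency",
    "build_report",
]

AMBIGUOUS_LID_COUNT = 12  # intermediate by default, but reference calls disagree here

REPORT_COLUMNS = [
    "id", "genome", "gesag_position", "gggf_position", "family",
    "identity_percent", "lid_hydrophobic_count", "sequon_count",
    "tunnel_hydrophobic_fraction", "tunnel_shape", "affinity_class",
    "efficiency_flag",
]


@dataclass(frozen=True)
class AffinityThresholds:
    """high: count >= high_min; low: count <= low_max; intermediate between."""

    high_min: int = 13
    low_max: int = 10

    def __post_init__(self):
        if self.high_min <= self.low_max:
            raise ConfigurationError(
                f"overlapping thresholds: high_min={self.high_min} "
                f"must exceed low_max={self.low_max}"
            )


def classify_affinity(lid_count: int,
                      thresholds: AffinityThresholds | None = None) -> str:
    if lid_count < 0:
        raise ConfigurationError("lid_count must be >= 0")
    thresholds = thresholds or AffinityThresholds()
    if lid_count >= thresholds.high_min:
        return "high"
    if lid_count <= thresholds.low_max:
        return "low"
    return "intermediate"


def classify_efficiency(shape_class: str | None) -> str:
    if shape_class is None or shape_class == "NA":
        return "unknown"
    if shape_class == "straight":
        return "OPE-like"
    if shape_class == "bent":
        return "Lip3-like"
    raise ConfigurationError(f"unknown shape class {shape_class!r}")


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def build_report(screen_result,
                 placement=None,
                 feature_table: pd.DataFrame | None = None,
                 tunnel_scores: dict[str, object] | None = None,
                 identity: dict[str, float] | None = None,
                 thresholds: AffinityThresholds | None = None,
                 config: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """One row per screening survivor; missing stages become "NA".

    Returns ``(table, manifest)``.  Raises :class:`JoinError` when a later
    stage reports candidates the screening stage never produced.
    """
    from .screen import genome_of  # local import to avoid a cycle

    thresholds = thresholds or AffinityThresholds()
    survivor_ids = [r.id for r in screen_result.survivors]
    id_set = set(survivor_ids)

    def check_ids(stage: str, ids) -> None:
        orphans = sorted(set(ids) - id_set)
        if orphans:
            raise JoinError(f"{stage} stage reports unknown candidates: {orphans}")

    families, distances = {}, {}
    if placement is not None:
        check_ids("placement", placement.families)
        families = placement.families
        distances = placement.mean_versatile_distance

    lid_counts: dict[str, object] = {}
    sequon_counts: dict[str, object] = {}
    if feature_table is not None and len(feature_table):
        check_ids("features", feature_table["candidate"].unique())
        for cid, grp in feature_table.groupby("candidate"):
            lid = grp.loc[grp["feature"] == "lid_hydrophobic_count", "position"]
            lid_counts[cid] = None if lid.empty or pd.isna(lid.iloc[0]) else int(lid.iloc[0])
            sequon_counts[cid] = int((grp["feature"] == "sequon").sum())

    tunnel_scores = tunnel_scores or {}
    check_ids("tunnels", tunnel_scores)
    identity = identity or {}
    check_ids("identity", identity)

    warnings_list: list[str] = []
    rows = []
    for rec in sorted(screen_result.survivors, key=lambda r: r.id):
        cid = rec.id
        hits = screen_result.hits[cid]
        lid = lid_counts.get(cid)
        score = tunnel_scores.get(cid)
        shape = getattr(score, "shape_class", None) if score is not None else None
        affinity = classify_affinity(lid, thresholds) if lid is not None else "NA"
        if lid == AMBIGUOUS_LID_COUNT:
            warnings_list.append(
                f"{cid}: lid count {AMBIGUOUS_LID_COUNT} sits where reference "
                "affinity calls are inconsistent; classified "
                f"'{affinity}' by the configured thresholds"
            )
        rows.append({
            "id": cid,
            "genome": genome_of(rec),
            "gesag_position": hits.get("GESAG", [None])[0],
            "gggf_position": hits.get("GGGF", [None])[0],
            "family": families.get(cid, "NA"),
            "identity_percent": identity.get(cid, "NA"),
            "lid_hydrophobic_count": lid if lid is not None else "NA",
            "sequon_count": sequon_counts.get(cid, "NA"),
            "tunnel_hydrophobic_fraction":
                getattr(score, "hydrophobic_fraction", "NA") if score else "NA",
            "tunnel_shape": shape if shape is not None else "NA",
            "affinity_class": affinity,
            "efficiency_flag": classify_efficiency(shape),
        })
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    manifest = {
        "config": config or {},
        "thresholds": {"high_min": thresholds.high_min, "low_max": thresholds.low_max},
        "tallies": screen_result.tallies,
        "n_candidates": len(rows),
        "stage_inputs": {
            "placement": placement is not None,
            "features": feature_table is not None,
            "tunnels": bool(tunnel_scores),
        },
        "input_digests": {
            "survivor_sequences": _digest("".join(r.seq for r in screen_result.survivors)),
        },
        "warnings": warnings_list,
    }
    return table, manifest


def report_tsv(table: pd.DataFrame) -> str:
    return table.to_csv(sep="\t", index=False)


def report_json(table: pd.DataFrame, manifest: dict) -> str:
    return json.dumps({"manifest": manifest,
                       "candidates": table.to_dict(orient="records")},
                      indent=2, sort_keys=True)


def manifest_yaml(manifest: dict) -> str:
    return yaml.safe_dump(manifest, sort_keys=True)
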