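"""Reference-anchored sequence feature annotation.

Functional positions known on a reference (catalytic triad, oxyanion
motif, lid-delimiting Cys pair) are transferred onto each candidate
through a global alignment; the lid hydrophobicity statistic and
N-glycosylation sequons are computed on the candidate itself.

All coordinates are 1-based on the mature chain (after optional signal
peptide stripping).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .align import AlignParams, global_align
from .errors import FeatureError, InputError
from .records import STANDARD_AA, ProteinRecord
from .synthetic import DEFAULT_HYDROPHOBIC, GESAG, GGGF

__all__ = [
    "HydrophobicSet",
    "ReferenceAnnotation",
    "FeatureAnnotation",
    "load_reference_annotation",
    "transfer_annotation",
    "lid_hydrophobic_count",
    "find_sequons",
    "strip_signal_peptide",
]

_SEQUON_RE = re.compile(r"(?=N[^P][ST])")

FEATURE_NAMES = ("gggf_start", "gesag_start", "ser", "glu", "his", "cys1", "cys2")


@dataclass(frozen=True)
class HydrophobicSet:
    """The residue letters counted as hydrophobic (config value)."""

    letters: frozenset[str] = DEFAULT_HYDROPHOBIC

    def __post_init__(self):
        letters = frozenset(str(c).upper() for c in self.letters)
        if not letters:
            raise InputError("hydrophobic set must be non-empty")
        bad = letters - set(STANDARD_AA)
        if bad:
            raise InputError(f"non-standard letters in hydrophobic set: {sorted(bad)}")
        object.__setattr__(self, "letters", letters)

    def __contains__(self, letter: str) -> bool:
        return letter.upper() in self.letters


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Mature-chain feature positions on the reference protein."""

    reference_id: str
    gggf_start: int
    gesag_start: int
    ser: int
    glu: int
    his: int
    cys_pair: tuple[int, int]

    def __post_init__(self):
        if not self.gesag_start <= self.ser <= self.gesag_start + len(GESAG) - 1:
            raise InputError("catalytic Ser must lie inside the GESAG occurrence")
        c1, c2 = self.cys_pair
        if not c1 < c2:
            raise InputError("cys_pair must be strictly ordered")
        for name in ("gggf_start", "gesag_start", "ser", "glu", "his"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be a positive 1-based position")

    def positions(self) -> dict[str, int]:
        return {
            "gggf_start": self.gggf_start,
            "gesag_start": self.gesag_start,
            "ser": self.ser,
            "glu": self.glu,
            "his": self.his,
            "cys1": self.cys_pair[0],
            "cys2": self.cys_pair[1],
        }

    def validate_against(self, reference: ProteinRecord) -> None:
        n = len(reference)
        for name, pos in self.positions().items():
            if pos > n:
                raise InputError(f"{name}={pos} outside reference of length {n}")
        if reference.seq[self.gesag_start - 1:self.gesag_start - 1 + len(GESAG)] != GESAG:
            raise InputError("gesag_start does not point at a GESAG occurrence")
        if reference.seq[self.gggf_start - 1:self.gggf_start - 1 + len(GGGF)] != GGGF:
            raise InputError("gggf_start does not point at a GGGF occurrence")
        for pos in self.cys_pair:
            if reference.residue(pos) != "C":
                raise InputError(f"cys position {pos} does not hold Cys in the reference")


def load_reference_annotation(source=None) -> ReferenceAnnotation:
    """Load a reference annotation from YAML (default: the packaged Lip3 file)."""
    if source is None:
        doc = yaml.safe_load(
            resources.files("lipmine.data").joinpath("lip3_annotation.yaml").read_text()
        )
    elif isinstance(source, dict):
        doc = source
    elif isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = yaml.safe_load(str(source))
    return ReferenceAnnotation(
        reference_id=doc["reference_id"],
        gggf_start=int(doc["gggf_start"]),
        gesag_start=int(doc["gesag_start"]),
        ser=int(doc["ser"]),
        glu=int(doc["glu"]),
        his=int(doc["his"]),
        cys_pair=(int(doc["cys_pair"][0]), int(doc["cys_pair"][1])),
    )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Reference features mapped onto one candidate.

    ``positions[name]`` is the mapped 1-based candidate position or None
    when the reference position aligned against a gap; ``status[name]`` is
    "ok", "absent" or "mismatch" (mapped Cys that is not a Cys).
    """

    candidate_id: str
    positions: dict[str, int | None]
    status: dict[str, str]
    lid_span: tuple[int, int] | None   # inclusive, Cys excluded
    lid_sequence: str | None
    sequons: tuple[int, ...]
    signal_len: int | None = None

    def to_rows(self) -> list[dict]:
        rows = [
            {"candidate": self.candidate_id, "feature": name,
             "position": self.positions[name], "status": self.status[name]}
            for name in FEATURE_NAMES
        ]
        for pos in self.sequons:
            rows.append({"candidate": self.candidate_id, "feature": "sequon",
                         "position": pos, "status": "ok"})
        return rows


def find_sequons(sequence: str) -> tuple[int, ...]:
    """1-based positions of N-X(!=P)-[S/T] matches, overlaps allowed.

    Whitespace and line breaks in the input are ignored.
    """
    seq = "".join(str(sequence).split()).upper()
    return tuple(m.start() + 1 for m in _SEQUON_RE.finditer(seq))


def strip_signal_peptide(record: ProteinRecord, cleavage_pos: int) -> ProteinRecord:
    """Residues after ``cleavage_pos``; downstream coordinates are mature-chain."""
    if not 0 <= cleavage_pos < len(record):
        raise InputError(
            f"cleavage_pos {cleavage_pos} outside [0, {len(record) - 1}] "
            f"for record {record.id}"
        )
    if cleavage_pos == 0:
        return record
    return record.with_seq(record.seq[cleavage_pos:],
                           mature_offset=record.mature_offset + cleavage_pos)


def transfer_annotation(candidate: ProteinRecord,
                        reference: ProteinRecord,
                        ref_annot: ReferenceAnnotation,
                        align_params: AlignParams | None = None,
                        hydrophobic: HydrophobicSet | None = None,
                        signal_len: int | None = None) -> FeatureAnnotation:
    """Map reference feature positions onto the candidate via global alignment.

    Features whose reference column aligns to a candidate gap are reported
    "absent"; mapped Cys columns that do not hold Cys in the candidate are
    flagged "mismatch" (the lid is still computed from the mapped columns,
    with a warning).
    """
    if not candidate.seq or not reference.seq:
        raise InputError("cannot annotate an empty sequence")
    ref_annot.validate_against(reference)
    hydrophobic = hydrophobic or HydrophobicSet()
    aln = global_align(reference.seq, candidate.seq, align_params)
    ref_to_cand = aln.column_map()

    positions: dict[str, int | None] = {}
    status: dict[str, str] = {}
    for name, ref_pos in ref_annot.positions().items():
        mapped = ref_to_cand.get(ref_pos)
        positions[name] = mapped
        status[name] = "ok" if mapped is not None else "absent"
    for name in ("cys1", "cys2"):
        pos = positions[name]
        if pos is not None and candidate.residue(pos) != "C":
            status[name] = "mismatch"
            warnings.warn(
                f"{candidate.id}: mapped {name} column {pos} holds "
                f"{candidate.residue(pos)}, not Cys",
                stacklevel=2,
            )

    lid_span = lid_sequence = None
    c1, c2 = positions["cys1"], positions["cys2"]
    if c1 is not None and c2 is not None and c2 - c1 >= 2:
        lid_span = (c1 + 1, c2 - 1)
        lid_sequence = candidate.seq[c1:c2 - 1]

    return FeatureAnnotation(
        candidate_id=candidate.id,
        positions=positions,
        status=status,
        lid_span=lid_span,
        lid_sequence=lid_sequence,
        sequons=find_sequons(candidate.seq),
        signal_len=signal_len,
    )


def lid_hydrophobic_count(annotation: FeatureAnnotation,
                          hydrophobic: HydrophobicSet | None = None) -> int:
    """Number of lid residues whose letter is in the hydrophobic set."""
    if annotation.lid_span is None or annotation.lid_sequence is None:
        raise FeatureError(
            f"{annotation.candidate_id}: lid is undefined (missing Cys pair)"
        )
    hydrophobic = hydrophobic or HydrophobicSet()
    return sum(1 for c in annotation.lid_sequence if c in hydrophobic)


def annotate_all(candidates: list[ProteinRecord], reference: ProteinRecord,
                 ref_annot: ReferenceAnnotation,
                 cleavage: dict[str, int] | None = None,
                 align_params: AlignParams | None = None,
                 hydrophobic: HydrophobicSet | None = None) -> pd.DataFrame:
    """Annotate a batch of candidates; returns a tidy feature table."""
    rows = []
    for rec in candidates:
        signal = (cleavage or {}).get(rec.id, 0)
        mature = strip_signal_peptide(rec, signal)
        annot = transfer_annotation(mature, reference, ref_annot,
                                    align_params, hydrophobic, signal_len=signal)
        rows.extend(annot.to_rows())
        try:
            count = lid_hydrophobic_count(annot, hydrophobic)
        except FeatureError:
            count = None
        rows.append({"candidate": rec.id, "feature": "lid_hydrophobic_count",
                     "position": count, "status": "ok" if count is not None else "absent"})
    return pd.DataFrame(rows, columns=["candidate", "feature", "position", "status"])
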