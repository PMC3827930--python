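"""Synthetic proteomes and toy structures with known ground truth.

Two generators back the whole test strategy:

* :func:`generate_proteome` emits a FASTA-ready list of background proteins
  plus "planted" candidates that carry the screening motifs (GESAG, GGGF),
  a lid-delimiting Cys pair with an exact number of hydrophobic lid
  residues, catalytic Glu/His positions and an exact sequon count.
* :func:`generate_structure` emits a CA-only PDB text of a hollow tunnel
  (straight or bent) whose lining residue set and axis straightness are
  known by construction.

Accidental motif occurrences in background records ("collisions") are
detected by scanning and recorded in the ground-truth table, never
resampled away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConstraintError
from .records import STANDARD_AA, ProteinRecord

__all__ = [
    "DEFAULT_HYDROPHOBIC",
    "ProteomeSpec",
    "PlantedCandidate",
    "ToyStructureSpec",
    "ToyStructure",
    "generate_proteome",
    "generate_structure",
    "default_background_freqs",
]

DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWP")

GESAG = "GESAG"
GGGF = "GGGF"

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}


def default_background_freqs() -> tuple[float, ...]:
    """Uniform over the 20 standard letters with Cys down-weighted to 0.01."""
    p_other = (1.0 - 0.01) / 19.0
    return tuple(0.01 if aa == "C" else p_other for aa in STANDARD_AA)


def find_occurrences(seq: str, motif: str) -> list[int]:
    """All 1-based start positions of ``motif`` in ``seq``, overlaps allowed."""
    out, start = [], 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return out
        out.append(idx + 1)
        start = idx + 1


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSpec:
    n_background: int = 100
    n_planted: int = 0
    length_range: tuple[int, int] = (120, 400)
    background_freqs: tuple[float, ...] = field(default_factory=default_background_freqs)
    keyword_fraction: float = 0.3
    seed: int = 0
    n_genomes: int = 1

    def __post_init__(self):
        if self.n_background < 0:
            raise ConstraintError("n_background must be >= 0")
        if self.n_planted < 0:
            raise ConstraintError("n_planted must be >= 0")
        lo, hi = self.length_range
        if lo < 60 or hi < lo:
            raise ConstraintError("length_range: min length >= 60 and min <= max required")
        freqs = tuple(self.background_freqs)
        if len(freqs) != 20:
            raise ConstraintError("background_freqs must have 20 entries")
        if any(f < 0 for f in freqs):
            raise ConstraintError("background_freqs must be non-negative")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ConstraintError("background_freqs must sum to 1 within 1e-9")
        if not 0.0 <= self.keyword_fraction <= 1.0:
            raise ConstraintError("keyword_fraction must lie in [0, 1]")
        if self.n_genomes < 1:
            raise ConstraintError("n_genomes must be >= 1")
        object.__setattr__(self, "background_freqs", freqs)


@dataclass(frozen=True)
class PlantedCandidate:
    """Ground-truth feature layout for one planted candidate.

    All positions are 1-based indices into the emitted record (including
    the signal peptide region of length ``signal_len`` at the N-terminus).
    """

    oxyanion_pos: int          # start of GGGF
    shoulder_pos: int          # start of GESAG; catalytic Ser = shoulder_pos + 2
    cys_positions: tuple[int, int]
    lid_hydrophobic_count: int
    triad_glu_pos: int
    triad_his_pos: int
    sequon_count: int = 1
    signal_len: int = 0

    def __post_init__(self):
        c1, c2 = self.cys_positions
        if not self.oxyanion_pos < self.shoulder_pos:
            raise ConstraintError("oxyanion_pos must precede shoulder_pos")
        if not c1 < c2:
            raise ConstraintError("cys_positions must be strictly ordered")
        if self.lid_hydrophobic_count < 0:
            raise ConstraintError("lid_hydrophobic_count must be >= 0")
        if self.lid_length < self.lid_hydrophobic_count:
            raise ConstraintError(
                "lid_hydrophobic_count exceeds lid span length "
                f"({self.lid_hydrophobic_count} > {self.lid_length})"
            )
        if self.sequon_count < 0:
            raise ConstraintError("sequon_count must be >= 0")
        if self.signal_len < 0:
            raise ConstraintError("signal_len must be >= 0")
        spans = self.feature_spans()
        flat: list[tuple[int, int, str]] = sorted(
            (lo, hi, name) for name, (lo, hi) in spans.items()
        )
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(flat, flat[1:]):
            if lo2 <= hi1:
                raise ConstraintError(f"planted features overlap: {n1} and {n2}")
        if min(lo for lo, _, _ in flat) <= self.signal_len:
            raise ConstraintError("planted features must lie after signal_len")

    @property
    def lid_span(self) -> tuple[int, int]:
        """Residues strictly between the Cys pair (1-based, inclusive)."""
        c1, c2 = self.cys_positions
        return (c1 + 1, c2 - 1)

    @property
    def lid_length(self) -> int:
        lo, hi = self.lid_span
        return max(0, hi - lo + 1)

    def feature_spans(self) -> dict[str, tuple[int, int]]:
        c1, c2 = self.cys_positions
        return {
            "gggf": (self.oxyanion_pos, self.oxyanion_pos + len(GGGF) - 1),
            "gesag": (self.shoulder_pos, self.shoulder_pos + len(GESAG) - 1),
            # Cys delimiters and the lid between them form one reserved block.
            "lid_block": (c1, c2),
            "glu": (self.triad_glu_pos, self.triad_glu_pos),
            "his": (self.triad_his_pos, self.triad_his_pos),
        }

    @property
    def min_length(self) -> int:
        return max(hi for _, hi in self.feature_spans().values())


_KEYWORD_DESCS = (
    "putative sterol esterase",
    "secreted lipase precursor",
    "triacylglycerol lipase family protein",
    "carboxylesterase/lipase-like protein",
)
_NEUTRAL_DESCS = (
    "hypothetical protein",
    "serine/threonine protein kinase",
    "cytochrome P450 monooxygenase",
    "ABC transporter permease",
    "glycoside hydrolase family protein",
)

# Letters usable as neutral filler inside planted records: no N (sequon
# control), no C (lid-delimiter control), nothing hydrophobic (lid control).
_NEUTRAL_FILL = "DEGHKQRSTY"


def _draw_letters(rng: np.random.Generator, n: int, freqs: Sequence[float],
                  exclude: str = "") -> np.ndarray:
    letters = np.array(list(STANDARD_AA))
    p = np.array(freqs, dtype=float)
    if exclude:
        keep = ~np.isin(letters, list(exclude))
        letters, p = letters[keep], p[keep]
        if p.sum() <= 0:
            raise ConstraintError("background_freqs exclude all usable letters")
        p = p / p.sum()
    return rng.choice(letters, size=n, p=p)


def _build_planted_seq(rng: np.random.Generator, plant: PlantedCandidate,
                       spec: ProteomeSpec, hydrophobic: frozenset[str]) -> str:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    length = max(length, plant.min_length + 12 + 3 * plant.sequon_count)
    # Fill with background letters, excluding N/C and hydrophobics so the
    # planted counts stay exact; sequons and lid content are planted below.
    seq = _draw_letters(rng, length, spec.background_freqs,
                        exclude="NC" + "".join(sorted(hydrophobic)))
    reserved = np.zeros(length, dtype=bool)

    def put(pos1: int, text: str):
        i = pos1 - 1
        seq[i:i + len(text)] = list(text)
        reserved[i:i + len(text)] = True

    if plant.signal_len:
        sig = ["M"] + list(rng.choice(list("ALVFI"), size=plant.signal_len - 1))
        put(1, "".join(sig))
    put(plant.oxyanion_pos, GGGF)
    put(plant.shoulder_pos, GESAG)
    c1, c2 = plant.cys_positions
    put(c1, "C")
    put(c2, "C")
    lid_lo, lid_hi = plant.lid_span
    lid_cells = np.arange(lid_lo - 1, lid_hi)
    hydro_cells = rng.choice(lid_cells, size=plant.lid_hydrophobic_count, replace=False)
    hydro_letters = sorted(hydrophobic)
    for cell in np.sort(hydro_cells):
        seq[cell] = rng.choice(hydro_letters)
    for cell in lid_cells:
        if cell not in hydro_cells:
            seq[cell] = rng.choice(list(_NEUTRAL_FILL))
    reserved[lid_lo - 1:lid_hi] = True
    put(plant.triad_glu_pos, "E")
    put(plant.triad_his_pos, "H")
    # Plant sequons (N-A-S/T) in free slots after the signal peptide.
    free = [i for i in range(plant.signal_len, length - 2)
            if not reserved[i:i + 3].any()]
    planted_sequons = 0
    rng.shuffle(free)
    taken: set[int] = set()
    for i in free:
        if planted_sequons == plant.sequon_count:
            break
        if {i, i + 1, i + 2} & taken:
            continue
        seq[i] = "N"
        seq[i + 1] = "A"
        seq[i + 2] = rng.choice(["S", "T"])
        taken |= {i, i + 1, i + 2}
        planted_sequons += 1
    if planted_sequons < plant.sequon_count:
        raise ConstraintError(
            f"sequon_count: only {planted_sequons} of {plant.sequon_count} sequons fit"
        )
    return "".join(seq)


def _scan_sequons(seq: str) -> list[int]:
    return [i + 1 for i in range(len(seq) - 2)
            if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"]


def generate_proteome(
    spec: ProteomeSpec,
    planted: Sequence[PlantedCandidate] = (),
    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Emit ``n_background + n_planted`` records plus a ground-truth table.

    The table has one row per record with the scanned motif positions
    (columns ``gesag_positions``/``gggf_positions``, ";"-joined 1-based
    starts), a ``both_motifs`` flag (True for planted records and for
    background collisions alike), and the planted feature layout for
    planted rows.
    """
    if len(planted) != spec.n_planted:
        raise ConstraintError(
            f"n_planted: got {len(planted)} planted candidates for n_planted={spec.n_planted}"
        )
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    rows: list[dict] = []

    def genome_of(i: int) -> str:
        return f"syn{i % spec.n_genomes:02d}"

    for i, plant in enumerate(planted):
        seq = _build_planted_seq(rng, plant, spec, hydrophobic)
        rid = f"cand_{i + 1:02d}"
        genome = genome_of(i)
        desc = f"{_KEYWORD_DESCS[i % len(_KEYWORD_DESCS)]} [genome={genome}]"
        records.append(ProteinRecord(id=rid, seq=seq, description=desc))
        sequons = _scan_sequons(seq)
        if len(sequons) != plant.sequon_count:
            raise ConstraintError(
                f"sequon_count: planting produced {len(sequons)} sequons, "
                f"expected {plant.sequon_count}"
            )
        rows.append({
            "id": rid, "kind": "planted", "genome": genome, "keyword": True,
            "gesag_positions": ";".join(map(str, find_occurrences(seq, GESAG))),
            "gggf_positions": ";".join(map(str, find_occurrences(seq, GGGF))),
            "both_motifs": True,
            "oxyanion_pos": plant.oxyanion_pos, "shoulder_pos": plant.shoulder_pos,
            "cys1": plant.cys_positions[0], "cys2": plant.cys_positions[1],
            "lid_hydrophobic_count": plant.lid_hydrophobic_count,
            "triad_glu_pos": plant.triad_glu_pos, "triad_his_pos": plant.triad_his_pos,
            "sequon_count": plant.sequon_count, "signal_len": plant.signal_len,
        })

    lo, hi = spec.length_range
    for i in range(spec.n_background):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_draw_letters(rng, length, spec.background_freqs))
        keyword = bool(rng.random() < spec.keyword_fraction)
        pool = _KEYWORD_DESCS if keyword else _NEUTRAL_DESCS
        rid = f"bg_{i + 1:04d}"
        genome = genome_of(spec.n_planted + i)
        desc = f"{pool[i % len(pool)]} [genome={genome}]"
        records.append(ProteinRecord(id=rid, seq=seq, description=desc))
        ges = find_occurrences(seq, GESAG)
        ggg = find_occurrences(seq, GGGF)
        rows.append({
            "id": rid, "kind": "background", "genome": genome, "keyword": keyword,
            "gesag_positions": ";".join(map(str, ges)),
            "gggf_positions": ";".join(map(str, ggg)),
            "both_motifs": bool(ges and ggg),
        })

    truth = pd.DataFrame(rows)
    for col in ("oxyanion_pos", "shoulder_pos", "cys1", "cys2",
                "lid_hydrophobic_count", "triad_glu_pos", "triad_his_pos",
                "sequon_count", "signal_len"):
        if col in truth.columns:
            truth[col] = truth[col].astype("Int64")
    return records, truth


# ---------------------------------------------------------------------------
# Toy structure generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureSpec:
    n_shell_residues: int = 1000  # budget: generation fails if the wall needs more
    tunnel_radius: float = 2.9
    tunnel_length: float = 30.0
    bend_angle: float = 0.0
    seed_residue: int = 1
    lattice_jitter: float = 0.15
    seed: int = 0
    n_exits: int = 1
    decoy_residues: int = 40

    def __post_init__(self):
        if self.tunnel_radius < 1.4:
            raise ConstraintError("tunnel_radius must be >= 1.4 (probe passable)")
        if not 0.0 <= self.bend_angle <= 120.0:
            raise ConstraintError("bend_angle must lie in [0, 120] degrees")
        if self.tunnel_length <= 0:
            raise ConstraintError("tunnel_length must be > 0")
        if self.lattice_jitter < 0:
            raise ConstraintError("lattice_jitter must be >= 0")
        if self.seed_residue < 1:
            raise ConstraintError("seed_residue must be a positive residue number")
        if self.n_exits not in (1, 2):
            raise ConstraintError("n_exits must be 1 or 2")
        if self.n_shell_residues < 0 or self.decoy_residues < 0:
            raise ConstraintError("residue counts must be >= 0")


@dataclass(frozen=True)
class ToyStructure:
    pdb_text: str
    lining: frozenset[int]          # ground-truth lining residue numbers (4 A rule)
    straightness: float             # ground-truth axis chord / arc length
    axes: tuple[np.ndarray, ...]    # axis polylines, one per exit
    residues: pd.DataFrame          # resnum, resname, role, x, y, z, axis_distance


_SPACING = 1.5  # target atom spacing on walls, Angstrom


def _axis_polyline(spec: ToyStructureSpec) -> list[np.ndarray]:
    """Axis polylines starting at the buried end (origin)."""
    theta = math.radians(spec.bend_angle)
    if spec.n_exits == 2:
        up = np.array([[0, 0, 0], [0, 0, spec.tunnel_length]], dtype=float)
        down = np.array([
            [0, 0, 0],
            [spec.tunnel_length * math.sin(theta), 0, -spec.tunnel_length * math.cos(theta)],
        ])
        return [up, down]
    if spec.bend_angle == 0:
        return [np.array([[0, 0, 0], [0, 0, spec.tunnel_length]], dtype=float)]
    half = spec.tunnel_length / 2.0
    p1 = np.array([0.0, 0.0, half])
    d2 = np.array([math.sin(theta), 0.0, math.cos(theta)])
    return [np.vstack([[0, 0, 0], p1, p1 + half * d2])]


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = np.cross(d, helper)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(d, n1)
    return n1, n2


def _ring(center: np.ndarray, n1: np.ndarray, n2: np.ndarray,
          radius: float, phase: float) -> np.ndarray:
    n = max(6, int(math.ceil(2 * math.pi * radius / _SPACING)))
    angles = phase + 2 * math.pi * np.arange(n) / n
    return center + radius * (np.outer(np.cos(angles), n1) + np.outer(np.sin(angles), n2))


def _cap_points(axis: np.ndarray, radius: float) -> np.ndarray:
    """Two-layer disk sealing the buried axis end (a leak here would put
    free space right behind the seed residue)."""
    points = []
    d0 = axis[1] - axis[0]
    d0 = d0 / np.linalg.norm(d0)
    n1, n2 = _frame(d0)
    golden = math.pi * (3 - math.sqrt(5))
    r, k = _SPACING, 0
    while r < radius - 1e-9:
        points.append(_ring(axis[0], n1, n2, r, golden * k))
        r, k = r + _SPACING, k + 1
    back = axis[0] - _SPACING * d0
    points.append(back[None, :])
    r = _SPACING
    while r < radius + _SPACING - 1e-9:
        points.append(_ring(back, n1, n2, min(r, radius), golden * k))
        r, k = r + _SPACING, k + 1
    return np.vstack(points)


def _wall_points(axis: np.ndarray, radius: float) -> np.ndarray:
    points = []
    golden = math.pi * (3 - math.sqrt(5))
    ring_index = 0
    for a, b in zip(axis[:-1], axis[1:]):
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        n1, n2 = _frame(seg)
        s = 0.0
        while s <= seg_len + 1e-9:
            points.append(_ring(a + (s / seg_len) * seg, n1, n2, radius,
                                golden * ring_index))
            ring_index += 1
            s += _SPACING
    # Elbow patches: extra rings with interpolated directions close outer gaps.
    for i in range(1, len(axis) - 1):
        d1 = axis[i] - axis[i - 1]
        d2 = axis[i + 1] - axis[i]
        d1, d2 = d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)
        for t in (0.25, 0.5, 0.75):
            d = (1 - t) * d1 + t * d2
            if np.linalg.norm(d) < 1e-6:
                continue
            n1, n2 = _frame(d)
            points.append(_ring(axis[i], n1, n2, radius, golden * ring_index))
            ring_index += 1
    return np.vstack(points)


def point_polyline_distance(points: np.ndarray, polyline: np.ndarray,
                            return_projections: bool = False):
    """Distance of each point to the nearest segment of a polyline."""
    points = np.atleast_2d(points)
    best = np.full(len(points), np.inf)
    best_proj = np.zeros_like(points)
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom > 0:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            proj = a + np.outer(t, ab)
        else:
            proj = np.broadcast_to(a, points.shape)
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best
        best = np.where(better, d, best)
        best_proj[better] = proj[better]
    if return_projections:
        return best, best_proj
    return best


def _format_pdb(resnums, resnames, coords) -> str:
    lines = []
    for serial, (num, name, xyz) in enumerate(zip(resnums, resnames, coords), start=1):
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial % 100000:>5}  CA  {name:>3} A{num:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_structure(spec: ToyStructureSpec) -> ToyStructure:
    """CA-only toy structure with a hollow tunnel of known lining.

    The seed residue's CA sits at the buried axis end (the origin); the
    wall is a cylindrical shell of radius ``tunnel_radius`` around each
    axis, closed by a disk cap at the buried end for single-exit specs.
    Ground-truth lining is every residue whose CA lies within 4 A of the
    axis polyline; ground-truth straightness is chord over arc length of
    the (single-exit) axis.
    """
    rng = np.random.default_rng(spec.seed)
    axes = _axis_polyline(spec)

    # Seed CA: at the buried axis end for single-exit tunnels; for a
    # through-tunnel (two exits) an on-axis atom would plug the junction,
    # so the seed sits on the wall beside it, like a catalytic Ser.
    if spec.n_exits == 1:
        seed_xyz = np.zeros((1, 3))
        blister = np.empty((0, 3))
    else:
        seed_xyz = np.array([[spec.tunnel_radius, 0.0, 0.0]])
        # Patch of wall covering the seed from outside, so the free voxel
        # nearest the seed is in the tunnel, not in open space.
        yy, zz = np.meshgrid(np.arange(-3.0, 3.1, 1.5), np.arange(-3.0, 3.1, 1.5))
        blister = np.column_stack([
            np.full(yy.size, spec.tunnel_radius + 1.5), yy.ravel(), zz.ravel(),
        ])
    coords = [seed_xyz]
    roles = ["seed"]
    n_wall = 0
    wall = np.vstack([_wall_points(axis, spec.tunnel_radius) for axis in axes])
    # Wall points that poke into any axis's hollow volume (ring planes at
    # bends and shared origins would otherwise seal the corridor) are
    # projected outward onto the tunnel surface, forming a tight elbow.
    for _ in range(3):
        dist_axis = np.full(len(wall), np.inf)
        proj = np.zeros_like(wall)
        for axis in axes:
            d, p = point_polyline_distance(wall, axis, return_projections=True)
            closer = d < dist_axis
            dist_axis = np.where(closer, d, dist_axis)
            proj[closer] = p[closer]
        intruding = dist_axis < spec.tunnel_radius - 1e-6
        if not intruding.any():
            break
        safe = intruding & (dist_axis > 1e-6)
        u = wall[safe] - proj[safe]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        wall[safe] = proj[safe] + spec.tunnel_radius * u
        wall = wall[~(intruding & ~safe)]  # points exactly on an axis: drop
    coords.append(wall)
    roles.extend(["wall"] * len(wall))
    n_wall += len(wall)
    if spec.n_exits == 1:
        cap = _cap_points(axes[0], spec.tunnel_radius)
        coords.append(cap)
        roles.extend(["cap"] * len(cap))
        n_wall += len(cap)
    else:
        coords.append(blister)
        roles.extend(["cap"] * len(blister))
        n_wall += len(blister)
    if n_wall > spec.n_shell_residues:
        raise ConstraintError(
            f"n_shell_residues: a leak-free wall needs {n_wall} residues, "
            f"budget is {spec.n_shell_residues}"
        )
    if spec.decoy_residues:
        center = np.array([-(spec.tunnel_radius + 12.0), 0.0, spec.tunnel_length / 2.0])
        decoys = center + rng.normal(scale=2.5, size=(spec.decoy_residues, 3))
        coords.append(decoys)
        roles.extend(["decoy"] * len(decoys))
    xyz = np.vstack(coords)
    if spec.lattice_jitter:
        xyz = xyz + rng.uniform(-spec.lattice_jitter, spec.lattice_jitter, xyz.shape)

    n = len(xyz)
    resnums = [spec.seed_residue + i for i in range(n)]
    resnames = [AA3[aa] for aa in rng.choice(list(STANDARD_AA), size=n)]

    dist = np.full(n, np.inf)
    for axis in axes:
        dist = np.minimum(dist, point_polyline_distance(xyz, axis))
    lining = frozenset(num for num, d in zip(resnums, dist) if d <= 4.0)
    if not lining:
        raise ConstraintError("ground-truth lining set is empty; enlarge the tunnel")

    axis0 = axes[0]
    arc = float(np.sum(np.linalg.norm(np.diff(axis0, axis=0), axis=1)))
    chord = float(np.linalg.norm(axis0[-1] - axis0[0]))
    straightness = chord / arc

    residues = pd.DataFrame({
        "resnum": resnums,
        "resname": resnames,
        "role": roles,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "axis_distance": dist,
    })
    return ToyStructure(
        pdb_text=_format_pdb(resnums, resnames, xyz),
        lining=lining,
        straightness=straightness,
        axes=tuple(axes),
        residues=residues,
    )
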