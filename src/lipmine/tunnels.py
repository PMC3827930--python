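"""Tunnel detection from the catalytic serine and lining hydrophobicity.

A simplified grid/breadth-first tunnel finder: the structure's bounding
box (plus margin) is voxelized in a canonical frame derived from the atom
coordinates (centroid + principal axes), a voxel being "free" when its
center is farther than ``atom_radius + probe_radius`` from every atom
center.  A breadth-first search from the free voxel nearest the seed
residue's reference atom (OG if present, else CA) reaches the grid
boundary; the shortest path, truncated at the molecular surface and
smoothed by collinear-point elision plus line-of-sight shortcutting, is
the tunnel centerline.

Because the grid lives in the canonical frame, translating or rotating
the input coordinates leaves lining sets, fractions and straightness
unchanged.

Lining residues are those with any atom within a cutoff (default 4 A) of
any centerline point; the hydrophobic fraction is reported as a
percentage rounded half-up to the nearest integer.
"""

from __future__ import annotations

import math
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .errors import InputError, ParseError
from .features import HydrophobicSet
from .synthetic import AA1

__all__ = [
    "Atom",
    "Structure",
    "Tunnel",
    "TunnelScore",
    "TunnelParams",
    "read_structure",
    "find_tunnels",
    "score_tunnel",
    "classify_shape",
    "centerline_pdb",
]

_NEIGHBOR_STEPS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)


@dataclass
class Structure:
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise InputError("structure contains no atoms")
        self.coords = np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)
        if not np.isfinite(self.coords).all():
            raise InputError("non-finite atom coordinates")
        # residue order of first appearance
        self._residues: "OrderedDict[tuple, str]" = OrderedDict()
        for a in self.atoms:
            self._residues.setdefault(a.residue_id, a.resname)
        last: dict[str, int] = {}
        for rid in self._residues:
            chain, resseq, _ = rid
            if chain in last and resseq < last[chain]:
                warnings.warn(
                    f"residue numbers not increasing in chain {chain!r} "
                    f"(at {resseq} after {last[chain]})",
                    stacklevel=2,
                )
                break
            last[chain] = resseq

    @property
    def residues(self) -> list[tuple[tuple[str, int, str], str]]:
        return list(self._residues.items())

    def seed_reference_point(self, seed_residue) -> np.ndarray:
        """Coordinates of the seed residue's OG atom (else CA, else first)."""
        if isinstance(seed_residue, int):
            match = [a for a in self.atoms if a.resseq == seed_residue]
        else:
            chain, resseq = seed_residue[0], int(seed_residue[1])
            icode = seed_residue[2] if len(seed_residue) > 2 else ""
            match = [a for a in self.atoms
                     if a.chain == chain and a.resseq == resseq and a.icode == icode]
        if not match:
            raise InputError(f"seed residue {seed_residue!r} not found in structure")
        for name in ("OG", "CA"):
            for a in match:
                if a.name == name:
                    return np.array([a.x, a.y, a.z])
        a = match[0]
        return np.array([a.x, a.y, a.z])


def read_structure(pdb_text: str | Path) -> Structure:
    """Parse ATOM/HETATM records from fixed-column PDB text.

    Only altloc ' ' or 'A' is kept (a warning reports how many alternate
    locations were dropped); insertion codes are preserved in residue ids.
    """
    if isinstance(pdb_text, Path) or (isinstance(pdb_text, str)
                                      and "\n" not in pdb_text
                                      and Path(pdb_text).is_file()):
        pdb_text = Path(pdb_text).read_text()
    atoms: list[Atom] = []
    dropped_altloc = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            altloc = line[16:17].strip()
            atom = Atom(
                serial=int(line[6:11]),
                name=line[12:16].strip(),
                altloc=altloc,
                resname=line[17:20].strip(),
                chain=line[21:22].strip(),
                resseq=int(line[22:26]),
                icode=line[26:27].strip(),
                x=float(line[30:38]),
                y=float(line[38:46]),
                z=float(line[46:54]),
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed ATOM record ({exc})", lineno) from exc
        if atom.altloc not in ("", "A"):
            dropped_altloc += 1
            continue
        atoms.append(atom)
    if dropped_altloc:
        warnings.warn(f"dropped {dropped_altloc} alternate-location atoms "
                      "(keeping altloc ' ' or 'A')", stacklevel=2)
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")
    return Structure(atoms=atoms)


@dataclass(frozen=True)
class TunnelParams:
    grid_step: float = 0.8
    probe_radius: float = 1.4
    atom_radius: float = 1.7       # united-atom radius, all elements
    max_tunnels: int = 2
    margin: float = 4.0
    mouth_min_separation: float = 8.0

    def __post_init__(self):
        if self.grid_step <= 0 or self.probe_radius <= 0 or self.atom_radius <= 0:
            raise InputError("grid_step, probe_radius and atom_radius must be > 0")
        if self.max_tunnels < 1:
            raise InputError("max_tunnels must be >= 1")

    @property
    def clearance(self) -> float:
        return self.atom_radius + self.probe_radius


@dataclass(frozen=True)
class Tunnel:
    centerline: np.ndarray        # (n, 3) points, input frame, seed -> mouth
    radii: np.ndarray             # per-point clearance radius, A
    seed_residue: object
    mouth: np.ndarray             # surface exit point, input frame
    arc_length: float
    straightness: float           # chord / arc length, in (0, 1]

    def __post_init__(self):
        if len(self.centerline) < 2:
            raise InputError("a tunnel needs at least 2 centerline points")

    @property
    def bottleneck_radius(self) -> float:
        return float(np.min(self.radii))


@dataclass(frozen=True)
class TunnelScore:
    lining_residues: tuple[tuple[str, int, str], ...]
    hydrophobic_count: int
    total_count: int
    hydrophobic_fraction: int     # percent, rounded half-up
    shape_class: str              # "straight" or "bent"


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal-axis rotation with deterministic sign choice.

    Axis signs follow the third moment (skewness) of the coordinate
    distribution along each axis, which is invariant under rigid motion of
    the input; the rare symmetric case falls back to a fixed rule.
    """
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order].T  # rows are principal directions
    for i in range(2):
        proj = centered @ axes[i]
        scale = max(float(np.std(proj)), 1e-12)
        skew = float(np.mean(proj ** 3)) / scale ** 3
        if abs(skew) > 1e-6:
            if skew < 0:
                axes[i] = -axes[i]
        elif axes[i][int(np.argmax(np.abs(axes[i])))] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return center, axes


def _polyline_arc(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _elide_collinear(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    if len(points) <= 2:
        return points
    keep = [0]
    for i in range(1, len(points) - 1):
        a, b, c = points[keep[-1]], points[i], points[i + 1]
        if np.linalg.norm(np.cross(b - a, c - b)) > tol:
            keep.append(i)
    keep.append(len(points) - 1)
    return points[keep]


def _segment_is_free(a: np.ndarray, b: np.ndarray, tree: cKDTree,
                     clearance: float, step: float) -> bool:
    n = max(2, int(math.ceil(np.linalg.norm(b - a) / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    samples = a + np.outer(t, b - a)
    d, _ = tree.query(samples)
    return bool(np.all(d > clearance))


def _string_pull(points: np.ndarray, tree: cKDTree, clearance: float,
                 step: float) -> np.ndarray:
    out = [0]
    i = 0
    last = len(points) - 1
    while i < last:
        j = last
        while j > i + 1 and not _segment_is_free(points[i], points[j], tree,
                                                 clearance, step):
            j -= 1
        out.append(j)
        i = j
    return points[out]


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return points[:1]
    n = max(2, int(math.ceil(total / spacing)) + 1)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, cum, points[:, k])
    return out


def find_tunnels(structure: Structure, seed_residue,
                 params: TunnelParams | None = None) -> list[Tunnel]:
    """Detect up to ``params.max_tunnels`` tunnels from the seed residue.

    Returns an empty list when the seed region has no free voxel or no
    path to the boundary.  Tunnels are ranked by bottleneck radius
    (descending) then arc length (ascending); mouths of distinct tunnels
    are separated by more than ``params.mouth_min_separation``.
    """
    params = params or TunnelParams()
    seed_world = structure.seed_reference_point(seed_residue)
    center, axes = _canonical_frame(structure.coords)
    coords = (structure.coords - center) @ axes.T
    seed_point = (seed_world - center) @ axes.T

    lo = coords.min(axis=0) - params.margin
    hi = coords.max(axis=0) + params.margin
    shape = np.maximum(np.ceil((hi - lo) / params.grid_step).astype(int), 2)
    axes_1d = [lo[k] + (np.arange(shape[k]) + 0.5) * params.grid_step for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes_1d, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    tree = cKDTree(coords)
    nearest, _ = tree.query(centers, workers=-1)
    nearest = nearest.reshape(tuple(shape))
    free = nearest > params.clearance

    # Seed voxel: nearest free voxel to the seed point, within a local search
    # radius; a buried seed in a solid block has none -> no tunnels.
    free_idx = np.argwhere(free)
    if len(free_idx) == 0:
        return []
    free_centers = lo + (free_idx + 0.5) * params.grid_step
    d_seed = np.linalg.norm(free_centers - seed_point, axis=1)
    search_radius = params.clearance + 3.0 * params.grid_step
    order = np.lexsort((free_idx[:, 2], free_idx[:, 1], free_idx[:, 0], d_seed))
    best = order[0]
    if d_seed[best] > search_radius:
        return []
    start = tuple(free_idx[best])

    # Level-synchronous BFS (6-connectivity) with parent directions.
    dist = np.full(tuple(shape), -1, dtype=np.int32)
    parent = np.full(tuple(shape), -1, dtype=np.int8)
    dist[start] = 0
    frontier = np.zeros(tuple(shape), dtype=bool)
    frontier[start] = True
    level = 0
    while frontier.any():
        level += 1
        nxt = np.zeros_like(frontier)
        for di, (sx, sy, sz) in enumerate(_NEIGHBOR_STEPS):
            shifted = np.roll(frontier, (sx, sy, sz), axis=(0, 1, 2))
            # zero out wrap-around
            if sx:
                shifted[0 if sx > 0 else -1, :, :] = False
            if sy:
                shifted[:, 0 if sy > 0 else -1, :] = False
            if sz:
                shifted[:, :, 0 if sz > 0 else -1] = False
            newly = shifted & free & (dist < 0)
            parent[newly] = di
            dist[newly] = level
            nxt |= newly
        frontier = nxt

    boundary_mask = np.zeros(tuple(shape), dtype=bool)
    boundary_mask[0, :, :] = boundary_mask[-1, :, :] = True
    boundary_mask[:, 0, :] = boundary_mask[:, :, 0] = True
    boundary_mask[:, -1, :] = boundary_mask[:, :, -1] = True
    reached = boundary_mask & (dist >= 0)
    if not reached.any():
        return []

    exits = np.argwhere(reached)
    exit_dists = dist[reached]
    order = np.lexsort((exits[:, 2], exits[:, 1], exits[:, 0], exit_dists))
    exits = exits[order]

    def reconstruct(end_idx: tuple[int, int, int]) -> np.ndarray:
        path = [end_idx]
        cur = end_idx
        while cur != start:
            di = parent[cur]
            sx, sy, sz = _NEIGHBOR_STEPS[di]
            cur = (cur[0] - sx, cur[1] - sy, cur[2] - sz)
            path.append(cur)
        path.reverse()
        return lo + (np.array(path) + 0.5) * params.grid_step

    # The tunnel ends where the path leaves the molecular envelope,
    # approximated by the convex hull of the atom centers.
    hull = Delaunay(coords)
    tunnels: list[Tunnel] = []
    accepted_trees: list[cKDTree] = []
    accepted_mouths: list[np.ndarray] = []

    def near_accepted(point: np.ndarray) -> bool:
        # A distinct tunnel must exit far from every point of an accepted
        # centerline, not merely far from its mouth; this rejects paths
        # that wrap around the outside of an already-found exit.
        return any(t.query(point)[0] <= params.mouth_min_separation
                   for t in accepted_trees)

    for exit_idx in exits:
        if len(tunnels) >= params.max_tunnels:
            break
        raw = reconstruct(tuple(exit_idx))
        outside = np.nonzero(hull.find_simplex(raw) < 0)[0]
        cut = int(outside[0]) if len(outside) else len(raw)
        trimmed = raw[:max(cut, 2)]
        if len(trimmed) < 2:
            continue
        mouth_canon = trimmed[-1]
        if near_accepted(mouth_canon):
            continue
        # A path that runs through an accepted mouth re-uses that exit and
        # merely wanders on after it; it is not a distinct tunnel.
        if accepted_mouths and cKDTree(accepted_mouths).query(trimmed)[0].min() \
                <= params.mouth_min_separation:
            continue
        smooth = _string_pull(_elide_collinear(trimmed), tree,
                              params.clearance, params.grid_step / 2.0)
        centerline_canon = _resample(smooth, params.grid_step)
        if len(centerline_canon) < 2:
            continue
        radii_d, _ = tree.query(centerline_canon)
        radii = radii_d - params.atom_radius
        arc = _polyline_arc(smooth)
        chord = float(np.linalg.norm(smooth[-1] - smooth[0]))
        straightness = chord / arc if arc > 0 else 1.0
        centerline_world = centerline_canon @ axes + center
        mouth_world = mouth_canon @ axes + center
        tunnels.append(Tunnel(
            centerline=centerline_world,
            radii=radii,
            seed_residue=seed_residue,
            mouth=mouth_world,
            arc_length=arc,
            straightness=min(straightness, 1.0),
        ))
        accepted_trees.append(cKDTree(centerline_canon))
        accepted_mouths.append(mouth_canon)

    tunnels.sort(key=lambda t: (-t.bottleneck_radius, t.arc_length))
    return tunnels


def classify_shape(tunnel: Tunnel, threshold: float = 0.85) -> str:
    """"straight" iff straightness >= threshold, else "bent"."""
    return "straight" if tunnel.straightness >= threshold else "bent"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def score_tunnel(structure: Structure, tunnel,
                 hydrophobic: HydrophobicSet | None = None,
                 cutoff: float = 4.0,
                 shape_threshold: float = 0.85) -> TunnelScore:
    """Lining residues within ``cutoff`` of the centerline and their
    hydrophobic fraction.

    ``tunnel`` may be a single :class:`Tunnel` or a list; with a list the
    lining is the union over all tunnels and the shape class is that of
    the exit tunnel (the second-ranked one when present, else the first).
    """
    tunnels = [tunnel] if isinstance(tunnel, Tunnel) else list(tunnel)
    if not tunnels:
        raise InputError("score_tunnel needs at least one tunnel")
    hydrophobic = hydrophobic or HydrophobicSet()

    tree = cKDTree(structure.coords)
    atom_idx: set[int] = set()
    for t in tunnels:
        for hits in tree.query_ball_point(t.centerline, cutoff):
            atom_idx.update(hits)
    residue_order = {rid: k for k, (rid, _) in enumerate(structure.residues)}
    lining: dict[tuple, str] = {}
    for i in sorted(atom_idx):
        a = structure.atoms[i]
        lining.setdefault(a.residue_id, a.resname)
    lining_ids = tuple(sorted(lining, key=lambda rid: residue_order[rid]))
    total = len(lining_ids)
    hydro = sum(
        1 for rid in lining_ids
        if AA1.get(lining[rid], "?") in hydrophobic
    )
    fraction = _round_half_up(100.0 * hydro / total) if total else 0
    exit_tunnel = tunnels[1] if len(tunnels) > 1 else tunnels[0]
    return TunnelScore(
        lining_residues=lining_ids,
        hydrophobic_count=hydro,
        total_count=total,
        hydrophobic_fraction=fraction,
        shape_class=classify_shape(exit_tunnel, shape_threshold),
    )


def centerline_pdb(tunnels: list[Tunnel]) -> str:
    """PyMOL-loadable pseudo-atom trace of tunnel centerlines."""
    lines = []
    serial = 0
    for t_index, t in enumerate(tunnels, start=1):
        chain = chr(ord("X") + (t_index - 1) % 3)
        for p in t.centerline:
            serial += 1
            lines.append(
                f"HETATM{serial % 100000:>5}  C   TUN {chain}{t_index % 10000:>4}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"           C"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
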