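"""Family placement of screened candidates among labelled references.

Pairwise global-alignment distances (d = 1 - identity/100) feed a
neighbor-joining tree; each candidate is assigned the family of the
smallest edge-induced bipartition side that contains it together with
references of a single family.  Candidates assigned to the target family
are ranked by mean distance to a designated "versatile" reference subset.
"""

from __future__ import annotations

import io
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .align import AlignParams, global_align
from .errors import InputError
from .records import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "ReferencePanel",
    "DistanceMatrix",
    "PlacementResult",
    "build_distance_matrix",
    "neighbor_joining",
    "assign_family",
    "select_top_candidates",
    "place",
]

FAMILIES = ("crugosa_like", "yarrowia", "brefeldin", "organellar",
            "pancreatic", "bacterial")

_FAMILY_RE = re.compile(r"family=(\S+)")
_VERSATILE_RE = re.compile(r"versatile=(\S+)")


@dataclass(frozen=True)
class ReferencePanel:
    """Family-labelled reference records plus the versatile subset."""

    records: tuple[ProteinRecord, ...]
    families: dict[str, str]        # record id -> family
    versatile: frozenset[str]       # ids of the versatile subset

    def __post_init__(self):
        ids = {r.id for r in self.records}
        unknown = set(self.families) - ids
        if unknown:
            raise InputError(f"family labels for unknown records: {sorted(unknown)}")
        if len(set(self.families.values())) < 2:
            raise InputError("reference panel must contain at least 2 families")
        bad_family = set(self.families.values()) - set(FAMILIES)
        if bad_family:
            raise InputError(f"unknown family labels: {sorted(bad_family)}")
        outside = [v for v in self.versatile
                   if self.families.get(v) != "crugosa_like"]
        if outside:
            raise InputError(
                f"versatile subset must be crugosa_like members: {sorted(outside)}"
            )

    @classmethod
    def from_records(cls, records: list[ProteinRecord]) -> "ReferencePanel":
        """Parse ``family=`` and ``versatile=`` tokens from FASTA headers."""
        families, versatile = {}, set()
        for rec in records:
            fm = _FAMILY_RE.search(rec.description)
            if not fm:
                raise InputError(f"panel record {rec.id} lacks a family= header token")
            families[rec.id] = fm.group(1)
            vm = _VERSATILE_RE.search(rec.description)
            if vm and vm.group(1) not in ("0", "false", "no"):
                versatile.add(rec.id)
        return cls(records=tuple(records), families=families,
                   versatile=frozenset(versatile))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate taxon labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InputError("distance matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise InputError("distance entries must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def build_distance_matrix(records: list[ProteinRecord],
                          params: AlignParams | None = None) -> DistanceMatrix:
    """All-pairs alignment distances d = 1 - identity_fraction."""
    if len(records) < 3:
        raise InputError("need at least 3 records for a distance matrix")
    labels = tuple(r.id for r in records)
    if len(set(labels)) != len(labels):
        raise InputError("duplicate taxon labels")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i].seq, records[j].seq, params)
            d[i, j] = d[j, i] = 1.0 - res.identity_percent / 100.0
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str | None
    length: float = 0.0
    children: list["_Node"] = field(default_factory=list)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # Negative branch lengths are clamped to 0 with the deficit moved to
    # the sister edge so the pair sum is preserved.
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(matrix: DistanceMatrix) -> str:
    """Unrooted NJ tree in Newick format.

    Q-matrix minimisation with Studier-Keppler branch lengths; ties in Q
    are broken lexicographically on the (sorted) label pair.  Triangle
    violations in the input are tolerated.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, _Node] = {lab: _Node(name=lab) for lab in labels}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[(a, b)] = float(matrix.values[i, j])

    def dist(a: str, b: str) -> float:
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best, best_pair = None, None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best, best_pair = key, (a, b)
        a, b = best_pair
        dab = dist(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        counter += 1
        new_name = f"__nj{counter:04d}"
        parent = _Node(name=None)
        nodes[a].length, nodes[b].length = la, lb
        parent.children = [nodes[a], nodes[b]]
        nodes[new_name] = parent
        for c in active:
            if c in (a, b):
                continue
            d[(new_name, c)] = (dist(a, c) + dist(b, c) - dab) / 2.0
        active = sorted(set(active) - {a, b} | {new_name})

    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    root = _Node(name=None)
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(ln, 0.0)
        root.children.append(node)
    return root.newick()


# ---------------------------------------------------------------------------
# Family assignment and candidate selection
# ---------------------------------------------------------------------------

def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(io.StringIO(tree), convert_underscores=False)


def assign_family(tree, panel: ReferencePanel, candidate: str) -> str:
    """Family of the smallest bipartition side containing the candidate and
    at least one reference; "unplaced" when that side mixes families or the
    minimal sides disagree."""
    t = _as_tree(tree)
    all_leaves = frozenset(n.name for n in t.tips())
    if candidate not in all_leaves:
        raise InputError(f"candidate {candidate} is not a leaf of the tree")
    ref_ids = set(panel.families)

    sides: list[frozenset[str]] = []
    for node in t.traverse(include_self=False):
        below = frozenset(n.name for n in node.tips()) if node.children \
            else frozenset({node.name})
        side = below if candidate in below else all_leaves - below
        if side & ref_ids:
            sides.append(side)
    if not sides:
        return "unplaced"
    smallest = min(len(s) for s in sides)
    verdicts = set()
    for side in sides:
        if len(side) != smallest:
            continue
        fams = {panel.families[r] for r in side & ref_ids}
        verdicts.add(fams.pop() if len(fams) == 1 else "unplaced")
    return verdicts.pop() if len(verdicts) == 1 else "unplaced"


@dataclass(frozen=True)
class PlacementResult:
    newick: str
    families: dict[str, str]             # candidate id -> family or "unplaced"
    mean_versatile_distance: dict[str, float]
    selected: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        rank = {cid: i + 1 for i, cid in enumerate(self.selected)}
        for cid in sorted(self.families):
            rows.append({
                "candidate": cid,
                "family": self.families[cid],
                "mean_distance": self.mean_versatile_distance.get(cid, np.nan),
                "rank": rank.get(cid, pd.NA),
            })
        return pd.DataFrame(rows, columns=["candidate", "family", "mean_distance", "rank"])


def select_top_candidates(families: dict[str, str],
                          mean_distance: dict[str, float],
                          k: int,
                          target_family: str = "crugosa_like") -> tuple[str, ...]:
    """The k target-family candidates with smallest mean distance to the
    versatile subset; ascending distance, ties broken lexicographically."""
    if k < 1:
        raise InputError("k must be >= 1")
    placed = [cid for cid, fam in families.items() if fam == target_family]
    ordered = sorted(placed, key=lambda cid: (mean_distance[cid], cid))
    if len(ordered) < k:
        warnings.warn(
            f"only {len(ordered)} candidates placed in {target_family}; "
            f"returning all of them (k={k})",
            stacklevel=2,
        )
        return tuple(ordered)
    return tuple(ordered[:k])


def place(candidates: list[ProteinRecord], panel: ReferencePanel, k: int = 6,
          params: AlignParams | None = None,
          tree: str | None = None) -> PlacementResult:
    """Full placement stage; ``tree`` may supply an externally built Newick."""
    cand_ids = [r.id for r in candidates]
    overlap = set(cand_ids) & set(r.id for r in panel.records)
    if overlap:
        raise InputError(f"candidate ids collide with panel ids: {sorted(overlap)}")
    matrix = build_distance_matrix(list(candidates) + list(panel.records), params)
    newick = tree if tree is not None else neighbor_joining(matrix)
    t = _as_tree(newick)
    families = {cid: assign_family(t, panel, cid) for cid in cand_ids}
    versatile = sorted(panel.versatile)
    mean_d = {
        cid: float(np.mean([matrix.get(cid, v) for v in versatile])) if versatile
        else float("nan")
        for cid in cand_ids
    }
    selected = select_top_candidates(families, mean_d, k)
    return PlacementResult(newick=newick, families=families,
                           mean_versatile_distance=mean_d, selected=selected)
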