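"""Global pairwise alignment and percent identity.

Needleman-Wunsch global alignment under BLOSUM62 with affine gaps.
Gap cost convention: a gap of length ``k`` costs ``open + (k - 1) * extend``
(the opening penalty covers the first gapped position).  Terminal gaps are
penalised like internal ones.  Identity is the fraction of alignment columns
whose two letters are identical, over the full alignment length including
gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError

__all__ = ["AlignParams", "AlignmentResult", "global_align"]

_MATRIX_CACHE: dict[str, object] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for :func:`global_align`."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties are magnitudes and must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def column_map(self) -> dict[int, int | None]:
        """Map 1-based positions of sequence a to 1-based positions of b.

        Positions of ``a`` aligned against a gap map to ``None``.
        """
        mapping: dict[int, int | None] = {}
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            if ca != "-":
                mapping[ia] = ib if cb != "-" else None
        return mapping


def _sanitize(seq: str, alphabet: str) -> str:
    """Letters the substitution matrix does not know are scored as X."""
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def identity_percent(aligned_a: str, aligned_b: str) -> float:
    if len(aligned_a) != len(aligned_b) or not aligned_a:
        raise InputError("aligned strings must be non-empty and equal length")
    same = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return 100.0 * same / len(aligned_a)


def global_align(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal global alignment of two residue strings.

    Raises :class:`InputError` on empty input.  When several alignments are
    co-optimal the first one in Biopython's deterministic enumeration order
    is reported; the score is unique.
    """
    params = params or AlignParams()
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    matrix = _load_matrix(params.matrix)
    alphabet = str(matrix.alphabet)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    sa, sb = _sanitize(a, alphabet), _sanitize(b, alphabet)
    alignment = aligner.align(sa, sb)[0]
    # Restore the original letters (sanitisation only affects scoring).
    aligned_a = _restore(str(alignment[0]), a)
    aligned_b = _restore(str(alignment[1]), b)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity_percent=identity_percent(aligned_a, aligned_b),
    )


def _restore(aligned: str, original: str) -> str:
    out, i = [], 0
    for c in aligned:
        if c == "-":
            out.append("-")
        else:
            out.append(original[i].upper())
            i += 1
    if i != len(original):
        raise AssertionError("alignment does not cover the input sequence")
    return "".join(out)
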