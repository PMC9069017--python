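"""Deterministic pairwise protein alignment and reference-position mapping.

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with affine
gap penalties and a packaged substitution matrix, plus the column-level
bookkeeping needed to carry reference-numbered positions (e.g. *E. coli*
PolA position 762) through a gapped alignment.

Gap convention: ``gap_open`` is the score of the first column of a gap and
``gap_extend`` of each subsequent column, so a gap of length *k* scores
``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices as _submat

from .seqio import ProteinRecord

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "pairwise_align",
    "map_reference_position",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for pairwise alignment.

    Defaults are the classical BLOSUM62 / −11 / −1 pairing. ``mode`` is
    ``"global"`` (end-to-end, terminal gaps scored) or ``"local"``
    (maximal-scoring segment pair).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored pairwise alignment with per-column position bookkeeping.

    ``column_map`` holds, for each alignment column, a pair of 1-based
    sequence positions, with ``None`` marking a gap on that side.
    ``identity`` is identical residue pairs over all alignment columns
    (gap columns included in the denominator); ``coverage_a``/``coverage_b``
    are the aligned span on each sequence divided by its full length.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage_a: float
    coverage_b: float
    column_map: tuple[tuple[int | None, int | None], ...]
    length_a: int
    length_b: int
    mode: str = "global"

    @property
    def n_columns(self) -> int:
        return len(self.column_map)


@lru_cache(maxsize=8)
def _matrix(name: str):
    return _submat.load(name)


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.substitution_matrix = _matrix(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aligner.mode = params.mode
    return aligner


def _gap_score(length: int, params: AlignmentParams) -> float:
    if length == 0:
        return 0.0
    return params.gap_open + (length - 1) * params.gap_extend


def _finalize(
    aligned_a: str,
    aligned_b: str,
    score: float,
    a_offset: int,
    b_offset: int,
    len_a: int,
    len_b: int,
    params: AlignmentParams,
) -> PairwiseAlignment:
    column_map: list[tuple[int | None, int | None]] = []
    a_pos, b_pos = a_offset, b_offset
    n_ident = 0
    both = []  # column indices where neither side is a gap
    for i, (ca, cb) in enumerate(zip(aligned_a, aligned_b)):
        pa = pb = None
        if ca != "-":
            a_pos += 1
            pa = a_pos
        if cb != "-":
            b_pos += 1
            pb = b_pos
        if pa is not None and pb is not None:
            both.append(i)
            if ca == cb:
                n_ident += 1
        column_map.append((pa, pb))
    n_cols = len(column_map)
    identity = n_ident / n_cols if n_cols else 0.0
    if both:
        first, last = both[0], both[-1]
        span_a = column_map[last][0] - column_map[first][0] + 1
        span_b = column_map[last][1] - column_map[first][1] + 1
        cov_a = span_a / len_a
        cov_b = span_b / len_b
    else:
        cov_a = cov_b = 0.0
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        identity=identity,
        coverage_a=cov_a,
        coverage_b=cov_b,
        column_map=tuple(column_map),
        length_a=len_a,
        length_b=len_b,
        mode=params.mode,
    )


def pairwise_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    params: AlignmentParams | None = None,
) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment of two protein sequences.

    Accepts :class:`ProteinRecord` or plain residue strings. The traceback
    is deterministic (the aligner's first optimal path). In local mode an
    empty sequence is an error; in global mode it aligns against all gaps.
    """
    params = params or AlignmentParams()
    seq_a = a.residues if isinstance(a, ProteinRecord) else a
    seq_b = b.residues if isinstance(b, ProteinRecord) else b
    if not seq_a or not seq_b:
        if params.mode == "local":
            raise ValueError("empty sequence in local alignment")
        # Global mode: the nonempty side aligns against all gaps.
        aligned_a = seq_a or "-" * len(seq_b)
        aligned_b = seq_b or "-" * len(seq_a)
        score = _gap_score(max(len(seq_a), len(seq_b)), params)
        if not seq_a and not seq_b:
            raise ValueError("cannot align two empty sequences")
        return _finalize(aligned_a, aligned_b, score, 0, 0,
                         max(len(seq_a), 1), max(len(seq_b), 1), params)
    result = _aligner(params).align(seq_a, seq_b)
    try:
        best = result[0]
    except IndexError:
        # Local mode: no positively scoring segment pair exists.
        return _finalize("", "", 0.0, 0, 0, len(seq_a), len(seq_b), params)
    a_offset = int(best.coordinates[0][0])
    b_offset = int(best.coordinates[1][0])
    return _finalize(
        str(best[0]), str(best[1]), best.score,
        a_offset, b_offset, len(seq_a), len(seq_b), params,
    )


def map_reference_position(aln: PairwiseAlignment, ref_pos: int) -> int | None:
    """Map a 1-based position on sequence *a* to its aligned position on *b*.

    Returns the 1-based *b* position, or ``None`` when the reference
    position sits opposite a gap (or outside a local alignment's segment).
    """
    if not (1 <= ref_pos <= aln.length_a):
        raise ValueError(
            f"reference position {ref_pos} outside sequence of length {aln.length_a}"
        )
    for pa, pb in aln.column_map:
        if pa == ref_pos:
            return pb
    return None
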