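"""Pairwise protein alignment and alignment statistics.

Global (Needleman-Wunsch, terminal gaps penalized) and local
(Smith-Waterman) affine-gap alignment, delegating the dynamic
programming to Biopython's :class:`Bio.Align.PairwiseAligner`.  The gap
model is: a gap of length ``L`` costs ``gap_open + L * gap_extend``.

The default scoring scheme is BLOSUM62 with gap_open 10 and
gap_extend 0.5.  ``X`` matches nothing: its substitution score against a
residue is the minimum of that residue's row, a conservative treatment
of unknown/masked positions that also makes ``X``-masked spans invisible
to local rescanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import AA20, AA21, ProteinRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def matrix(self) -> substitution_matrices.Array:
        return _x_adjusted_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def self_score(self, sequence: str) -> float:
        """Score of a sequence aligned gap-free against itself."""
        m = self.matrix
        return float(sum(m[c, c] for c in sequence))


@lru_cache(maxsize=None)
def _x_adjusted_matrix(name: str) -> substitution_matrices.Array:
    """Restrict a packaged matrix to AA20+X with X scoring row minima."""
    base = substitution_matrices.load(name)
    out = substitution_matrices.Array(alphabet=AA21, dims=2)
    for a in AA20:
        for b in AA20:
            out[a, b] = base[a, b]
    row_min = {a: min(float(base[a, b]) for b in AA20) for a in AA20}
    global_min = min(row_min.values())
    for a in AA20:
        out[a, "X"] = out["X", a] = row_min[a]
    out["X", "X"] = global_min
    return out


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored pairwise alignment.

    ``a_span``/``b_span`` are 1-based inclusive intervals on the ungapped
    inputs covered by the alignment (``None`` for an empty local
    alignment).  Aligned strings have equal length and no column is a gap
    in both rows.
    """

    aligned_a: str
    aligned_b: str
    score: float
    mode: str
    a_span: tuple[int, int] | None
    b_span: tuple[int, int] | None

    def __len__(self) -> int:
        return len(self.aligned_a)

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = scheme.matrix
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each subsequent one; our convention charges
    # gap_open + L * gap_extend for a length-L gap.
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    al.mode = mode
    return al


def _seq(x: ProteinRecord | str) -> str:
    return x.sequence if isinstance(x, ProteinRecord) else x


def _run(a, b, scheme: ScoringScheme, mode: str) -> PairwiseAlignment:
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    result = _aligner(scheme, mode).align(sa, sb)
    if mode == "local" and (len(result) == 0 or result.score <= 0):
        return PairwiseAlignment("", "", 0.0, "local", None, None)
    best = result[0]
    coords = best.coordinates
    a_span = (int(coords[0, 0]) + 1, int(coords[0, -1]))
    b_span = (int(coords[1, 0]) + 1, int(coords[1, -1]))
    return PairwiseAlignment(str(best[0]), str(best[1]), float(best.score), mode, a_span, b_span)


def global_align(a, b, scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Affine-gap global optimum; terminal gaps are penalized."""
    return _run(a, b, scheme, "global")


def local_align(a, b, scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Smith-Waterman optimum; the empty alignment (score 0) is allowed."""
    return _run(a, b, scheme, "local")


def percent_identity(al: PairwiseAlignment, denominator: str = "aligned_columns") -> float:
    """100 x identical columns / denominator; gaps never count as identical."""
    if len(al) == 0:
        raise ValueError("percent_identity of an empty alignment")
    ident = sum(1 for x, y in al.columns() if x == y and x != "-")
    if denominator == "aligned_columns":
        denom = len(al)
    elif denominator == "shorter_seq":
        denom = min(
            len(al.aligned_a.replace("-", "")),
            len(al.aligned_b.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * ident / denom


def percent_similarity(
    al: PairwiseAlignment,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    denominator: str = "aligned_columns",
) -> float:
    """Like percent_identity but counting positive-scoring columns too."""
    if len(al) == 0:
        raise ValueError("percent_similarity of an empty alignment")
    m = scheme.matrix
    sim = sum(
        1
        for x, y in al.columns()
        if x != "-" and y != "-" and (x == y or float(m[x, y]) > 0)
    )
    if denominator == "aligned_columns":
        denom = len(al)
    elif denominator == "shorter_seq":
        denom = min(
            len(al.aligned_a.replace("-", "")),
            len(al.aligned_b.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * sim / denom


def p_distance(al: PairwiseAlignment) -> float:
    """Mismatched fraction of gap-free columns of a global alignment."""
    comparable = [(x, y) for x, y in al.columns() if x != "-" and y != "-"]
    if not comparable:
        raise ValueError("p_distance: alignment has no gap-free columns")
    mismatches = sum(1 for x, y in comparable if x != y)
    return mismatches / len(comparable)
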