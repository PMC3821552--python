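"""Banded single-gap alignment kernel.

The aligner answers the following question: given a text ``t`` of length
``n`` and a pattern ``x`` of length ``m``, what is the best semi-global
alignment of ``x`` against a prefix of ``t`` that inserts *at most one
gap* (in either sequence) of length at most ``beta``?  Only the diagonal
stripe of dynamic-programming cells with ``|i - j| <= beta`` is ever
computed, so the work is O(m * beta) rather than O(n * m).

Two value semantics share the same band structure:

* *count* mode minimises the number of mismatches (gaps are free, their
  length is only bounded), which solves approximate matching with
  k mismatches and a single gap of length between ``alpha`` and ``beta``;
* *score* mode maximises a substitution-matrix score minus an affine gap
  penalty ``open + (L - 1) * extend``, the scheme used by EMBOSS.

A companion band ``H`` records, for every cell where the gap branch of
the recurrence was strictly better than the diagonal branch, the length
of that gap; tracing back through ``H`` recovers the gap position in
O(m) steps.  The unaligned suffix of the text is never penalised (free
end gap), which is what makes the alignment semi-global.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _kernels
from .scoring import DNA, GapPenalty, SubstitutionMatrix, load_matrix

__all__ = [
    "AlignParams",
    "BandedDP",
    "AlignmentResult",
    "fill_count",
    "fill_score",
    "best_cell",
    "traceback",
    "count_solutions",
]

GapSide = Literal["none", "in_text", "in_pattern"]


@dataclass(frozen=True)
class AlignParams:
    """Parameters shared by all single-gap alignment calls.

    beta    maximum gap length == half-width of the DP band (default:
            text length - 1, the widest band the problem admits);
    alpha   minimum admissible gap length (0 disables the lower bound);
    k       mismatch budget for count mode (None: unbounded);
    mode    "score" (substitution matrix + affine penalty) or "count";
    matrix  substitution matrix for score mode (default EDNAFULL);
    gap     affine gap penalty for score mode.
    """

    beta: int | None = None
    alpha: int = 0
    k: int | None = None
    mode: Literal["score", "count"] = "score"
    matrix: SubstitutionMatrix | None = None
    gap: GapPenalty = field(default_factory=GapPenalty)

    def resolve(self, n: int) -> "AlignParams":
        """Fill in defaults that depend on the text length ``n``."""
        beta = self.beta if self.beta is not None else n - 1
        matrix = self.matrix
        if self.mode == "score" and matrix is None:
            matrix = load_matrix("EDNAFULL")
        if not 0 <= self.alpha <= beta:
            raise ValueError(f"need 0 <= alpha <= beta, got alpha={self.alpha}, beta={beta}")
        if beta >= n:
            raise ValueError(f"beta must be smaller than the text length ({beta} >= {n})")
        return replace(self, beta=beta, matrix=matrix)


@dataclass
class BandedDP:
    """The filled pruned matrices G (values) and H (gap bookkeeping)."""

    t: str
    x: str
    beta: int
    mode: str
    G: np.ndarray  # (imax + 1, 2*beta + 1); int64 counts or float64 scores
    H: np.ndarray  # same shape, int64 gap lengths (0: diagonal branch optimal)
    cells_computed: int

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def m(self) -> int:
        return len(self.x)

    @property
    def imax(self) -> int:
        return min(self.n, self.m + self.beta)

    def _offset(self, i: int, j: int) -> int:
        if abs(i - j) > self.beta:
            raise IndexError(f"cell ({i}, {j}) is outside the band |i-j| <= {self.beta}")
        if not (0 <= i <= self.imax and 0 <= j <= self.m):
            raise IndexError(f"cell ({i}, {j}) is outside the computed stripe")
        return j - i + self.beta

    def value(self, i: int, j: int) -> float | int:
        """Band cell G[i, j]; raises IndexError outside the band."""
        v = self.G[i, self._offset(i, j)]
        return float(v) if self.mode == "score" else int(v)

    def gap_at(self, i: int, j: int) -> int:
        return int(self.H[i, self._offset(i, j)])

    def dump(self) -> str:
        """Debug text dump: one line per stored cell (i, j, G, H)."""
        out = []
        for i in range(self.imax + 1):
            for j in range(max(0, i - self.beta), min(self.m, i + self.beta) + 1):
                d = j - i + self.beta
                out.append(f"{i}\t{j}\t{self.G[i, d]}\t{self.H[i, d]}")
        return "\n".join(out)


@dataclass
class AlignmentResult:
    """Outcome of a single-gap alignment.

    ``end_text`` is the 1-based ending position i* of the alignment in
    the text; the band offset of the chosen ending cell fixes the gap
    length as ``|end_text - m|``.  ``gap_pos`` is the 1-based alignment
    column of the first gap symbol (0 when gapless, None when traceback
    was skipped).
    """

    score: float | None
    mismatches: int | None
    end_text: int
    gap_length: int
    gap_side: GapSide
    gap_pos: int | None
    valid_for_problem1: bool = True

    @property
    def has_gap(self) -> bool:
        return self.gap_length > 0


def _encode(t: str, x: str, matrix: SubstitutionMatrix | None):
    alphabet = matrix.alphabet if matrix is not None else DNA
    return alphabet.encode(t), alphabet.encode(x)


def _check_fill(t: str, x: str, beta: int) -> None:
    if not t or not x:
        raise ValueError("sequences must be non-empty")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta >= len(t):
        raise ValueError(f"beta must be smaller than the text length ({beta} >= {len(t)})")
    if len(x) > len(t) + beta:
        raise ValueError(
            f"pattern of length {len(x)} cannot align within text of length "
            f"{len(t)} with a single gap of at most {beta}"
        )


def fill_count(t: str, x: str, beta: int) -> BandedDP:
    """Fill the count-mode band: minimum mismatches with at most one gap."""
    _check_fill(t, x, beta)
    # count mode only compares letters for equality: any alphabet works
    tc = np.frombuffer(t.upper().encode("ascii"), dtype=np.uint8)
    xc = np.frombuffer(x.upper().encode("ascii"), dtype=np.uint8)
    G, H, ncells = _kernels.fill_count_band(tc, xc, beta)
    return BandedDP(t=t.upper(), x=x.upper(), beta=beta, mode="count", G=G, H=H,
                    cells_computed=ncells)


def fill_score(
    t: str,
    x: str,
    matrix: SubstitutionMatrix,
    gp: GapPenalty,
    beta: int,
) -> BandedDP:
    """Fill the score-mode band: maximum matrix score minus affine gap penalty."""
    _check_fill(t, x, beta)
    tc, xc = _encode(t.upper(), x.upper(), matrix)
    S, H, ncells = _kernels.fill_score_band(tc, xc, matrix.scores, gp.open, gp.extend, beta)
    return BandedDP(t=t.upper(), x=x.upper(), beta=beta, mode="score", G=S, H=H,
                    cells_computed=ncells)


def _admissible(L: int, alpha: int, beta: int, strict_alpha_zero: bool) -> bool:
    if L == 0:
        return alpha == 0 if strict_alpha_zero else True
    return alpha <= L <= beta


def best_cell(dp: BandedDP, params: AlignParams) -> AlignmentResult | None:
    """Scan the <= 2*beta + 1 candidate ending cells (i, m) and pick the optimum.

    Candidates are the cells in the last band column, i.e. ending
    positions i with |i - m| <= beta; the gap length of candidate i is
    |i - m|, and only lengths in {0} union [alpha, beta] are admissible.
    Ties are broken toward no gap, then the shorter gap, then the
    larger ending position (the alignment explaining the longest text
    prefix, which is the natural choice when extending a seed).
    Returns None when no cell is admissible (a "no alignment" outcome,
    not an error).
    """
    m, beta = dp.m, dp.beta
    minimise = dp.mode == "count"
    best: tuple | None = None
    best_i = -1
    for i in range(max(0, m - beta), min(dp.imax, m + beta) + 1):
        L = abs(i - m)
        if not _admissible(L, params.alpha, beta, strict_alpha_zero=False):
            continue
        v = dp.G[i, m - i + beta]
        if minimise and v >= _kernels.COUNT_INF:
            continue
        if not minimise and v <= _kernels.SCORE_NEG / 2:
            continue
        key = (v if minimise else -v, 0 if L == 0 else 1, L, -i)
        if best is None or key < best:
            best = key
            best_i = i
    if best is None:
        return None
    i = best_i
    L = abs(i - m)
    value = dp.G[i, m - i + beta]
    side: GapSide = "none" if L == 0 else ("in_pattern" if i > m else "in_text")
    res = AlignmentResult(
        score=float(value) if dp.mode == "score" else None,
        mismatches=int(value) if dp.mode == "count" else None,
        end_text=i,
        gap_length=L,
        gap_side=side,
        gap_pos=0 if L == 0 else None,
        valid_for_problem1=_problem1_valid(dp, params, i, L),
    )
    return res


def _problem1_valid(dp: BandedDP, params: AlignParams, i: int, L: int) -> bool:
    if dp.mode != "count" or params.k is None:
        return True
    if dp.G[i, dp.m - i + dp.beta] > params.k:
        return False
    return _admissible(L, params.alpha, dp.beta, strict_alpha_zero=True)


def traceback(dp: BandedDP, cell: tuple[int, int]) -> AlignmentResult:
    """Recover gap placement and mismatch tally from ending ``cell`` in O(m).

    Walks anti-diagonally toward the origin; at the first cell whose H
    entry is non-zero the gap is placed (its length is the H value, its
    side follows from the index order) and the larger index jumps across
    it; the walk then continues on the main diagonal.
    """
    i, j = cell
    beta = dp.beta
    value = dp.value(i, j)
    end_i = i
    gap_length = 0
    gap_side: GapSide = "none"
    gap_pos = 0
    mismatches = 0
    while i > 0 or j > 0:
        if i == 0 or j == 0:
            # leading gap recorded in the band border cells
            L = int(dp.H[i, j - i + beta]) if (i + j) > 0 else 0
            if L:
                if L != max(i, j) or min(i, j) != 0:
                    raise RuntimeError(f"inconsistent H at border cell ({i}, {j})")
                gap_length, gap_pos = L, 1
                gap_side = "in_pattern" if i > j else "in_text"
            break
        h = int(dp.H[i, j - i + beta])
        if h:
            if i == j:
                raise RuntimeError(f"inconsistent H: gap of {h} at diagonal cell ({i}, {j})")
            gap_length = h
            if i > j:
                gap_side, gap_pos = "in_pattern", j + 1
                i -= h
            else:
                gap_side, gap_pos = "in_text", i + 1
                j -= h
        else:
            if dp.t[i - 1] != dp.x[j - 1]:
                mismatches += 1
            i -= 1
            j -= 1
    if gap_length != abs(end_i - dp.m) and cell[1] == dp.m:
        raise RuntimeError("traceback gap length disagrees with the band offset")
    return AlignmentResult(
        score=float(value) if dp.mode == "score" else None,
        mismatches=mismatches if dp.mode == "score" else int(value),
        end_text=end_i,
        gap_length=gap_length,
        gap_side=gap_side,
        gap_pos=gap_pos,
    )


def count_solutions(t: str, x: str, k: int, alpha: int, beta: int) -> list[AlignmentResult]:
    """All ending positions solving the k-mismatch single-gap problem.

    Returns every prefix end i of ``t`` with |i - m| <= beta whose band
    value G[i, m] is at most ``k`` and whose implied gap length L is
    admissible: either alpha <= L <= beta, or L = 0 which (being a pure
    Hamming match) requires alpha = 0.
    """
    n, m = len(t), len(x)
    if not 0 <= k < m:
        raise ValueError(f"need 0 <= k < m, got k={k}, m={m}")
    if not 0 <= alpha <= beta:
        raise ValueError(f"need 0 <= alpha <= beta, got {alpha}, {beta}")
    if beta >= n:
        raise ValueError(f"beta must be smaller than the text length ({beta} >= {n})")
    dp = fill_count(t, x, beta)
    out = []
    for i in range(max(0, m - beta), min(dp.imax, m + beta) + 1):
        L = abs(i - m)
        if not _admissible(L, alpha, beta, strict_alpha_zero=True):
            continue
        if dp.G[i, m - i + beta] <= k:
            out.append(traceback(dp, (i, m)))
    return out
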