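"""Independent baselines: a brute-force single-gap oracle and a Gotoh aligner.

``brute_force_single_gap`` enumerates every admissible gap placement
directly from the definitions and is used as a test oracle for the
banded kernel; it refuses large instances on purpose.

``semi_global_gotoh`` is a full (unbanded) affine-gap Needleman-Wunsch/
Gotoh aligner with free end gaps, the configuration EMBOSS ``needle``
uses by default (endweight false).  It plays the role of the
conventional semi-global aligner in the validity/correctness
experiments: unlike the single-gap kernel it may open any number of
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernels
from .core import AlignmentResult, AlignParams
from .scoring import GapPenalty, SubstitutionMatrix, gap_penalty

__all__ = [
    "GenericAlignment",
    "brute_force_single_gap",
    "semi_global_gotoh",
    "count_internal_gaps",
]

_ORACLE_CAP = 64


@dataclass
class GenericAlignment:
    """A gap-annotated pairwise alignment ('-' marks gap columns)."""

    aligned_text: str
    aligned_pattern: str
    score: float
    free_end_gaps: bool = True

    def __post_init__(self) -> None:
        if len(self.aligned_text) != len(self.aligned_pattern):
            raise ValueError("aligned strings must have equal length")

    @property
    def mismatches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_text, self.aligned_pattern)
            if a != "-" and b != "-" and a != b
        )

    @property
    def gap_runs(self) -> list[tuple[str, int, int]]:
        """Maximal gap runs as (side, 1-based start column, length)."""
        runs = []
        for side, s in (("text", self.aligned_text), ("pattern", self.aligned_pattern)):
            start = None
            for col, ch in enumerate(s):
                if ch == "-" and start is None:
                    start = col
                elif ch != "-" and start is not None:
                    runs.append((side, start + 1, col - start))
                    start = None
            if start is not None:
                runs.append((side, start + 1, len(s) - start))
        runs.sort(key=lambda r: r[1])
        return runs

    def recompute_score(self, matrix: SubstitutionMatrix, gp: GapPenalty) -> float:
        """Score the aligned strings from scratch (consistency check)."""
        total = 0.0
        ncols = len(self.aligned_text)
        for side, start, length in self.gap_runs:
            touches_end = start + length - 1 == ncols
            touches_start = start == 1
            if self.free_end_gaps and (touches_end or touches_start):
                continue
            total -= gap_penalty(gp, length)
        for a, b in zip(self.aligned_text, self.aligned_pattern):
            if a != "-" and b != "-":
                total += matrix.score(a, b)
        return total


def count_internal_gaps(
    a: GenericAlignment, exclude_leading: bool = False
) -> tuple[int, int]:
    """Count gap runs and their total length, excluding trailing end gaps.

    A run touching the right end of the alignment is a free end gap and
    is not counted; a leading run counts unless ``exclude_leading``.
    """
    ncols = len(a.aligned_text)
    count = total = 0
    for _side, start, length in a.gap_runs:
        if start + length - 1 == ncols:
            continue
        if exclude_leading and start == 1:
            continue
        count += 1
        total += length
    return count, total


def _span_count(t: str, x: str, t0: int, x0: int, length: int) -> int:
    return sum(1 for p in range(length) if t[t0 + p] != x[x0 + p])


def _span_score(t: str, x: str, t0: int, x0: int, length: int, matrix) -> float:
    idx = matrix.alphabet.index()
    s = matrix.scores
    return float(
        sum(s[idx[t[t0 + p]], idx[x[x0 + p]]] for p in range(length))
    )


def brute_force_single_gap(
    t: str, x: str, params: AlignParams | None = None
) -> AlignmentResult | None:
    """Enumerate every single-gap placement and return the optimum.

    For each candidate ending position i the gap length is forced to
    L = |i - m| (the sequences' length difference inside the aligned
    region); the gap may start after any of the possible split points,
    and the value is computed directly from the definition of
    correspondence.  Tie-breaking matches the banded aligner: better
    value, then no gap, then shorter gap, then larger ending position,
    then the earliest gap start.  Only small instances are accepted —
    this is a test oracle, not an aligner.
    """
    params = (params or AlignParams()).resolve(len(t))
    if len(t) > _ORACLE_CAP or len(x) > _ORACLE_CAP:
        raise ValueError(f"oracle instances are capped at {_ORACLE_CAP} letters")
    t, x = t.upper(), x.upper()
    n, m, beta, alpha = len(t), len(x), params.beta, params.alpha
    count_mode = params.mode == "count"
    matrix, gp = params.matrix, params.gap

    best_key: tuple | None = None
    best: AlignmentResult | None = None
    for i in range(max(0, m - beta), min(n, m + beta) + 1):
        L = abs(i - m)
        if L != 0 and not alpha <= L <= beta:
            continue
        if L == 0:
            value = (
                _span_count(t, x, 0, 0, m)
                if count_mode
                else _span_score(t, x, 0, 0, m, matrix)
            )
            cands = [(value, 0)]
        else:
            cands = []
            if i > m:  # gap in the pattern covers t[g0+1 .. g0+L]
                for g0 in range(0, m + 1):
                    head = (
                        _span_count(t, x, 0, 0, g0)
                        if count_mode
                        else _span_score(t, x, 0, 0, g0, matrix)
                    )
                    tail = (
                        _span_count(t, x, g0 + L, g0, m - g0)
                        if count_mode
                        else _span_score(t, x, g0 + L, g0, m - g0, matrix)
                    )
                    value = head + tail
                    if not count_mode:
                        value -= gap_penalty(gp, L)
                    cands.append((value, g0))
            else:  # i < m: gap in the text covers x[g0+1 .. g0+L]
                for g0 in range(0, i + 1):
                    head = (
                        _span_count(t, x, 0, 0, g0)
                        if count_mode
                        else _span_score(t, x, 0, 0, g0, matrix)
                    )
                    tail = (
                        _span_count(t, x, g0, g0 + L, i - g0)
                        if count_mode
                        else _span_score(t, x, g0, g0 + L, i - g0, matrix)
                    )
                    value = head + tail
                    if not count_mode:
                        value -= gap_penalty(gp, L)
                    cands.append((value, g0))
        for value, g0 in cands:
            key = (
                value if count_mode else -value,
                0 if L == 0 else 1,
                L,
                -i,
                g0,
            )
            if best_key is None or key < best_key:
                best_key = key
                side = "none" if L == 0 else ("in_pattern" if i > m else "in_text")
                if count_mode:
                    mism = int(value)
                    score = None
                else:
                    score = float(value)
                    g_t0 = g0 + L if (i > m) else g0
                    g_x0 = g0 if (i > m) else g0 + L
                    span = (m - g0) if i > m else (i - g0)
                    mism = _span_count(t, x, 0, 0, g0) + _span_count(t, x, g_t0, g_x0, span) \
                        if L else _span_count(t, x, 0, 0, m)
                best = AlignmentResult(
                    score=score,
                    mismatches=mism,
                    end_text=i,
                    gap_length=L,
                    gap_side=side,
                    gap_pos=0 if L == 0 else g0 + 1,
                )
    return best


def semi_global_gotoh(
    t: str,
    x: str,
    matrix: SubstitutionMatrix,
    gp: GapPenalty,
    free_end_gaps: bool = True,
) -> GenericAlignment:
    """Full affine-gap alignment (any number of gaps), free end gaps.

    Traceback tie-breaking is fixed: substitution beats a gap in the
    pattern, which beats a gap in the text, so repeated runs give
    byte-identical alignments.
    """
    if not t or not x:
        raise ValueError("sequences must be non-empty")
    if not free_end_gaps:
        raise NotImplementedError("only the free-end-gap (semi-global) variant is provided")
    t, x = t.upper(), x.upper()
    tc = matrix.alphabet.encode(t)
    xc = matrix.alphabet.encode(x)
    M, Ix, Iy = _kernels.gotoh_fill(tc, xc, matrix.scores, gp.open, gp.extend)
    n, m = len(t), len(x)

    def cell_best(i: int, j: int) -> float:
        return max(M[i, j], Ix[i, j], Iy[i, j])

    # free trailing gap: the optimum may end anywhere on the last row/column
    end = (n, m)
    best = cell_best(n, m)
    for i in range(n - 1, -1, -1):
        v = cell_best(i, m)
        if v > best:
            best, end = v, (i, m)
    for j in range(m - 1, -1, -1):
        v = cell_best(n, j)
        if v > best:
            best, end = v, (n, j)

    at, ax = [], []
    i, j = end
    # pad the unaligned suffixes as trailing end gaps
    if i < n:
        at.append(t[i:])
        ax.append("-" * (n - i))
    if j < m:
        at.append("-" * (m - j))
        ax.append(x[j:])

    if M[i, j] >= Ix[i, j] and M[i, j] >= Iy[i, j]:
        state = "M"
    elif Ix[i, j] >= Iy[i, j]:
        state = "X"
    else:
        state = "Y"
    while i > 0 and j > 0:
        if state == "M":
            at.append(t[i - 1])
            ax.append(x[j - 1])
            prev = M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = "MXY"[max(range(3), key=lambda s: (prev[s], -s))]
        elif state == "X":
            at.append(t[i - 1])
            ax.append("-")
            val = Ix[i, j]
            if val == M[i - 1, j] - gp.open:
                state = "M"
            elif val == Ix[i - 1, j] - gp.extend:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            at.append("-")
            ax.append(x[j - 1])
            val = Iy[i, j]
            if val == M[i, j - 1] - gp.open:
                state = "M"
            elif val == Iy[i, j - 1] - gp.extend:
                state = "Y"
            else:
                state = "X"
            j -= 1
    if i > 0:
        at.append(t[:i])
        ax.append("-" * i)
    if j > 0:
        at.append("-" * j)
        ax.append(x[:j])
    aligned_t = "".join(reversed(at))
    aligned_x = "".join(reversed(ax))
    return GenericAlignment(
        aligned_text=aligned_t, aligned_pattern=aligned_x, score=float(best)
    )
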