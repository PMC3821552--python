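"""User-facing alignment drivers.

``one_to_one`` / ``one_to_many`` / ``many_to_many`` mirror the classic
library surface for extending seed alignments: a query (pattern) is
aligned semi-globally against one or many targets (texts) with at most
one gap.  ``align_fragments`` lifts the single-gap restriction by
splitting the query into ``f`` contiguous fragments, aligning each
independently against the remaining text, which bounds the total number
of gaps by ``f``; ``align_optimal_fragments`` additionally searches for
the fragment count with the highest summed score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core import AlignmentResult, AlignParams, best_cell, fill_count, fill_score, traceback

__all__ = [
    "one_to_one",
    "one_to_many",
    "many_to_many",
    "align_fragments",
    "align_optimal_fragments",
    "FragmentedAlignment",
]


def one_to_one(
    t: str,
    x: str,
    params: AlignParams | None = None,
    with_traceback: bool = True,
) -> AlignmentResult | None:
    """Optimal single-gap semi-global alignment of pattern ``x`` against text ``t``.

    Fills the band in O(m * beta), scans the candidate ending cells in
    O(beta), and (unless ``with_traceback`` is off) localises the gap by
    tracing the H band in O(m).  Returns None when no admissible ending
    cell exists.
    """
    params = (params or AlignParams()).resolve(len(t))
    if params.mode == "count":
        dp = fill_count(t, x, params.beta)
    else:
        dp = fill_score(t, x, params.matrix, params.gap, params.beta)
    res = best_cell(dp, params)
    if res is None or not with_traceback:
        return res
    full = traceback(dp, (res.end_text, dp.m))
    full.valid_for_problem1 = res.valid_for_problem1
    if dp.mode == "count":
        full.score = None
    return full


def one_to_many(
    x: str,
    targets: list[str],
    params: AlignParams | None = None,
    with_traceback: bool = True,
) -> list[AlignmentResult | None]:
    """Align one query against each of ``targets`` in order."""
    out = []
    for idx, t in enumerate(targets):
        try:
            out.append(one_to_one(t, x, params, with_traceback))
        except Exception as exc:
            raise type(exc)(f"target {idx}: {exc}") from exc
    return out


def many_to_many(
    queries: list[str],
    targets: list[str],
    params: AlignParams | None = None,
    with_traceback: bool = True,
) -> list[list[AlignmentResult | None]]:
    """Row-major table of alignments: one row per query, one column per target."""
    return [one_to_many(x, targets, params, with_traceback) for x in queries]


@dataclass
class FragmentedAlignment:
    """Alignment of a query split into ``f`` fragments, each with at most one gap."""

    f: int
    fragments: list[AlignmentResult]
    total_score: float
    found: bool = True

    @property
    def n_gaps(self) -> int:
        return sum(1 for r in self.fragments if r.gap_length > 0)

    @property
    def total_gap_length(self) -> int:
        return sum(r.gap_length for r in self.fragments)

    @property
    def mismatches(self) -> int:
        return sum(r.mismatches or 0 for r in self.fragments)


def _no_alignment(f: int) -> FragmentedAlignment:
    return FragmentedAlignment(f=f, fragments=[], total_score=-math.inf, found=False)


def align_fragments(
    t: str,
    x: str,
    f: int,
    params: AlignParams | None = None,
    with_traceback: bool = True,
) -> FragmentedAlignment:
    """Split ``x`` into ``f`` contiguous fragments and align them left to right.

    Fragment lengths are ceil(m / f) with the remainder in the last
    fragment.  Fragment r+1 is aligned against the suffix of ``t``
    starting right after fragment r's ending position, so fragments tile
    the text like successive extension steps; per-fragment beta is the
    global beta capped at the remaining text length - 1.  The total
    score is the exact sum of the fragment scores.  If the text runs out
    before every fragment is placed, the result is flagged as not found.
    """
    params = params or AlignParams()
    if params.mode != "score":
        raise ValueError("fragment alignment is defined for score mode only")
    m = len(x)
    if not 1 <= f <= m:
        raise ValueError(f"need 1 <= f <= {m}, got f={f}")
    size = math.ceil(m / f)
    pieces = [x[r * size : (r + 1) * size] for r in range(f)]
    pieces = [p for p in pieces if p]

    offset = 0  # 0-based start of the remaining text
    frags: list[AlignmentResult] = []
    total = 0.0
    pat_off = 0
    for piece in pieces:
        sub_t = t[offset:]
        if not sub_t:
            return _no_alignment(f)
        beta = len(sub_t) - 1 if params.beta is None else min(params.beta, len(sub_t) - 1)
        if len(piece) > len(sub_t) + beta:
            return _no_alignment(f)
        sub_params = replace(params, beta=beta)
        res = one_to_one(sub_t, piece, sub_params, with_traceback)
        if res is None:
            return _no_alignment(f)
        total += res.score
        # map fragment-local coordinates into the full-sequence frame
        res.end_text += offset
        if with_traceback and res.gap_pos:
            res.gap_pos += pat_off
        frags.append(res)
        offset = res.end_text
        pat_off += len(piece) + (res.gap_length if res.gap_side == "in_pattern" else 0)
    return FragmentedAlignment(f=len(pieces), fragments=frags, total_score=total)


def align_optimal_fragments(
    t: str,
    x: str,
    f_max: int,
    params: AlignParams | None = None,
) -> FragmentedAlignment:
    """Try every fragment count f = 1..f_max and keep the best total score.

    The scoring passes skip traceback; the winning f (ties go to the
    smaller f) is then re-run with traceback.
    """
    if not 1 <= f_max <= len(x):
        raise ValueError(f"need 1 <= f_max <= {len(x)}, got {f_max}")
    best_f, best_score = None, -math.inf
    for f in range(1, f_max + 1):
        cand = align_fragments(t, x, f, params, with_traceback=False)
        if cand.found and cand.total_score > best_score:
            best_f, best_score = f, cand.total_score
    if best_f is None:
        return _no_alignment(f_max)
    return align_fragments(t, x, best_f, params, with_traceback=True)
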