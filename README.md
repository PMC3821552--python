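# onegap

Banded single-gap semi-global alignment for extending short-read
alignments, with a simulation and evaluation harness.

## The problem

Short-read mappers follow *seed-and-extend*: the high-quality prefix of
a read (the seed) is located cheaply in the reference, and the
remaining suffix must then be aligned against the reference bases that
follow — tolerating a few mismatches and, because indels are rare but
real, ideally exactly one bounded gap. A general aligner
(Needleman–Wunsch/Gotoh) cannot bound the number of gaps it opens, so
it both wastes work and over-segments the alignment. `onegap`
implements the alternative: a dynamic-programming aligner that, given a
text `t` (length `n`), a pattern `x` (length `m`) and a gap bound `β`,
finds the best semi-global alignment of `x` against a prefix of `t`
containing **at most one gap** of length ≤ β, in O(mβ) time.

## The method

Let `G[i, j]` be the best value for aligning `x[1..j]` against
`t[1..i]` with at most one gap. Because one gap of length ≤ β can shift
the diagonal by at most β, only the stripe `|i − j| ≤ β` (width 2β + 1)
is computed. The recurrence continues the diagonal
(`G[i−1, j−1] + cost(t[i], x[j])`) or jumps from the main-diagonal cell
(`G[j, j]` when `i > j`: a gap in the pattern; `G[i, i]` when `i < j`:
a gap in the text), charging the whole affine penalty
`open + (L − 1)·extend` in one step. Two value semantics share the
kernel: *count* mode (minimise mismatches; gaps free but bounded, the
k-mismatches-one-gap matching problem) and *score* mode (maximise an
EDNAFULL/EBLOSUM62 substitution score minus the affine penalty, the
EMBOSS scheme). The optimum is found by scanning the ≤ 2β + 1 cells
`(i, m)` in Θ(β); a companion band `H` records where the gap branch won
so traceback recovers the gap position in O(m). The unaligned text
suffix is a free end gap (semi-global).

A bounded number of gaps is supported by splitting the query into `f`
fragments, each aligned independently with one gap
(`align_fragments`); `align_optimal_fragments` picks the `f ≤ f_max`
with the best summed score.

## Worked example

The classic illustration: align `x = GGGTA` against `t = AGGTCAT`
allowing k = 1 mismatch and one gap of length exactly 1 (α = β = 1), in
count mode:

```sh
$ onegap align --query q.fa --target t.fa -k 1 -a 1 -m 1
########################################
# 1: target
# 2: query
# Mismatches: 1
########################################

target     AGGTCAT
           .||| |
query      GGGT-A-
```

The pattern matches the text prefix ending at position 6 with one
mismatch (A/G at position 1) and a single gap of length 1 at alignment
position 5: `GGGTA` becomes `GGGT-A` against `AGGTCA`, and the final
`T` of the text is the free end gap. In the library:

```python
>>> from onegap import AlignParams, one_to_one
>>> r = one_to_one("AGGTCAT", "GGGTA", AlignParams(beta=1, alpha=1, k=1, mode="count"))
>>> r.end_text, r.mismatches, r.gap_side, r.gap_length, r.gap_pos
(6, 1, 'in_pattern', 1, 5)
```

The evaluation harness regenerates the validity/correctness comparison
against a conventional affine-gap semi-global aligner on simulated
pairs (100 bp, one gap of uniform length 1–30, 1–10 substitutions):

```sh
$ onegap evaluate-pairs --n 2000 --seed 1
Programme        Valid   Correct  Accuracy
single_gap        2000      2000    1.0000
gotoh             1877      1834    0.9170
```

`single_gap` is *valid* (no more gaps than were inserted) by
construction on every pair — it can emit at most one gap — while the
unrestricted aligner splits the inserted gap in ~6% of pairs at the
default penalties (gap open 10.0, extend 0.5).

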