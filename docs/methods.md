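# Methods

## Model

`onegap` solves single-gap semi-global alignment: given text `t`
(length `n`), pattern `x` (length `m`), and bounds `0 ≤ α ≤ β < n`,
find the prefixes `t[1..i]` that align against `x` with at most one
gap `g` (in either sequence) with `α ≤ |g| ≤ β`, either minimising
mismatches (count mode, with an optional budget `k`) or maximising a
substitution-matrix score minus an affine gap penalty (score mode).
The gap is a run of don't-care positions: a deletion in one sequence
is equivalently an insertion in the other. The text suffix after the
chosen ending position is never penalised (free end gap), which is the
semi-global convention appropriate for extending a seed: the caller
does not know in advance how much reference the extension will
consume.

Because a single gap of length ≤ β shifts the alignment diagonal by at
most β, every reachable DP cell satisfies `|i − j| ≤ β`. The kernel
stores exactly this stripe (row `i`, offset `j − i + β`, width
`2β + 1`) and computes

* diagonal: `G[i−1, j−1] + cost(t[i], x[j])`,
* gap in pattern (`i > j`): jump from the main-diagonal cell `G[j, j]`,
  charging `open + (i−j−1)·extend` in score mode and nothing in count
  mode (the gap is only length-bounded there),
* gap in text (`i < j`): symmetric, from `G[i, i]`.

Since every jump starts on the main diagonal, which is itself pure
diagonal from the origin, any path contains at most one jump — the
single-gap constraint is structural, not checked. Border cells
`(i, 0)` / `(0, j)` inside the stripe represent a leading gap (free in
count mode, affine-charged in score mode), so a gap at the leftmost
alignment position is representable. A companion band `H` stores the
jump length wherever the jump branch was *strictly* better than the
diagonal branch (ties keep `H = 0`).

The optimum is the best cell among the ≤ 2β + 1 candidates `(i, m)`;
the candidate's gap length is forced to `|i − m|` by the length
bookkeeping. Admissible gap lengths are `{0} ∪ [α, β]` (the strict
problem formulation additionally requires `α = 0` for the gapless
branch; `count_solutions` applies that rule, the optimisation surface
`best_cell` does not). Traceback walks the anti-diagonal from the
chosen cell, places the gap at the first cell with `H ≠ 0`, jumps
across it, and continues — O(m) steps.

### Tie-breaking

Order of preference at equal value: no gap, then the shorter gap, then
the **larger ending position** (the alignment that explains the
longest text prefix — the natural choice when the caller is consuming
reference bases during extension), and within a cell the earliest gap
start (a consequence of keeping `H = 0` on ties, verified against the
enumeration oracle). Both the kernel and the brute-force oracle
implement the identical rule, so optimal *placements*, not just
values, are compared in tests.

### Work bounds

The filled stripe has at most `(2β + 1)(min(n, m) + β + 1)` cells; the
fill reports its cell count and tests assert the bound. The optimum
scan is Θ(β) and traceback O(m).

## Score scheme

Score mode uses EDNAFULL (DNA) or EBLOSUM62 (protein), bundled in
EMBOSS matrix-file format, and the affine penalty
`open + (L − 1)·extend`, defaults 10.0 / 0.5 (the EMBOSS defaults).
Ambiguity codes score whatever the matrix says — no wildcard logic —
and sequences are folded to upper case on ingest. Scores are floats
throughout so both value semantics share one kernel signature; with
integer matrices and half-integer extends all comparisons are exact in
float64. Letters absent from the matrix alphabet raise, naming the
letter.

## Fragments

`align_fragments(t, x, f)` splits `x` into `f` contiguous pieces of
length ⌈m/f⌉ (remainder in the last piece) and aligns piece `r + 1`
against the text suffix starting right after piece `r`'s ending
position, capping each piece's β at the remaining text length − 1.
Fragments therefore tile the text left to right like successive
extension steps, the total score is the exact sum of piece scores, and
the number of gaps is bounded by `f`. If the text is exhausted before
all pieces are placed the whole call reports "no alignment" rather
than guessing a penalty. `align_optimal_fragments` evaluates the total
score for each `f = 1..f_max` without traceback, picks the maximiser
(ties to the smaller `f`), and re-runs it with traceback. Fragment
drivers are defined for score mode only, since the selection criterion
is the summed score.

## Baselines

`semi_global_gotoh` is a full three-state affine-gap aligner with free
end gaps on both sequences — the configuration EMBOSS `needle` uses by
default — and a fixed traceback preference (substitution, then gap in
pattern, then gap in text; gap closure checked before extension). It
is the "conventional aligner" in the comparisons and may open any
number of gaps. `brute_force_single_gap` enumerates every ending
position and gap start directly from the definitions (O(n·m)
candidates) and is the oracle the banded kernel is tested against; it
refuses sequences longer than 64 residues to keep it honest as a test
tool.

## Synthetic data

**Pairs.** Two copies of a uniform random DNA sequence (default
100 bp); one copy loses a run of uniform length 1–30 (the gap — side
chosen uniformly); 1–10 substitutions (always to a different base) are
scattered uniformly over the columns outside the gap locus. All edits
are recorded, so removing the gap locus leaves exactly the recorded
mismatches.

One placement rule matters: the gap run ends at least `end_margin`
(default 15) columns before the right end of the sequences. Within
roughly `(open + (β−1)·extend)/match` columns of the right end the
recorded truth is *not* the optimum of any affine-gap aligner — the
free trailing end gap can absorb the gap outright, or stretch it to
swallow nearby substitutions, at less than the mismatch cost — so no
aligner could be expected to report the inserted edits there, and
validity/correctness counts would measure end-effect ambiguity rather
than aligner behaviour. With the margin, the recorded edits are the
unambiguous optimum at both penalty settings used in the comparison
(verified empirically: the single-gap aligner recovers them in
≥ 99.9% of pairs). Substitutions are *not* kept away from the gap's
immediate neighbourhood: mismatch-adjacent-to-gap configurations are
exactly what makes an unrestricted aligner split one gap into two, the
phenomenon the comparison exists to measure.

**Reads.** Fixed-length reads (default 100 bp) from a reference, each
base independently substituted with probability 1.6×10⁻³ and opening a
gap with probability 2.4×10⁻⁵ (frequencies observed in plant
resequencing data); 42% of gaps are insertions, 58% deletions.
Insertions shorten the consumed reference window, deletions lengthen
it, so reads keep their nominal length exactly and the recorded edits
invert the read onto its origin window. Gap lengths follow a truncated
geometric distribution on 1..30 (decay 0.75) with a ×2 boost at
multiples of 3, emulating the qualitative shape of observed
indel-length spectra (exponential decrease, triplet periodicity); the
real spectra are not reproduced numerically, only parametrically.

What the generators do *not* emulate: base-quality profiles,
technology-specific error modes, repeat structure or compositional
bias of real genomes. Passing the evaluation on synthetic references
shows the aligners and the classification pipeline behave as designed
under the stated edit model, not that accuracy numbers transfer to any
particular organism.

## Evaluation

An observed alignment is **valid** if its number of internal gaps is
at most the number originally inserted, where a gap run touching the
right end of the alignment is a free end gap and does not count
(leading runs do count); **correct** if it is valid and both its total
gap length and its mismatch count are at most the inserted ones;
**accuracy** is the fraction of correct alignments. For the banded
aligner's results these quantities come from traceback; for the Gotoh
baseline they are recounted from the aligned strings.

`run_pair_experiment` aligns generated pairs with the single-gap
aligner (score mode, band covering the whole text unless β is given)
and the Gotoh baseline and tabulates valid/correct. The single-gap
aligner is valid on every pair by construction. At n = 10,000 pairs
the Gotoh valid fraction is ≈ 0.94 at penalties 10.0/0.5 and ≈ 0.75 at
8.0/1.0 — the unrestricted aligner's tendency to split a long gap
grows as opening gets cheaper relative to extension.

`run_accuracy_experiment` simulates reads and aligns each against its
true origin window plus β trailing reference bases (the seed step is
assumed done; the free end gap absorbs the slack), for the single-gap
aligner, the fragment variants, the Gotoh baseline, and a gapless
Hamming extender. Raising the Gotoh gap-open penalty on a fixed read
set raises its valid count but lowers its correct count (true gaps get
suppressed in favour of runs of mismatches); on the pair protocol —
where every pair carries a real 1–30 bp gap — the correct count
instead rises with the open penalty, so the trade-off is asserted on
reads, its native regime.

## Problem sizes and numerics

Default test/experiment sizes: 10,000 pairs per penalty setting,
10,000 random oracle-equivalence instances (n ≤ 14, m ≤ 9, β ≤ 4),
2,000–4,000 pairs/reads for the monotonicity and fragment properties,
26,000–60,000 reads for simulator calibration — chosen so the whole
suite runs in well under a minute of kernel time on one core; the
inner DP loops (banded fills and the Gotoh fill) are numba-compiled,
everything else is numpy/Python. Sequences are handled as uint8 code
arrays; count mode compares raw bytes, score mode indexes the matrix
by alphabet position. Degenerate inputs (empty sequences, β ≥ n,
patterns longer than n + β, fragments that exhaust the text) raise or
report "no alignment" explicitly rather than returning sentinel
scores.

## Known limitations

* One gap per kernel call is a modelling commitment, not an
  approximation: inputs whose true alignment needs two nearby gaps are
  served only by the fragment drivers, whose split points are
  positional rather than adaptive.
* The Gotoh baseline fixes one deterministic tie-breaking; alignments
  (and hence valid/correct counts) at exactly tied scores may differ
  from other implementations of the same objective.
* The read simulator's per-base Bernoulli model matches stated
  aggregate frequencies in expectation but has no position-dependent
  error structure.
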