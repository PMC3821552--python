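"""Validity / correctness classification and the simulation experiments.

An observed alignment is *valid* when it contains no more internal gaps
than were originally inserted into the simulated input (a gap run
touching the right end of the alignment is a free end gap and does not
count), and *correct* when it is valid and both its total gap length
and its mismatch count are at most the inserted ones.  *Accuracy* is
the fraction of correct alignments over a dataset.

``run_pair_experiment`` regenerates the pair-protocol comparison of the
single-gap aligner against the conventional Gotoh semi-global aligner;
``run_accuracy_experiment`` does the same for simulated reads extended
against their true origin window (the seed step is assumed done, so the
aligner sees the right window plus ``beta`` slack bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .api import FragmentedAlignment, align_fragments, align_optimal_fragments, one_to_one
from .core import AlignmentResult, AlignParams
from .reference import GenericAlignment, count_internal_gaps, semi_global_gotoh
from .scoring import GapPenalty, SubstitutionMatrix, hamming, load_matrix
from .simulate import SimulatedPair, SimulatedRead, generate_pair, random_dna, simulate_reads

__all__ = [
    "Classification",
    "ExperimentReport",
    "classify",
    "observed_counts",
    "run_pair_experiment",
    "run_accuracy_experiment",
    "PAIR_PROGRAMMES",
    "READ_PROGRAMMES",
]

PAIR_PROGRAMMES = ("single_gap", "gotoh")
READ_PROGRAMMES = ("one_to_one", "f2", "f3", "onf2", "onf3", "gotoh")


@dataclass
class Classification:
    valid: bool
    correct: bool
    observed_gap_count: int
    observed_gap_total: int
    observed_mismatches: int


@dataclass
class ExperimentReport:
    n_pairs: int
    seed: int
    params: dict
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def accuracy(self, programme: str) -> float:
        return self.counts[programme]["correct"] / self.n_pairs if self.n_pairs else 0.0

    def to_rows(self) -> list[dict]:
        return [
            {
                "programme": p,
                "valid": c["valid"],
                "correct": c["correct"],
                "accuracy": self.accuracy(p),
            }
            for p, c in self.counts.items()
        ]

    def render(self) -> str:
        lines = [f"{'Programme':<12}{'Valid':>10}{'Correct':>10}{'Accuracy':>10}"]
        for row in self.to_rows():
            lines.append(
                f"{row['programme']:<12}{row['valid']:>10}{row['correct']:>10}"
                f"{row['accuracy']:>10.4f}"
            )
        return "\n".join(lines)


def observed_counts(
    observed: GenericAlignment | AlignmentResult | FragmentedAlignment,
) -> tuple[int, int, int]:
    """(gap count, total gap length, mismatches) of an observed alignment.

    Gap runs touching the right end of the alignment are free end gaps
    and are excluded, whichever representation the alignment uses.
    """
    if isinstance(observed, GenericAlignment):
        gaps, total = count_internal_gaps(observed)
        return gaps, total, observed.mismatches
    if isinstance(observed, FragmentedAlignment):
        gaps = total = mism = 0
        last = len(observed.fragments) - 1
        for idx, frag in enumerate(observed.fragments):
            if idx == last:
                g, tot, mis = observed_counts(frag)
                gaps, total, mism = gaps + g, total + tot, mism + mis
            else:
                # internal fragments: even an end-touching gap is internal overall
                gaps += 1 if frag.gap_length else 0
                total += frag.gap_length
                mism += frag.mismatches or 0
        return gaps, total, mism
    if observed.gap_pos is None:
        raise ValueError("observed alignment lacks traceback information")
    gaps, total = (1, observed.gap_length) if observed.gap_length else (0, 0)
    if observed.gap_length:
        ncols = (
            observed.end_text
            if observed.gap_side == "in_pattern"
            else observed.end_text + observed.gap_length
        )
        if observed.gap_pos + observed.gap_length - 1 == ncols:
            gaps, total = 0, 0  # the gap is a trailing end gap
    return gaps, total, observed.mismatches or 0


def _truth_counts(truth) -> tuple[int, int, int]:
    if isinstance(truth, SimulatedPair):
        return 1, truth.gap_length, truth.n_mismatches
    if isinstance(truth, SimulatedRead):
        return truth.n_gaps, truth.truth_gap_total, truth.n_mismatches
    raise ValueError(f"truth must be a SimulatedPair or SimulatedRead, got {type(truth)!r}")


def classify(observed, truth) -> Classification:
    """Apply the validity and correctness rules to one alignment."""
    t_gaps, t_total, t_mis = _truth_counts(truth)
    o_gaps, o_total, o_mis = observed_counts(observed)
    valid = o_gaps <= t_gaps
    correct = valid and o_total <= t_total and o_mis <= t_mis
    return Classification(
        valid=valid,
        correct=correct,
        observed_gap_count=o_gaps,
        observed_gap_total=o_total,
        observed_mismatches=o_mis,
    )


def run_pair_experiment(
    n_pairs: int,
    length: int = 100,
    gap_len_range: tuple[int, int] = (1, 30),
    mis_range: tuple[int, int] = (1, 10),
    gap: GapPenalty = GapPenalty(10.0, 0.5),
    beta: int | None = None,
    programmes: Iterable[str] = PAIR_PROGRAMMES,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
    pairs: list[SimulatedPair] | None = None,
) -> ExperimentReport:
    """Generate pairs, align with each programme, count valid/correct.

    ``single_gap`` is the banded one-gap aligner in score mode with the
    band covering the whole text (beta = n - 1 unless given); ``gotoh``
    is the conventional semi-global aligner.  A pre-generated ``pairs``
    list may be passed to evaluate several penalty settings on the same
    inputs.
    """
    matrix = matrix if matrix is not None else load_matrix("EDNAFULL")
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = [generate_pair(length, gap_len_range, mis_range, rng) for _ in range(n_pairs)]
    report = ExperimentReport(
        n_pairs=len(pairs),
        seed=seed,
        params={
            "length": length,
            "gap_len_range": list(gap_len_range),
            "mis_range": list(mis_range),
            "gap_open": gap.open,
            "gap_extend": gap.extend,
            "beta": beta,
            "matrix": matrix.name,
        },
    )
    for prog in programmes:
        report.counts[prog] = {"valid": 0, "correct": 0}
    for pair in pairs:
        for prog in programmes:
            if prog == "single_gap":
                b = beta if beta is not None else len(pair.t) - 1
                params = AlignParams(beta=b, mode="score", matrix=matrix, gap=gap)
                obs = one_to_one(pair.t, pair.x, params)
            elif prog == "gotoh":
                obs = semi_global_gotoh(pair.t, pair.x, matrix, gap)
            else:
                raise ValueError(f"unknown pair programme {prog!r}")
            c = classify(obs, pair)
            report.counts[prog]["valid"] += c.valid
            report.counts[prog]["correct"] += c.correct
    return report


def _align_read(prog, window, read, params):
    if prog == "one_to_one":
        return one_to_one(window, read, params)
    if prog.startswith("onf"):
        return align_optimal_fragments(window, read, int(prog[3:]), params)
    if prog.startswith("f"):
        return align_fragments(window, read, int(prog[1:]), params)
    raise ValueError(f"unknown read programme {prog!r}")


def run_accuracy_experiment(
    reference: str | None,
    n_reads: int,
    read_len: int = 100,
    mismatch_freq: float = 1.6e-3,
    gap_freq: float = 2.4e-5,
    insertion_fraction: float = 0.42,
    beta: int = 30,
    gap: GapPenalty = GapPenalty(10.0, 0.5),
    programmes: Iterable[str] = READ_PROGRAMMES,
    seed: int = 0,
    reference_length: int = 200_000,
    matrix: SubstitutionMatrix | None = None,
    reads: list[SimulatedRead] | None = None,
    max_gaps: int | None = None,
) -> ExperimentReport:
    """Simulate reads and measure per-programme extension accuracy.

    Each read is aligned against the window of the reference it came
    from, extended by ``beta`` trailing bases (the free end gap absorbs
    the slack) — the seed step of seed-and-extend is taken as given.
    The ``no_gap`` programme extends by Hamming distance alone.
    """
    matrix = matrix if matrix is not None else load_matrix("EDNAFULL")
    rng = np.random.default_rng(seed)
    if reads is None:
        if reference is None:
            reference = random_dna(reference_length, rng)
        reads = simulate_reads(
            reference,
            n_reads,
            read_len=read_len,
            mismatch_freq=mismatch_freq,
            gap_freq=gap_freq,
            insertion_fraction=insertion_fraction,
            rng=rng,
            max_gaps=max_gaps,
        )
    elif reference is None:
        raise ValueError("pre-simulated reads need the reference they came from")
    report = ExperimentReport(
        n_pairs=len(reads),
        seed=seed,
        params={
            "read_len": read_len,
            "mismatch_freq": mismatch_freq,
            "gap_freq": gap_freq,
            "insertion_fraction": insertion_fraction,
            "beta": beta,
            "gap_open": gap.open,
            "gap_extend": gap.extend,
        },
    )
    for prog in programmes:
        report.counts[prog] = {"valid": 0, "correct": 0}
    params = AlignParams(beta=beta, mode="score", matrix=matrix, gap=gap)
    for read in reads:
        _, start, end = read.origin
        window = reference[start - 1 : min(end + beta, len(reference))]
        for prog in programmes:
            if prog == "gotoh":
                obs = semi_global_gotoh(window, read.read, matrix, gap)
                c = classify(obs, read)
            elif prog == "no_gap":
                mism = hamming(window[: len(read.read)], read.read)
                c = Classification(True, mism <= read.n_mismatches, 0, 0, mism)
            else:
                obs = _align_read(prog, window, read.read, params)
                if obs is None or (isinstance(obs, FragmentedAlignment) and not obs.found):
                    c = Classification(False, False, 0, 0, 0)
                else:
                    c = classify(obs, read)
            report.counts[prog]["valid"] += c.valid
            report.counts[prog]["correct"] += c.correct
    return report
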