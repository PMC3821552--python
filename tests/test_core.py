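"""The banded single-gap kernel: fills, optimum search, traceback."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onegap.core import (
    AlignParams,
    best_cell,
    count_solutions,
    fill_count,
    fill_score,
    traceback,
)
from onegap.reference import brute_force_single_gap
from onegap.scoring import GapPenalty, hamming

from conftest import random_seq


class TestFillCount:
    def test_short_example_cells(self, example_short):
        t, x, *_ = example_short
        dp = fill_count(t, x, 1)
        assert dp.value(6, 5) == 1
        assert dp.value(5, 5) == 2  # diagonal cell: plain Hamming distance

    def test_identity_diagonal(self):
        dp = fill_count("ACGTACGT", "ACGTACGT", 1)
        assert dp.value(8, 8) == 0
        assert dp.gap_at(8, 8) == 0

    def test_diagonal_law(self, rng):
        t = random_seq(rng, 12)
        x = random_seq(rng, 9)
        dp = fill_count(t, x, 3)
        for j in range(1, 10):
            assert dp.value(j, j) == hamming(t[:j], x[:j])

    def test_band_cells_absent(self):
        dp = fill_count("ACGTACGTAC", "ACGTA", 2)
        with pytest.raises(IndexError):
            dp.value(8, 5)  # |i - j| = 3 > beta
        with pytest.raises(IndexError):
            dp.value(1, 4)

    def test_leading_gap_base_cases(self):
        dp = fill_count("ACGTACGT", "ACG", 2)
        assert dp.value(2, 0) == 0 and dp.gap_at(2, 0) == 2
        assert dp.value(0, 2) == 0 and dp.gap_at(0, 2) == 2

    def test_beta_at_least_text_length_rejected(self):
        with pytest.raises(ValueError):
            fill_count("ACGT", "ACG", 4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fill_count("", "ACG", 0)

    def test_work_bound(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 40))
            m = int(rng.integers(1, 30))
            beta = int(rng.integers(0, n))
            if m > n + beta:
                continue
            dp = fill_count(random_seq(rng, n), random_seq(rng, m), beta)
            assert dp.cells_computed <= (2 * beta + 1) * (min(n, m) + beta + 1)


class TestFillScore:
    def test_identity_score(self, ednafull):
        dp = fill_score("ACGT", "ACGT", ednafull, GapPenalty(), 2)
        assert dp.value(4, 4) == 4 * ednafull.score("A", "A")

    def test_gap_branch_is_admissible(self, ednafull):
        gp = GapPenalty(10.0, 0.5)
        dp = fill_score("AACGT", "ACGT", ednafull, gp, 2)
        assert dp.value(5, 4) >= dp.value(4, 4) - gp(1)

    def test_leading_gap_base_cases(self, ednafull):
        gp = GapPenalty(10.0, 0.5)
        dp = fill_score("ACGTACGT", "ACG", ednafull, gp, 2)
        assert dp.value(2, 0) == -gp(2)
        assert dp.value(0, 1) == -gp(1)

    def test_unknown_letter_names_it(self, ednafull):
        with pytest.raises(KeyError, match="'J'"):
            fill_score("ACJT", "ACGT", ednafull, GapPenalty(), 2)


class TestBestCellAndTraceback:
    def test_short_example_full_solution(self, example_short):
        t, x, k, alpha, beta = example_short
        params = AlignParams(beta=beta, alpha=alpha, k=k, mode="count")
        dp = fill_count(t, x, beta)
        res = best_cell(dp, params)
        assert res.end_text == 6
        full = traceback(dp, (res.end_text, dp.m))
        assert (full.gap_side, full.gap_length, full.gap_pos) == ("in_pattern", 1, 5)
        assert full.mismatches == 1

    def test_long_example_full_solution(self, example_long):
        t, x, k, alpha, beta = example_long
        params = AlignParams(beta=beta, alpha=alpha, k=k, mode="count")
        dp = fill_count(t, x, beta)
        res = best_cell(dp, params)
        assert res.end_text == 11
        full = traceback(dp, (11, 5))
        assert full.mismatches == 2
        assert full.gap_length == 6
        assert full.gap_side == "in_pattern"

    def test_identity_has_no_gap(self, ednafull):
        dp = fill_score("ACGTAC", "ACGTAC", ednafull, GapPenalty(), 2)
        res = best_cell(dp, AlignParams(beta=2))
        assert res.end_text == 6 and res.gap_side == "none"
        full = traceback(dp, (6, 6))
        assert full.gap_pos == 0 and full.gap_length == 0

    def test_gap_length_equals_band_offset(self, rng, ednafull):
        for _ in range(50):
            n = int(rng.integers(4, 16))
            m = int(rng.integers(2, 10))
            beta = int(rng.integers(1, min(n, 5)))
            if m > n + beta:
                continue
            dp = fill_score(random_seq(rng, n), random_seq(rng, m), ednafull, GapPenalty(), beta)
            res = best_cell(dp, AlignParams(beta=beta))
            if res is None:
                continue
            full = traceback(dp, (res.end_text, m))
            assert full.gap_length == abs(res.end_text - m)

    def test_admissibility_filter_respects_alpha(self, rng, ednafull):
        # with alpha set, any gapped optimum must have length in [alpha, beta]
        for _ in range(40):
            n = int(rng.integers(6, 16))
            m = int(rng.integers(2, 9))
            beta, alpha = 4, 3
            if m > n + beta:
                continue
            dp = fill_score(random_seq(rng, n), random_seq(rng, m), ednafull, GapPenalty(), beta)
            res = best_cell(dp, AlignParams(beta=beta, alpha=alpha))
            assert res is not None
            assert res.gap_length == 0 or alpha <= res.gap_length <= beta


class TestCountSolutions:
    def test_long_example_contains_printed_solution(self, example_long):
        t, x, k, alpha, beta = example_long
        sols = count_solutions(t, x, k, alpha, beta)
        assert 11 in {s.end_text for s in sols}
        eleven = next(s for s in sols if s.end_text == 11)
        assert eleven.mismatches == 2 and eleven.gap_length == 6

    def test_exact_prefix_occurrence(self):
        t = "ACGTACGT"
        sols = count_solutions(t, t[:5], 0, 0, 3)
        gapless = [s for s in sols if s.gap_length == 0]
        assert len(gapless) == 1 and gapless[0].end_text == 5

    def test_matches_brute_force_enumeration(self, rng):
        """Solution sets equal direct enumeration of every gap placement."""
        for _ in range(120):
            n = int(rng.integers(2, 13))
            m = int(rng.integers(2, min(9, n + 1)))
            beta = int(rng.integers(0, min(3, n - 1) + 1))
            alpha = int(rng.integers(0, beta + 1))
            k = int(rng.integers(0, m))
            t, x = random_seq(rng, n), random_seq(rng, m)
            got = {s.end_text for s in count_solutions(t, x, k, alpha, beta)}
            expected = set()
            for i in range(max(0, m - beta), min(n, m + beta) + 1):
                L = abs(i - m)
                if L == 0 and alpha != 0:
                    continue
                if L > 0 and not alpha <= L <= beta:
                    continue
                best = _enumerate_cell_minimum(t, x, i, m)
                if best <= k:
                    expected.add(i)
            assert got == expected, (t, x, k, alpha, beta)

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            count_solutions("ACGT", "AC", 2, 0, 2)  # k >= m
        with pytest.raises(ValueError):
            count_solutions("ACGT", "ACG", 1, 2, 1)  # alpha > beta


def _enumerate_cell_minimum(t: str, x: str, i: int, m: int) -> int:
    """Minimum mismatches over all single-gap strings ending at text position i."""
    L = abs(i - m)
    if L == 0:
        return hamming(t[:m], x)
    best = 10**9
    if i > m:  # gap in the pattern
        for g0 in range(m + 1):
            v = hamming(t[:g0], x[:g0]) + hamming(t[g0 + L : i], x[g0:])
            best = min(best, v)
    else:  # gap in the text
        for g0 in range(i + 1):
            v = hamming(t[:g0], x[:g0]) + hamming(t[g0:i], x[g0 + L :])
            best = min(best, v)
    return best


class TestFreeEndGapLaw:
    @given(data=st.data())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_appending_text_never_hurts(self, ednafull, data):
        n = data.draw(st.integers(4, 12))
        m = data.draw(st.integers(2, 8))
        beta = data.draw(st.integers(1, 3))
        if m > n + beta:
            m = n + beta
        t = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
        x = data.draw(st.text(alphabet="ACGT", min_size=m, max_size=m))
        extra = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
        gp = GapPenalty()
        r1 = best_cell(fill_score(t, x, ednafull, gp, beta), AlignParams(beta=beta))
        r2 = best_cell(fill_score(t + extra, x, ednafull, gp, beta), AlignParams(beta=beta))
        if r1 is not None:
            assert r2 is not None and r2.score >= r1.score
            if r2.end_text == r1.end_text:
                assert r2.score == r1.score and r2.gap_length == r1.gap_length


class TestOracleEquivalence:
    """The banded kernel against direct enumeration, both value semantics."""

    @pytest.mark.parametrize("mode", ["count", "score"])
    def test_random_instances(self, mode, rng, ednafull, eblosum62):
        for trial in range(400):
            mat = ednafull if trial % 2 == 0 else eblosum62
            letters = "ACGT" if trial % 2 == 0 else "ARNDCQEGHILKMFPSTWYV"
            n = int(rng.integers(2, 15))
            m = int(rng.integers(1, 10))
            beta = int(rng.integers(0, min(n, 5)))
            if m > n + beta:
                continue
            alpha = int(rng.integers(0, beta + 1)) if mode == "count" else 0
            t, x = random_seq(rng, n, letters), random_seq(rng, m, letters)
            params = AlignParams(beta=beta, alpha=alpha, mode=mode, matrix=mat)
            if mode == "count":
                dp = fill_count(t, x, beta)
            else:
                dp = fill_score(t, x, mat, params.gap, beta)
            got = best_cell(dp, params)
            want = brute_force_single_gap(t, x, params)
            if want is None:
                assert got is None
                continue
            got = traceback(dp, (got.end_text, m))
            assert got.end_text == want.end_text
            assert got.gap_length == want.gap_length
            assert got.gap_side == want.gap_side
            assert got.gap_pos == want.gap_pos
            if mode == "count":
                assert got.mismatches == want.mismatches
            else:
                assert got.score == pytest.approx(want.score)
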