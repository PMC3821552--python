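"""Ground-truth-annotated synthetic inputs for the evaluation harness.

Two generators are provided.

``generate_pair`` implements the pair protocol used for the validity /
correctness comparison: start from two identical random DNA sequences,
delete a single uniformly placed run of uniform random length from one
of them (which is exactly an alignment gap between the two), then
scatter a uniform number of substitutions over the columns outside the
gap locus.  Every edit is recorded so downstream classification can
compare what an aligner reports against what was actually inserted.

``simulate_reads`` emulates re-sequencing: fixed-length reads are drawn
from a reference with per-base Bernoulli mismatches and gap openings, a
configurable insertion/deletion mix, and a parametric gap-length
distribution (truncated geometric with a multiplicative boost at
multiples of three, mimicking the shape reported for real indel
spectra).  Reads keep their nominal length exactly: insertions push the
window end left, deletions pull extra reference bases in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulatedPair",
    "SimulatedRead",
    "random_dna",
    "generate_pair",
    "gap_length_weights",
    "simulate_reads",
    "write_fasta",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA sequence of the given length."""
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class SimulatedPair:
    """A sequence pair differing by one known gap plus known mismatches."""

    t: str
    x: str
    gap_length: int
    gap_in: str  # "text" | "pattern": which sequence lost the run
    gap_position: int  # 1-based start of the deleted run in the intact copy
    n_mismatches: int
    mismatch_positions: list[int]  # 1-based, in the intact copy's frame
    seed_info: str = ""


@dataclass
class SimulatedRead:
    """A read plus the exact edits that separate it from its origin window."""

    read: str
    origin: tuple[str, int, int]  # (reference id, 1-based start, 1-based end)
    edits: list[tuple[str, int, int]]  # (kind, 1-based read position, length)
    seed_info: str = ""

    @property
    def n_gaps(self) -> int:
        return sum(1 for k, _, _ in self.edits if k in ("insertion", "deletion"))

    @property
    def truth_gap_total(self) -> int:
        return sum(L for k, _, L in self.edits if k in ("insertion", "deletion"))

    @property
    def n_mismatches(self) -> int:
        return sum(1 for k, _, _ in self.edits if k == "mismatch")


def generate_pair(
    length: int = 100,
    gap_len_range: tuple[int, int] = (1, 30),
    mis_range: tuple[int, int] = (1, 10),
    rng: np.random.Generator | None = None,
    end_margin: int = 15,
    mismatch_buffer: int = 0,
) -> SimulatedPair:
    """One pair of the validity/correctness protocol (see module docstring).

    ``end_margin`` keeps the gap run at least that many columns away
    from the right end of the sequences.  Near the right end the
    recorded truth is not the optimum under any affine scheme: the
    trailing free end gap can absorb or stretch a gap placed there at
    less than its mismatch cost, so no aligner could be expected to
    report the inserted edits.  ``mismatch_buffer`` optionally keeps
    substituted columns away from the gap run (default 0: substitutions
    land anywhere outside the gap locus).  Set end_margin to 0 for
    fully uniform placement.
    """
    rng = rng if rng is not None else np.random.default_rng()
    glo, ghi = gap_len_range
    mlo, mhi = mis_range
    if not 1 <= glo <= ghi:
        raise ValueError(f"gap length range must satisfy 1 <= lo <= hi, got {gap_len_range}")
    if not 0 <= mlo <= mhi:
        raise ValueError(f"mismatch range must satisfy 0 <= lo <= hi, got {mis_range}")
    if length <= ghi + end_margin:
        raise ValueError(
            f"sequence length {length} must exceed max gap {ghi} plus the end margin"
        )

    full = rng.choice(_BASES, size=length).copy()
    short = full.copy()
    L = int(rng.integers(glo, ghi + 1))
    # 0-based start of the deleted run, end_margin columns clear of the right end
    p0 = int(rng.integers(0, length - L - end_margin + 1))
    short = np.delete(short, np.arange(p0, p0 + L))
    gap_in = "text" if rng.integers(2) == 0 else "pattern"

    # columns shared by both copies (intact frame), a buffer clear of the gap
    lo = max(0, p0 - mismatch_buffer)
    hi = min(length, p0 + L + mismatch_buffer)
    common = np.concatenate([np.arange(0, lo), np.arange(hi, length)])
    n_mis = int(rng.integers(mlo, mhi + 1))
    cols = rng.choice(common, size=n_mis, replace=False)
    for c in np.sort(cols):
        mutate_full = rng.integers(2) == 0
        c_short = c if c < p0 else c - L
        old = full[c] if mutate_full else short[c_short]
        choices = _BASES[_BASES != old]
        new = choices[rng.integers(len(choices))]
        if mutate_full:
            full[c] = new
        else:
            short[c_short] = new

    full_s = full.tobytes().decode("ascii")
    short_s = short.tobytes().decode("ascii")
    t, x = (short_s, full_s) if gap_in == "text" else (full_s, short_s)
    return SimulatedPair(
        t=t,
        x=x,
        gap_length=L,
        gap_in=gap_in,
        gap_position=p0 + 1,
        n_mismatches=n_mis,
        mismatch_positions=sorted(int(c) + 1 for c in cols),
    )


def gap_length_weights(
    max_len: int = 30, decay: float = 0.75, triplet_boost: float = 2.0
) -> np.ndarray:
    """Gap-length distribution: truncated geometric with a boost at multiples of 3.

    ``decay`` is the per-position geometric ratio; lengths divisible by
    three get their weight multiplied by ``triplet_boost``, reproducing
    the qualitative shape of observed indel-length spectra (exponential
    decrease with a 3-periodic preference).  Returns normalised weights
    for lengths 1..max_len.
    """
    lengths = np.arange(1, max_len + 1)
    w = decay ** (lengths - 1)
    w[lengths % 3 == 0] *= triplet_boost
    return w / w.sum()


def simulate_reads(
    reference: str,
    n: int,
    read_len: int = 100,
    mismatch_freq: float = 1.6e-3,
    gap_freq: float = 2.4e-5,
    insertion_fraction: float = 0.42,
    gap_len_weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    reference_id: str = "ref",
    max_gaps: int | None = None,
) -> list[SimulatedRead]:
    """Sample ``n`` reads of exactly ``read_len`` bases with per-base edits.

    Each read position independently mutates with probability
    ``mismatch_freq`` and opens a gap with probability ``gap_freq``; a
    gap is an insertion with probability ``insertion_fraction``, else a
    deletion, with length drawn from ``gap_len_weights`` (defaults to
    ``gap_length_weights()``).  ``max_gaps`` optionally caps the number
    of gaps per read.  Reads whose edits would run off the reference are
    re-drawn (bounded retries).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if gap_len_weights is None:
        gap_len_weights = gap_length_weights()
    max_gap_len = len(gap_len_weights)
    ref = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8)
    margin = read_len + max_gap_len * 4
    if len(ref) < margin:
        raise ValueError(
            f"reference of length {len(ref)} is too short for {read_len} bp reads"
        )
    lengths = np.arange(1, max_gap_len + 1)

    starts = rng.integers(0, len(ref) - margin + 1, size=n)
    n_gap_sites = rng.binomial(read_len, gap_freq, size=n)
    if max_gaps is not None:
        n_gap_sites = np.minimum(n_gap_sites, max_gaps)
    n_mis_sites = rng.binomial(read_len, mismatch_freq, size=n)

    reads: list[SimulatedRead] = []
    for r in range(n):
        for _attempt in range(100):
            start = int(starts[r])
            k_gap = int(n_gap_sites[r])
            k_mis = int(n_mis_sites[r])
            read, edits, consumed = _build_read(
                ref, start, read_len, k_gap, k_mis,
                insertion_fraction, gap_len_weights, lengths, rng,
            )
            if read is not None:
                reads.append(
                    SimulatedRead(
                        read=read,
                        origin=(reference_id, start + 1, start + consumed),
                        edits=edits,
                    )
                )
                break
            starts[r] = rng.integers(0, len(ref) - margin + 1)
        else:
            raise RuntimeError("could not place a read after 100 retries")
    return reads


def _build_read(ref, start, read_len, k_gap, k_mis, ins_frac, weights, lengths, rng):
    if k_gap == 0 and k_mis == 0:
        read = ref[start : start + read_len]
        return read.tobytes().decode("ascii"), [], read_len

    gap_pos = np.sort(rng.choice(read_len, size=k_gap, replace=False)) if k_gap else []
    out = np.empty(read_len, dtype=np.uint8)
    from_ref = np.ones(read_len, dtype=bool)
    edits: list[tuple[str, int, int]] = []
    rp = 0  # next read position to fill (0-based)
    ref_i = start
    for g in gap_pos:
        g = int(g)
        if g < rp:
            continue  # site swallowed by a previous deletion/insertion
        span = g - rp
        out[rp : rp + span] = ref[ref_i : ref_i + span]
        rp += span
        ref_i += span
        L = int(rng.choice(lengths, p=weights))
        if rng.random() < ins_frac:
            L = min(L, read_len - rp)
            if L == 0:
                continue
            out[rp : rp + L] = _BASES[rng.integers(0, 4, size=L)]
            from_ref[rp : rp + L] = False
            edits.append(("insertion", rp + 1, L))
            rp += L
        else:
            edits.append(("deletion", rp + 1, L))
            ref_i += L
    tail = read_len - rp
    if ref_i + tail > len(ref):
        return None, [], 0
    out[rp:] = ref[ref_i : ref_i + tail]
    ref_i += tail
    consumed = ref_i - start

    if k_mis:
        eligible = np.flatnonzero(from_ref)
        k_mis = min(k_mis, len(eligible))
        for p in np.sort(rng.choice(eligible, size=k_mis, replace=False)):
            p = int(p)
            choices = _BASES[_BASES != out[p]]
            out[p] = choices[rng.integers(len(choices))]
            edits.append(("mismatch", p + 1, 1))
    edits.sort(key=lambda e: e[1])
    return out.tobytes().decode("ascii"), edits, consumed


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) records as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(reads: list[SimulatedRead], path) -> None:
    """Truth sidecar: one row per read with origin and serialised edits."""
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tstart\tend\tn_gaps\tgap_total\tn_mismatches\tedits\n")
        for i, r in enumerate(reads):
            ed = ";".join(f"{k}:{p}:{L}" for k, p, L in r.edits)
            fh.write(
                f"read_{i}\t{r.origin[0]}\t{r.origin[1]}\t{r.origin[2]}\t"
                f"{r.n_gaps}\t{r.truth_gap_total}\t{r.n_mismatches}\t{ed}\n"
            )
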