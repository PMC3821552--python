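"""FASTA input and alignment rendering (EMBOSS-like text and TSV)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .core import AlignmentResult
from .scoring import DNA, PROTEIN, GapPenalty

__all__ = ["read_fasta", "render_alignment", "parse_tsv_line", "TSV_HEADER"]

TSV_HEADER = "query\ttarget\tscore\tmismatches\tend_text\tgap_side\tgap_pos\tgap_len"


def read_fasta(path: str | Path, alphabet=None) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences are folded to upper case.

    Rejects empty files, duplicate record ids, records without sequence,
    and (when an alphabet is given) sequences with letters outside it.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        if alphabet is not None:
            bad = set(seq) - set(alphabet.letters)
            if bad:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains letters {sorted(bad)} "
                    f"outside the {alphabet.kind} alphabet"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _aligned_strings(result: AlignmentResult, t: str, x: str) -> tuple[str, str]:
    """Rebuild the aligned region (gap rendered as '-') from a traceback result."""
    i, L = result.end_text, result.gap_length
    g0 = (result.gap_pos or 1) - 1
    if result.gap_side == "in_pattern":
        return t[:i], x[:g0] + "-" * L + x[g0:]
    if result.gap_side == "in_text":
        return t[:g0] + "-" * L + t[g0:i], x
    return t[: len(x)], x


def render_alignment(
    result: AlignmentResult,
    t: str,
    x: str,
    style: str = "emboss_like",
    names: tuple[str, str] = ("target", "query"),
    matrix_name: str = "EDNAFULL",
    gp: GapPenalty | None = None,
    width: int = 50,
) -> str:
    """Render a traceback-carrying result as text.

    ``emboss_like``: header lines plus aligned blocks with a midline
    ('|' match, '.' mismatch, ' ' at gaps); the unaligned text suffix is
    shown after the aligned region as the free end gap.  ``tsv``: one
    tab-separated line of the numeric fields.
    """
    if style == "tsv":
        score = "" if result.score is None else f"{result.score:g}"
        return (
            f"{names[1]}\t{names[0]}\t{score}\t"
            f"{result.mismatches}\t{result.end_text}\t{result.gap_side}\t"
            f"{result.gap_pos}\t{result.gap_length}"
        )
    if style != "emboss_like":
        raise ValueError(f"unknown style {style!r}")
    if result.gap_pos is None:
        raise ValueError("emboss_like rendering needs a traceback-enabled result")
    gp = gp or GapPenalty()
    t, x = t.upper(), x.upper()
    at, ax = _aligned_strings(result, t, x)
    mid = "".join(
        " " if "-" in (a, b) else ("|" if a == b else ".") for a, b in zip(at, ax)
    )
    tail = t[result.end_text :]
    if tail:  # free trailing gap against the remaining text
        at += tail
        ax += "-" * len(tail)
        mid += " " * len(tail)

    lines = [
        "########################################",
        f"# 1: {names[0]}",
        f"# 2: {names[1]}",
    ]
    if result.score is not None:
        lines += [
            f"# Matrix: {matrix_name}",
            f"# Gap_penalty: {gp.open:g}",
            f"# Extend_penalty: {gp.extend:g}",
        ]
    lines += [f"# Mismatches: {result.mismatches}"]
    if result.score is not None:
        lines += [f"# Score: {result.score:g}"]
    lines += ["########################################", ""]
    for ofs in range(0, len(at), width):
        lines.append(f"{names[0]:<10} {at[ofs : ofs + width]}")
        lines.append(f"{'':<10} {mid[ofs : ofs + width]}")
        lines.append(f"{names[1]:<10} {ax[ofs : ofs + width]}")
        lines.append("")
    return "\n".join(lines)


def parse_tsv_line(line: str) -> AlignmentResult:
    """Recover the numeric fields of a TSV-rendered result (round-trip)."""
    q, tname, score, mism, end, side, pos, length = line.rstrip("\n").split("\t")
    return AlignmentResult(
        score=float(score) if score else None,
        mismatches=int(mism) if mism not in ("", "None") else None,
        end_text=int(end),
        gap_length=int(length),
        gap_side=side,  # type: ignore[arg-type]
        gap_pos=int(pos) if pos != "None" else None,
    )


def alphabet_for(protein: bool):
    return PROTEIN if protein else DNA
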