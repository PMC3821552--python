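"""Alphabets, substitution matrices and the affine gap penalty.

Substitution matrices are read from EMBOSS matrix files ('#' comment
lines, a header row of letters, one score row per letter).  The two
matrices used throughout short-read work — EDNAFULL for DNA and
EBLOSUM62 for protein — are bundled as package data and can be loaded
by name.  Scores are kept as floats so the mismatch-counting and
score-maximising alignment kernels share one signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Alphabet",
    "SubstitutionMatrix",
    "GapPenalty",
    "load_matrix",
    "write_matrix",
    "gap_penalty",
    "hamming",
    "DNA",
    "PROTEIN",
]

BUNDLED_MATRICES = ("EDNAFULL", "EBLOSUM62")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of residue letters, folded to upper case on use."""

    kind: str  # "dna" | "protein"
    letters: tuple[str, ...]
    fold_case: bool = True

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        required = set("ACGTN") if self.kind == "dna" else set("ARNDCQEGHILKMFPSTWYV")
        missing = required - set(self.letters)
        if missing:
            raise ValueError(f"{self.kind} alphabet is missing {sorted(missing)}")

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.letters)}

    def encode(self, seq: str) -> np.ndarray:
        """Map a sequence to letter indices (uint8), raising on unknown letters."""
        if self.fold_case:
            seq = seq.upper()
        idx = self.index()
        try:
            return np.fromiter((idx[c] for c in seq), dtype=np.uint8, count=len(seq))
        except KeyError as exc:
            raise KeyError(
                f"letter {exc.args[0]!r} is not in the {self.kind} alphabet"
            ) from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric letter-pair score table over an alphabet."""

    alphabet: Alphabet
    scores: np.ndarray = field(repr=False)  # (A, A) float64, symmetric
    name: str = "custom"

    def __post_init__(self) -> None:
        a = len(self.alphabet.letters)
        if self.scores.shape != (a, a):
            raise ValueError("score table shape does not match the alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            i, j = np.argwhere(self.scores != self.scores.T)[0]
            li, lj = self.alphabet.letters[i], self.alphabet.letters[j]
            raise ValueError(f"matrix {self.name!r} is asymmetric at pair ({li}, {lj})")

    def score(self, a: str, b: str) -> float:
        if self.alphabet.fold_case:
            a, b = a.upper(), b.upper()
        idx = self.alphabet.index()
        for letter in (a, b):
            if letter not in idx:
                raise KeyError(f"letter {letter!r} is not in matrix {self.name!r}")
        return float(self.scores[idx[a], idx[b]])


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap penalty: a gap of length L costs ``open + (L - 1) * extend``."""

    open: float = 10.0
    extend: float = 0.5

    def __post_init__(self) -> None:
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def __call__(self, length: int) -> float:
        return gap_penalty(self, length)


def gap_penalty(gp: GapPenalty, length: int) -> float:
    """Cost of a single gap of ``length`` positions (length must be >= 1)."""
    if length < 1:
        raise ValueError(f"gap length must be >= 1, got {length}")
    return gp.open + (length - 1) * gp.extend


def hamming(u: str, v: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(u) != len(v):
        raise ValueError(f"hamming distance needs equal lengths ({len(u)} != {len(v)})")
    u, v = u.upper(), v.upper()
    return sum(a != b for a, b in zip(u, v))


def _parse_emboss(lines: Iterable[str], name: str) -> SubstitutionMatrix:
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if header is None:
            header = [f.upper() for f in fields]
            continue
        letter = fields[0].upper()
        values = [float(v) for v in fields[1:]]
        if len(values) != len(header):
            raise ValueError(
                f"matrix {name!r}: row {letter!r} has {len(values)} scores, "
                f"expected {len(header)}"
            )
        rows[letter] = values
    if header is None:
        raise ValueError(f"matrix {name!r}: no header row of letters found")
    missing = [c for c in header if c not in rows]
    if missing:
        raise ValueError(f"matrix {name!r}: missing score row for letter {missing[0]!r}")
    table = np.array([rows[c] for c in header], dtype=np.float64)
    asym = np.argwhere(table != table.T)
    if asym.size:
        i, j = asym[0]
        raise ValueError(
            f"matrix {name!r} is asymmetric at pair ({header[i]}, {header[j]})"
        )
    kind = "dna" if set("ACGT") <= set(header) and "L" not in header else "protein"
    alphabet = Alphabet(kind=kind, letters=tuple(header))
    return SubstitutionMatrix(alphabet=alphabet, scores=table, name=name)


def load_matrix(path_or_name: str | Path) -> SubstitutionMatrix:
    """Load a substitution matrix from an EMBOSS matrix file.

    ``path_or_name`` may be the name of a bundled matrix ("EDNAFULL",
    "EBLOSUM62") or a path to a file in the same format.
    """
    name = str(path_or_name)
    if name in BUNDLED_MATRICES:
        text = (resources.files("onegap") / "data" / name).read_text()
        return _parse_emboss(text.splitlines(), name)
    path = Path(path_or_name)
    if not path.exists():
        raise FileNotFoundError(f"no bundled matrix or file named {name!r}")
    return _parse_emboss(path.read_text().splitlines(), path.name)


def write_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write a matrix back out in EMBOSS matrix-file format."""
    letters = matrix.alphabet.letters
    with open(path, "w") as fh:
        fh.write(f"# {matrix.name}\n")
        fh.write("  " + " ".join(f"{c:>4}" for c in letters) + "\n")
        for i, a in enumerate(letters):
            row = " ".join(f"{matrix.scores[i, j]:>4.0f}" for j in range(len(letters)))
            fh.write(f"{a} {row}\n")


DNA = load_matrix("EDNAFULL").alphabet
PROTEIN = load_matrix("EBLOSUM62").alphabet
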