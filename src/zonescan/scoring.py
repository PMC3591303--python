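"""Residue alphabet, substitution matrices and k-tuple scores.

Everything downstream of FASTA parsing works on integer residue indices
(0..19 over the 20 standard amino acids, in the column order of the
substitution matrix header) and on integer *tuple codes*: a k-tuple is
encoded base-20, most significant digit first, so the code doubles as a
direct address into the lookup table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Residues outside the 20-letter standard alphabet (ambiguity and stop
#: codes). Tuples containing any of these contribute no seeds.
NONSTANDARD = set("BZXUOJ*-.")

#: Sentinel index for a non-standard residue in an encoded sequence.
BAD_RESIDUE = 255

_BUNDLED = {"BLOSUM62": "BLOSUM62.txt"}


class MatrixValidationError(ValueError):
    """Substitution matrix violates a structural requirement."""


@dataclass(frozen=True)
class ResidueAlphabet:
    """Ordered 20-letter amino-acid alphabet."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != 20 or len(set(self.symbols)) != 20:
            raise ValueError("alphabet must contain 20 distinct residues")

    @property
    def size(self) -> int:
        return 20

    @property
    def index_of(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.symbols)}

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to indices; non-standard letters map to
        :data:`BAD_RESIDUE`."""
        table = np.full(128, BAD_RESIDUE, dtype=np.uint8)
        for i, c in enumerate(self.symbols):
            table[ord(c)] = i
        raw = np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8)
        return table[raw]

    def decode(self, indices) -> str:
        return "".join(self.symbols[int(i)] for i in indices)


@dataclass
class SubstitutionMatrix:
    """20x20 integer residue-pair score table.

    Invariants checked at construction: symmetry, and the self-match score of
    every residue dominating its row (required for the safety of the
    branch-and-bound tuple diversification).
    """

    name: str
    scores: np.ndarray
    alphabet: ResidueAlphabet
    min_score: int = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        if s.shape != (20, 20):
            raise MatrixValidationError("matrix must be 20x20 over the standard residues")
        if not np.array_equal(s, s.T):
            i, j = np.argwhere(s != s.T)[0]
            raise MatrixValidationError(
                f"matrix not symmetric at ({self.alphabet.symbols[i]},{self.alphabet.symbols[j]})"
            )
        diag = np.diag(s)
        bad = np.argwhere(s > diag[:, None])
        if bad.size:
            i, j = bad[0]
            raise MatrixValidationError(
                "self-match score must dominate each row: "
                f"score({self.alphabet.symbols[i]},{self.alphabet.symbols[j]})="
                f"{s[i, j]} > score({self.alphabet.symbols[i]},{self.alphabet.symbols[i]})={s[i, i]}"
            )
        self.scores = s
        self.min_score = int(s.min())

    def score(self, a: str, b: str) -> int:
        idx = self.alphabet.index_of
        return int(self.scores[idx[a], idx[b]])

    def pair_score(self, i: int, j: int) -> int:
        """Score for two encoded residues; any non-standard residue scores
        the matrix minimum (heavily penalised, never rewarded)."""
        if i == BAD_RESIDUE or j == BAD_RESIDUE:
            return self.min_score
        return int(self.scores[i, j])


def _parse_ncbi_matrix(text: str, name: str) -> SubstitutionMatrix:
    rows: dict[str, list[int]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if header is None:
            if any(len(p) != 1 for p in parts):
                raise MatrixValidationError("malformed matrix header row")
            header = parts
            continue
        label, *vals = parts
        if len(label) != 1 or len(vals) != len(header):
            raise MatrixValidationError(f"malformed matrix row for '{label}'")
        rows[label] = [int(v) for v in vals]
    if header is None or not rows:
        raise MatrixValidationError("no matrix content found")
    standard = [c for c in header if c not in NONSTANDARD]
    if len(standard) != 20:
        raise MatrixValidationError("matrix header must include the 20 standard residues")
    alphabet = ResidueAlphabet("".join(standard))
    col = {c: k for k, c in enumerate(header)}
    scores = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(standard):
        if a not in rows:
            raise MatrixValidationError(f"missing matrix row for residue '{a}'")
        for j, b in enumerate(standard):
            scores[i, j] = rows[a][col[b]]
    return SubstitutionMatrix(name=name, scores=scores, alphabet=alphabet)


def load_matrix(source: str | Path = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix from a bundled name or an NCBI-format file.

    The matrix is restricted to the 20 standard residues; symmetry and
    row-dominant self scores are validated on load.
    """
    source = str(source)
    if source.upper() in _BUNDLED:
        ref = importlib.resources.files("zonescan.data") / _BUNDLED[source.upper()]
        return _parse_ncbi_matrix(ref.read_text(), source.upper())
    path = Path(source)
    if path.exists():
        return _parse_ncbi_matrix(path.read_text(), path.stem)
    raise FileNotFoundError(f"unknown matrix '{source}': not bundled and no such file")


# ---------------------------------------------------------------------------
# tuple codes


def encode_tuple(residues: str, alphabet: ResidueAlphabet) -> int:
    """Base-20 positional code of a k-tuple, most significant digit first."""
    idx = alphabet.encode(residues)
    if (idx == BAD_RESIDUE).any():
        bad = residues[int(np.argmax(idx == BAD_RESIDUE))]
        raise ValueError(f"residue '{bad}' is not in the standard alphabet")
    code = 0
    for i in idx:
        code = code * 20 + int(i)
    return code


def decode_tuple(code: int, k: int, alphabet: ResidueAlphabet) -> str:
    if not 0 <= code < 20**k:
        raise ValueError(f"tuple code {code} out of range for k={k}")
    digits = []
    for _ in range(k):
        digits.append(code % 20)
        code //= 20
    return alphabet.decode(reversed(digits))


def code_digits(codes: np.ndarray, k: int) -> np.ndarray:
    """Residue indices of each code, shape (n, k), most significant first."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.empty(codes.shape + (k,), dtype=np.int8)
    for p in range(k - 1, -1, -1):
        out[..., p] = codes % 20
        codes = codes // 20
    return out


def encode_sequence_tuples(indices: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all L-k+1 overlapping k-tuples of an encoded sequence.

    Returns ``(codes, valid)`` where ``valid`` is False for windows touching
    a non-standard residue (those windows carry no usable code).
    """
    indices = np.asarray(indices)
    n = len(indices) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    good = indices != BAD_RESIDUE
    clean = np.where(good, indices, 0).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for p in range(k):
        codes = codes * 20 + clean[p : p + n]
        valid &= good[p : p + n]
    return codes, valid


# ---------------------------------------------------------------------------
# tuple scores


def suffix_match_scores(a_digits, b_digits, matrix: SubstitutionMatrix) -> np.ndarray:
    """suffix[j] = sum of pair scores over positions j..k-1.

    Element 0 is the full-tuple match score.
    """
    a = np.asarray(a_digits, dtype=np.int64)
    b = np.asarray(b_digits, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("tuples must have equal length")
    per_pos = matrix.scores[a, b]
    return per_pos[::-1].cumsum()[::-1].astype(np.int64)


def match_score(a_digits, b_digits, matrix: SubstitutionMatrix) -> int:
    return int(suffix_match_scores(a_digits, b_digits, matrix)[0])


def suffix_self_scores(digits, matrix: SubstitutionMatrix) -> np.ndarray:
    return suffix_match_scores(digits, digits, matrix)


def tuple_self_score(digits, matrix: SubstitutionMatrix) -> int:
    return int(suffix_self_scores(digits, matrix)[0])
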