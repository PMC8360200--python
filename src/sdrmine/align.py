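"""Pairwise protein alignment with affine gap penalties.

This module provides the two alignment engines the mining pipeline is built
on: local (Smith-Waterman) alignment for scoring candidate ORFs against the
seed reductases, and global (Needleman-Wunsch) alignment for the percent
identity used in dereplication and the comparative heat map.

Scoring conventions
-------------------
* Substitution scores come from a named matrix (default BLOSUM62, loaded
  from Biopython).  The ambiguity residue ``X`` scores 0 against every
  residue; any letter outside the matrix alphabet is treated as ``X``.
* A gap of length L costs ``gap_open + gap_extend * L``: the opening charge
  is paid once per gap and every gapped column additionally pays the
  extension charge.
* Global alignments penalise end gaps (true global alignment).
* Traceback is deterministic.  Where several predecessors are co-optimal the
  order of preference is diagonal > up (gap in the second sequence) >
  left (gap in the first sequence), and the local traceback starts from the
  first (row-major) cell attaining the maximum score.

All scores are exact: substitution matrices are integral and the default
gap penalties are multiples of 0.5, both exactly representable in floats,
so equality tests in the traceback are safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_NEG = -1e30  # acts as -infinity in the DP without overflow on arithmetic


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a pairwise alignment.

    ``aligned_a``/``aligned_b`` are equal-length strings with ``-`` for gap
    columns; for a local alignment they cover only the aligned region and
    may be empty when no positive-scoring alignment exists.  ``identity`` is
    ``100 * identical columns / alignment length`` with gap columns counted
    in the denominator (0 for an empty alignment).
    """

    score: float
    aligned_a: str
    aligned_b: str
    identity: float
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0


@lru_cache(maxsize=8)
def _score_table(matrix_name: str) -> tuple[str, np.ndarray]:
    """Return (alphabet, dense score table) for a named substitution matrix.

    The table is symmetric, indexed by position in the returned alphabet.
    The X row/column is forced to 0.
    """
    try:
        mat = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:  # Biopython raises this for unknown names
        raise ValueError(f"unknown substitution matrix: {matrix_name!r}") from exc
    alphabet = str(mat.alphabet)
    if "X" not in alphabet:
        alphabet += "X"
    n = len(alphabet)
    table = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if a == "X" or b == "X":
                table[i, j] = 0.0
            else:
                table[i, j] = float(mat[a, b])
    return alphabet, table


def _encode(seq: str, alphabet: str) -> np.ndarray:
    x_idx = alphabet.index("X")
    lookup = np.full(128, x_idx, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lookup[ord(ch)] = i
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return lookup[codes]


def _fill(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    table: np.ndarray,
    gap_open: float,
    gap_extend: float,
    local: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three affine-gap DP matrices H (match), E (gap in a), F (gap in b)."""
    m, n = len(a_codes), len(b_codes)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    first = gap_open + gap_extend
    if not local:
        H[0, 1:] = -(gap_open + gap_extend * np.arange(1, n + 1))
        H[1:, 0] = -(gap_open + gap_extend * np.arange(1, m + 1))
        E[0, 1:] = H[0, 1:]
        F[1:, 0] = H[1:, 0]
    sub = table[a_codes][:, b_codes] if m and n else np.zeros((m, n))
    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] - gap_extend, H[i - 1, 1:] - first)
        diag = H[i - 1, :-1] + sub[i - 1]
        h_prev = H[i, 0]
        e = E[i, 0]
        row_h = H[i]
        row_e = E[i]
        row_f = F[i]
        for j in range(1, n + 1):
            e = max(e - gap_extend, h_prev - first)
            h = diag[j - 1]
            if row_f[j] > h:
                h = row_f[j]
            if e > h:
                h = e
            if local and h < 0.0:
                h = 0.0
            row_e[j] = e
            row_h[j] = h
            h_prev = h
    return H, E, F


def _traceback(
    a: str,
    b: str,
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    table: np.ndarray,
    H: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
    gap_open: float,
    gap_extend: float,
    local: bool,
    end: tuple[int, int],
) -> AlignmentResult:
    first = gap_open + gap_extend
    i, j = end
    out_a: list[str] = []
    out_b: list[str] = []
    state = "M"
    while True:
        if local:
            if state == "M" and H[i, j] == 0.0:
                break
        elif i == 0 and j == 0:
            break
        if state == "M":
            # preference: diagonal > up > left
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + table[a_codes[i - 1], b_codes[j - 1]]:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise RuntimeError("traceback failed: inconsistent DP matrices")
        elif state == "F":  # gap in b, consume a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            closed = H[i - 1, j] - first
            extended = F[i - 1, j] - gap_extend
            state = "M" if closed >= extended else "F"
            i -= 1
        else:  # state == "E": gap in a, consume b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            closed = H[i, j - 1] - first
            extended = E[i, j - 1] - gap_extend
            state = "M" if closed >= extended else "E"
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    length = len(aligned_a)
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    identity = 100.0 * matches / length if length else 0.0
    return AlignmentResult(
        score=float(H[end]),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        identity=identity,
        a_start=i,
        a_end=end[0],
        b_start=j,
        b_end=end[1],
    )


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Returns the best-scoring local alignment under affine gaps; the score is
    never negative and an all-negative scoring pair yields score 0 with an
    empty alignment.

    Raises ``ValueError`` on empty input or an unknown matrix name.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alphabet, table = _score_table(matrix)
    a_codes = _encode(a, alphabet)
    b_codes = _encode(b, alphabet)
    H, E, F = _fill(a_codes, b_codes, table, gap_open, gap_extend, local=True)
    flat = int(np.argmax(H))  # first maximum in row-major order: deterministic
    end = (flat // H.shape[1], flat % H.shape[1])
    if H[end] == 0.0:
        return AlignmentResult(0.0, "", "", 0.0)
    return _traceback(a, b, a_codes, b_codes, table, H, E, F, gap_open, gap_extend, True, end)


def needleman_wunsch(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment (end gaps penalised) of two protein sequences.

    The default penalties follow the EMBOSS-needle convention commonly used
    for percent-identity reporting.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alphabet, table = _score_table(matrix)
    a_codes = _encode(a, alphabet)
    b_codes = _encode(b, alphabet)
    H, E, F = _fill(a_codes, b_codes, table, gap_open, gap_extend, local=False)
    return _traceback(
        a, b, a_codes, b_codes, table, H, E, F, gap_open, gap_extend, False, (len(a), len(b))
    )
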