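"""Independent brute-force oracles used to certify the fast implementations.

Everything here is deliberately naive: exhaustive enumeration of alignment
move sequences, a genetic-code table decoded from the compact published
TCAG-order string, and a direct (start, stop)-pair ORF enumerator.  None of
it shares code with the package under test.
"""

from __future__ import annotations

from itertools import product

# ---------------------------------------------------------------------------
# genetic code, decoded from the standard compact representation
# (codon order TTT, TTC, TTA, TTG, TCT, ... with base order TCAG)

_BASES = "TCAG"
_TABLE11_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

CODON_TO_AA_11: dict[str, str] = {
    "".join(codon): aa
    for codon, aa in zip(product(_BASES, repeat=3), _TABLE11_AA)
}

STOPS_11 = {c for c, aa in CODON_TO_AA_11.items() if aa == "*"}


def translate_oracle(dna: str) -> str:
    assert len(dna) % 3 == 0
    out = []
    for i in range(0, len(dna), 3):
        out.append(CODON_TO_AA_11.get(dna[i : i + 3].upper(), "X"))
    return "".join(out)


def revcomp_oracle(dna: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(dna.upper()))


# ---------------------------------------------------------------------------
# exhaustive affine-gap alignment enumeration
#
# A gap of length L costs gap_open + gap_extend * L.  Alignments are move
# sequences; the recursion tracks the previous move so gap opening is
# charged once per run.  For each problem we return the optimal score and
# the set of identity percentages attained by optimal alignments.


def enumerate_global(a, b, score_fn, gap_open, gap_extend):
    best = [float("-inf")]
    identities: set[float] = set()
    first = gap_open + gap_extend

    def rec(i, j, score, state, matches, length):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
                identities.clear()
            if score == best[0]:
                identities.add(100.0 * matches / length if length else 0.0)
            return
        if i < len(a) and j < len(b):
            m = matches + (1 if a[i] == b[j] else 0)
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), "M", m, length + 1)
        if i < len(a):
            cost = gap_extend if state == "F" else first
            rec(i + 1, j, score - cost, "F", matches, length + 1)
        if j < len(b):
            cost = gap_extend if state == "E" else first
            rec(i, j + 1, score - cost, "E", matches, length + 1)

    rec(0, 0, 0.0, "M", 0, 0)
    return best[0], identities


def enumerate_local(a, b, score_fn, gap_open, gap_extend):
    """Best local alignment score over all start points and stop points."""
    best = [0.0]  # the empty alignment scores 0
    identities: set[float] = {0.0}
    first = gap_open + gap_extend

    def visit(score, matches, length):
        if score > best[0]:
            best[0] = score
            identities.clear()
        if score == best[0]:
            identities.add(100.0 * matches / length if length else 0.0)

    def rec(i, j, score, state, matches, length):
        visit(score, matches, length)
        if i < len(a) and j < len(b):
            m = matches + (1 if a[i] == b[j] else 0)
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), "M", m, length + 1)
        if i < len(a):
            cost = gap_extend if state == "F" else first
            rec(i + 1, j, score - cost, "F", matches, length + 1)
        if j < len(b):
            cost = gap_extend if state == "E" else first
            rec(i, j + 1, score - cost, "E", matches, length + 1)

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, 0.0, "M", 0, 0)
    return best[0], identities


# ---------------------------------------------------------------------------
# brute-force ORF enumeration: test every (start codon, stop codon) pair


def orf_oracle(contig: str, min_len_aa: int):
    """All first-ATG-per-segment ORFs as (start, end, strand, protein) tuples.

    For every frame on both strands, every ATG is paired with the nearest
    downstream in-frame stop; ORFs sharing a stop keep only the earliest
    ATG.  Coordinates are forward-strand, half-open, stop included.
    """
    contig = contig.upper()
    L = len(contig)
    per_stop: dict[tuple, tuple] = {}
    for strand in "+-":
        seq = contig if strand == "+" else revcomp_oracle(contig)
        for frame in range(3):
            codons = [
                (p, seq[p : p + 3]) for p in range(frame, L - 2, 3)
            ]
            stop_positions = [p for p, c in codons if c in STOPS_11]
            for p, c in codons:
                if c != "ATG":
                    continue
                downstream = [s for s in stop_positions if s >= p]
                if not downstream:
                    continue
                stop = downstream[0]
                protein = translate_oracle(seq[p:stop])
                if len(protein) < min_len_aa or "*" in protein:
                    continue
                key = (strand, frame, stop)
                if key not in per_stop or p < per_stop[key][0]:
                    per_stop[key] = (p, stop, protein)
    out = set()
    for (strand, _frame, _stop), (p, stop, protein) in per_stop.items():
        s, e = p, stop + 3
        if strand == "-":
            s, e = L - (stop + 3), L - p
        out.add((s, e, strand, protein))
    return out
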