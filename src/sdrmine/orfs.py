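"""Six-frame open-reading-frame discovery on assembled contigs.

Candidate coding regions are required to begin with an initiator methionine
(ATG) and to terminate at a stop codon inside the contig, and are reported
only if the encoded protein reaches a minimum length (default 230 residues,
the permissive end of the 230-250 band typical for the SDR family).

Coordinate conventions
----------------------
All coordinates are 0-based, half-open and given on the forward strand,
with the stop codon included in the interval, so
``end - start == 3 * (len(protein) + 1)``.  ``frame`` is the reading-frame
offset (0, 1, 2) on the ORF's own strand.

By default each stop-to-stop segment of a reading frame contributes at most
one ORF, anchored at the segment's first ATG; ``all_starts=True`` reports
every nested ATG variant instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable

from Bio.Data import CodonTable
from Bio.Seq import Seq

STOP_SYMBOL = "*"


@dataclass(frozen=True)
class OrfRecord:
    """A candidate coding region on a contig."""

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int  # 0..2 on its own strand
    protein: str  # without the stop symbol

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@lru_cache(maxsize=4)
def _codon_map(code: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP_SYMBOL
    return mapping


def translate(dna: str, code: int = 11) -> str:
    """Translate an in-frame DNA string; stops render as ``*``.

    Codons containing a base outside ACGT (e.g. N) translate to ``X``.
    The default genetic code is the bacterial/plastid table (11).
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    mapping = _codon_map(code)
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        out.append(mapping.get(codon, "X"))
    return "".join(out)


def revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def find_orfs(
    contig: str,
    min_len_aa: int = 230,
    code: int = 11,
    contig_id: str = "contig",
    all_starts: bool = False,
    max_x_fraction: float = 0.05,
) -> list[OrfRecord]:
    """Scan all six reading frames of a contig for complete ORFs.

    Only ATG initiates an ORF and a stop codon must lie within the contig.
    Proteins whose fraction of ambiguous residues (X) exceeds
    ``max_x_fraction`` are dropped.  Records are sorted by forward-strand
    coordinates and assigned sequential ids ``<contig_id>_orf<k>``.
    """
    contig = contig.upper()
    if len(contig) < 3:
        raise ValueError("contig must be at least 3 bp")
    mapping = _codon_map(code)
    length = len(contig)
    found: list[OrfRecord] = []
    for strand in "+-":
        seq = contig if strand == "+" else revcomp(contig)
        for frame in range(3):
            starts: list[int] = []  # ATG codon offsets since the last stop
            for pos in range(frame, length - 2, 3):
                codon = seq[pos : pos + 3]
                aa = mapping.get(codon, "X")
                if codon == "ATG":
                    starts.append(pos)
                if aa == STOP_SYMBOL:
                    chosen = starts if all_starts else starts[:1]
                    for s in chosen:
                        stop_end = pos + 3
                        protein = translate(seq[s:pos], code)
                        if len(protein) < min_len_aa:
                            continue
                        if protein.count("X") > max_x_fraction * len(protein):
                            continue
                        if strand == "+":
                            fwd_start, fwd_end = s, stop_end
                        else:
                            fwd_start, fwd_end = length - stop_end, length - s
                        found.append(
                            OrfRecord(
                                orf_id="",
                                contig_id=contig_id,
                                start=fwd_start,
                                end=fwd_end,
                                strand=strand,
                                frame=frame,
                                protein=protein,
                            )
                        )
                    starts = []
    found.sort(key=lambda r: (r.start, r.end, r.strand))
    return [
        replace(rec, orf_id=f"{contig_id}_orf{k + 1}") for k, rec in enumerate(found)
    ]


def find_orfs_multi(
    contigs: Iterable[tuple[str, str]],
    min_len_aa: int = 230,
    code: int = 11,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Run :func:`find_orfs` over (contig_id, sequence) pairs."""
    out: list[OrfRecord] = []
    for contig_id, seq in contigs:
        out.extend(
            find_orfs(
                seq,
                min_len_aa=min_len_aa,
                code=code,
                contig_id=contig_id,
                all_starts=all_starts,
            )
        )
    return out


def filter_orfs(
    orfs: Iterable[OrfRecord],
    min_len_aa: int = 0,
    max_len_aa: int | None = None,
) -> list[OrfRecord]:
    """Stable-ordered subset of ORFs whose protein length lies in the bounds."""
    if max_len_aa is not None and min_len_aa > max_len_aa:
        raise ValueError("min_len_aa must not exceed max_len_aa")
    out = []
    for rec in orfs:
        n = len(rec.protein)
        if n < min_len_aa:
            continue
        if max_len_aa is not None and n > max_len_aa:
            continue
        out.append(rec)
    return out


def write_protein_fasta(orfs: Iterable[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in orfs:
            header = f"{rec.orf_id}|{rec.contig_id}|{rec.start}|{rec.end}|{rec.strand}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.protein), 60):
                fh.write(rec.protein[i : i + 60] + "\n")


ORF_TABLE_COLUMNS = ["orf_id", "contig_id", "start", "end", "strand", "frame", "protein"]


def write_orf_table(orfs: Iterable[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ORF_TABLE_COLUMNS) + "\n")
        for r in orfs:
            fh.write(
                f"{r.orf_id}\t{r.contig_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.frame}\t{r.protein}\n"
            )


def read_orf_table(path) -> list[OrfRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ORF_TABLE_COLUMNS:
            raise ValueError(f"unexpected ORF table header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                OrfRecord(f[0], f[1], int(f[2]), int(f[3]), f[4], int(f[5]), f[6])
            )
    return out
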