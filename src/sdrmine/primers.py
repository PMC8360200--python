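"""Gibson-assembly primer design and in-silico cloning verification.

Each candidate gene is spliced into an expression vector so that its
initiator Met sits at the translation start site and its endogenous stop
codon is removed, letting translation read through into the vector-encoded
hexa-histidine tag.  Primers therefore carry two parts: a 3' annealing
portion taken from the gene (grown from ``anneal_min`` until the melting
temperature reaches the target, capped at ``anneal_max``) and a 5' adapter
identical to the vector sequence flanking the multiple-cloning-site span.
The amplicon is then assembled in silico and the construct validated:
correct junction homology, no in-frame stop between the insert ATG and the
tag, and a fusion protein ending ...HHHHHH.

The bundled mock vector is a synthetic miniature stand-in for a C-terminal
His-tag expression backbone (pET29a-style): a fixed backbone, a defined
MCS span, then a Gly-Ser-Gly linker, the His6 codons and a TAA stop.  A
real vector sequence can be supplied through :class:`VectorSpec` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orfs import revcomp, translate

HIS6_DNA = "CACCACCACCACCACCAC"
STOP_CODONS = ("TAA", "TAG", "TGA")


class AmplificationError(RuntimeError):
    """Primer annealing site absent or non-unique on the template."""


class AssemblyError(RuntimeError):
    """A Gibson junction lacks the required exact homology."""


@dataclass(frozen=True)
class VectorSpec:
    """A circular expression vector with a defined insertion span.

    The insert replaces ``[site_start, site_end)``; ``his6_frame_offset``
    is the number of codons between the insert's last codon and the first
    His codon (the linker length).  The His6 run must be present downstream
    of the site in that frame.
    """

    sequence: str
    site_start: int
    site_end: int
    his6_frame_offset: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.site_start < self.site_end <= len(self.sequence):
            raise ValueError("invalid insertion span")
        expected = self.site_end + 3 * self.his6_frame_offset
        if self.sequence[expected : expected + len(HIS6_DNA)] != HIS6_DNA:
            raise ValueError("His6 codon run not found at the declared frame offset")

    def upstream_homology(self, length: int) -> str:
        if self.site_start < length:
            raise ValueError("vector too short upstream of the site")
        return self.sequence[self.site_start - length : self.site_start]

    def downstream_homology(self, length: int) -> str:
        if self.site_end + length > len(self.sequence):
            raise ValueError("vector too short downstream of the site")
        return self.sequence[self.site_end : self.site_end + length]


def make_mock_vector() -> VectorSpec:
    """Deterministic synthetic mini-vector with MCS, GSG linker and His6 tag."""
    upstream = (
        "TTAACGCGACTATCGGCTCTAAGGTACCGATCGGAGCTCCACCGCGGTGGCGGCCGCTCT"
        "AGAACTAGTGGATCCCCCGGGCTGCAGGAATTCGATATCAAGCTTATCGATACCGTCGAC"
    )
    mcs = "CATATGGGATCCGAATTCGAGCTC"  # placeholder span the insert replaces
    linker = "GGCAGCGGC"  # Gly-Ser-Gly
    downstream = (
        linker + HIS6_DNA + "TAA"
        + "CTGCAGGCATGCAAGCTTGGCACTGGCCGTCGTTTTACAACGTCGTGACTGGGAAAACC"
    )
    seq = upstream + mcs + downstream
    return VectorSpec(
        sequence=seq,
        site_start=len(upstream),
        site_end=len(upstream) + len(mcs),
        his6_frame_offset=len(linker) // 3,
    )


def melting_temp(seq: str) -> float:
    """Deterministic Tm estimate in deg C.

    Wallace rule ``2(A+T) + 4(G+C)`` below 14 nt, otherwise the GC formula
    ``64.9 + 41 * (GC - 16.4) / length``.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence must be at least 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError("ambiguous bases not allowed in Tm calculation")
    gc = seq.count("G") + seq.count("C")
    at = len(seq) - gc
    if len(seq) < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


@dataclass(frozen=True)
class PrimerPair:
    """Adapter-bearing Gibson primers for one gene."""

    forward: str
    reverse: str
    anneal_len_f: int
    anneal_len_r: int
    tm_f: float
    tm_r: float
    adapter_len_f: int
    adapter_len_r: int

    @property
    def forward_anneal(self) -> str:
        return self.forward[self.adapter_len_f :]

    @property
    def reverse_anneal(self) -> str:
        return self.reverse[self.adapter_len_r :]


def _validate_cds(gene: str) -> None:
    gene = gene.upper()
    if len(gene) < 6 or (len(gene) - 3) % 3 != 0:
        raise ValueError("gene must be a whole-codon CDS including its stop")
    if not gene.startswith("ATG"):
        raise ValueError("gene must start with ATG")
    if gene[-3:] not in STOP_CODONS:
        raise ValueError("gene must end with a stop codon")
    body = translate(gene[:-3])
    if "*" in body:
        raise ValueError("gene has an internal in-frame stop codon")


def _grow_anneal(candidates: str, anneal_min: int, anneal_max: int, tm_target: float) -> str:
    length = anneal_min
    while length < min(anneal_max, len(candidates)) and melting_temp(candidates[:length]) < tm_target:
        length += 1
    return candidates[:length]


def design_gibson_primers(
    gene: str,
    vector: VectorSpec,
    adapter_len: int = 20,
    tm_target: float = 60.0,
    anneal_min: int = 18,
    anneal_max: int = 30,
) -> PrimerPair:
    """Design the forward/reverse Gibson primer pair for one CDS.

    The forward primer anneals from the gene's ATG; the reverse primer
    anneals to the 3' end of the gene *excluding the stop codon*, so the
    amplified insert reads through into the vector's His tag.  Adapters are
    ``adapter_len`` bases of vector homology on each side of the insertion
    span.
    """
    gene = gene.upper()
    _validate_cds(gene)
    if anneal_min < 8 or anneal_min > anneal_max:
        raise ValueError("require 8 <= anneal_min <= anneal_max")
    fwd_anneal = _grow_anneal(gene, anneal_min, anneal_max, tm_target)
    body_rc = revcomp(gene[:-3])  # stop codon excluded by construction
    rev_anneal = _grow_anneal(body_rc, anneal_min, anneal_max, tm_target)
    fwd_adapter = vector.upstream_homology(adapter_len)
    rev_adapter = revcomp(vector.downstream_homology(adapter_len))
    return PrimerPair(
        forward=fwd_adapter + fwd_anneal,
        reverse=rev_adapter + rev_anneal,
        anneal_len_f=len(fwd_anneal),
        anneal_len_r=len(rev_anneal),
        tm_f=melting_temp(fwd_anneal),
        tm_r=melting_temp(rev_anneal),
        adapter_len_f=len(fwd_adapter),
        adapter_len_r=len(rev_adapter),
    )


def _find_unique(haystack: str, needle: str, what: str) -> int:
    first = haystack.find(needle)
    if first < 0:
        raise AmplificationError(f"{what} annealing site not found on template")
    if haystack.find(needle, first + 1) >= 0:
        raise AmplificationError(f"{what} annealing site not unique on template")
    return first


def simulate_pcr(gene: str, pair: PrimerPair) -> str:
    """Amplify a template with an adapter-bearing primer pair.

    Both annealing portions must match the template exactly once; the
    amplicon is adapter + template span + adapter (reverse complemented on
    the reverse side).
    """
    gene = gene.upper()
    f_pos = _find_unique(gene, pair.forward_anneal, "forward")
    r_rc = revcomp(pair.reverse_anneal)
    r_pos = _find_unique(gene, r_rc, "reverse")
    r_end = r_pos + len(r_rc)
    if r_end <= f_pos:
        raise AmplificationError("primer sites in wrong orientation/order")
    fwd_adapter = pair.forward[: pair.adapter_len_f]
    rev_adapter = pair.reverse[: pair.adapter_len_r]
    return fwd_adapter + gene[f_pos:r_end] + revcomp(rev_adapter)


@dataclass(frozen=True)
class PlasmidAssembly:
    """A simulated circular construct plus its validation report."""

    sequence: str  # circular, given linearised from the vector origin
    insert_start: int
    insert_end: int
    fusion_protein: str
    valid: bool
    issues: tuple[str, ...]


def _shared_overlap_prefix(amplicon: str, vector: VectorSpec) -> int:
    best = 0
    for u in range(1, min(len(amplicon), vector.site_start) + 1):
        if amplicon[:u] == vector.sequence[vector.site_start - u : vector.site_start]:
            best = u
    return best


def _shared_overlap_suffix(amplicon: str, vector: VectorSpec) -> int:
    best = 0
    limit = min(len(amplicon), len(vector.sequence) - vector.site_end)
    for v in range(1, limit + 1):
        if amplicon[-v:] == vector.sequence[vector.site_end : vector.site_end + v]:
            best = v
    return best


def simulate_gibson(
    vector: VectorSpec,
    amplicon: str,
    overlap_min: int = 15,
) -> PlasmidAssembly:
    """Assemble an amplicon into the vector and validate the fusion.

    Raises :class:`AssemblyError` (naming the junction) when either end of
    the amplicon shares fewer than ``overlap_min`` exact bases with the
    vector arm.  Reading-frame problems (missing ATG, premature stop, tag
    out of frame) are reported as validation issues, not exceptions.
    """
    amplicon = amplicon.upper()
    u = _shared_overlap_prefix(amplicon, vector)
    if u < overlap_min:
        raise AssemblyError(f"upstream junction overlap {u} nt < {overlap_min} nt")
    v = _shared_overlap_suffix(amplicon, vector)
    if v < overlap_min:
        raise AssemblyError(f"downstream junction overlap {v} nt < {overlap_min} nt")
    insert = amplicon[u : len(amplicon) - v]
    assembled = vector.sequence[: vector.site_start] + insert + vector.sequence[vector.site_end :]
    issues: list[str] = []
    if not insert.startswith("ATG"):
        issues.append("insert does not begin with ATG at the translation start site")
    if len(insert) % 3 != 0:
        issues.append("insert length breaks the tag reading frame")
    # translate from the insert ATG through the vector until the first stop
    tail = assembled[vector.site_start :]
    tail = tail[: len(tail) - len(tail) % 3]
    fusion = translate(tail)
    stop_at = fusion.find("*")
    fusion_protein = fusion[:stop_at] if stop_at >= 0 else fusion
    expected_insert_aa = len(insert) // 3
    if 0 <= stop_at < expected_insert_aa:
        issues.append(f"premature in-frame stop at codon {stop_at} inside the insert")
    if stop_at < 0:
        issues.append("no stop codon downstream of the tag")
    if not fusion_protein.endswith("HHHHHH"):
        issues.append("fusion protein does not end with the His6 tag")
    return PlasmidAssembly(
        sequence=assembled,
        insert_start=vector.site_start,
        insert_end=vector.site_start + len(insert),
        fusion_protein=fusion_protein,
        valid=not issues,
        issues=tuple(issues),
    )


PRIMER_TABLE_COLUMNS = [
    "gene_id", "forward_seq", "reverse_seq", "anneal_len_f", "anneal_len_r",
    "tm_f", "tm_r",
]


def write_primer_table(rows: list[tuple[str, PrimerPair]], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PRIMER_TABLE_COLUMNS) + "\n")
        for gene_id, p in rows:
            fh.write(
                f"{gene_id}\t{p.forward}\t{p.reverse}\t{p.anneal_len_f}"
                f"\t{p.anneal_len_r}\t{p.tm_f:.1f}\t{p.tm_r:.1f}\n"
            )
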