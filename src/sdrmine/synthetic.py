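"""Synthetic metagenome generation with planted reductase genes.

Real mining starts from environmental contigs that cannot ship with a
package, so every downstream stage here is exercised against simulated
contigs carrying planted short-chain dehydrogenase/reductase (SDR) genes at
controlled protein identity to a set of seed enzymes, plus shuffled decoys,
with a ground-truth table recording exactly what was planted where.

The bundled ``SEED_PROTEINS`` are three synthetic stand-ins for R-selective
carbonyl-reductase seed sequences: 250-residue proteins sharing the family
hallmarks (N-terminal TGxxxGxG glycine-rich cofactor loop, Ser-Tyr-Lys
catalytic constellation with the supporting Asn) at 54-59% mutual identity.
They were generated once from a common synthetic ancestor and are frozen as
constants so every run sees the same family.

Divergent homologs are produced by substitution-only mutation, so a planted
gene keeps its template's length and residue coordinates; motif positions
can be protected from mutation so that motif QC has a guaranteed positive
set.  Planted coding sequences use the most-frequent-codon reverse
translation for Escherichia coli, start at ATG (the Met of the template)
and end in TAA, and an in-frame TAA guard is written immediately upstream
so that six-frame ORF calling recovers exactly the planted protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import ABSENT, scan_catalytic, scan_gly_motif
from .orfs import revcomp, translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Most-frequent codon per residue (E. coli usage); deterministic reverse
#: translation for DNA-level tests, not a fidelity claim.
CODON_USAGE: dict[str, str] = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

STOP_CODON = "TAA"

#: Synthetic stand-ins for the three R-selective carbonyl reductase seeds.
SEED_PROTEINS: dict[str, str] = {
    "seedR1": (
        "MSLLANNTGASRGIGSQGEVGAIFFLDDVLILDQRVDYRLTVYLSFYDDGIALVLMTDRA"
        "RAFKPKKLFNVQKNAMPWRRNQAADIISIATIKVMFRHKARDVGGNEGASNCIKADHDIT"
        "FVLELEIEDELGIDKATLSNLRLTKWNYALGYRENKAISNWTYMACRMVQYGILILCHHF"
        "SLTCTGAKKQMLFLKSGQPDQCIEAGVSRAELEAKVSHNQRDNGSILAVWRRITFMYVNV"
        "VFKRPMVITN"
    ),
    "seedR2": (
        "MEPYANLTGASRGIGTVNEDGCSDSLDDVLIHDQRVTYNERVGRSFYDDGQALEGMTDRS"
        "SFFKPEKLNNVVKGAMPRRRPSAQDMYSITTIKVEQTAKAADVEGNEGACNCIEADIDIE"
        "FVLELEKEDELPADKTTLSALHLPKWNPALNYRENKAIDNLTSGKNRVDGNACCILVIAN"
        "SLTVAQAKKQDLYLKTGQPDEEITKGNVVAAQERWDCHNQRDNTSNLLVPAIIGFVIVNA"
        "VFVRPMVIKN"
    ),
    "seedR3": (
        "MECIANLTGASRGIGRCHEDGAIDFNDDVLFPDGRVYYRLTRALKPYDDGIPLVGMTDQH"
        "TAYKPCMLFSVYVGAMRFTRNFAADIRTYTVIKVGQRVKARDVFGEEGACNCIKADPAIC"
        "FVLVLEMEMELHRSDAYLSPLWISKWNYALGYRENKADVNIRSGANHLWGYAILICVIAS"
        "SLTVTGAKKQPLFLKKGQPDEEITMENLVAELEIKVSDLMYDNGSNLLWNRKHTFMIVNA"
        "QFKIGMVITK"
    ),
}


class InfeasibleTargetError(ValueError):
    """Requested identity cannot be reached with motif sites protected."""


class PlacementError(RuntimeError):
    """No contig can host a planted gene without overlap."""


@dataclass(frozen=True)
class GeneTemplate:
    """A parent protein from which divergent homologs are minted.

    With ``keep_motifs`` set, the glycine-rich TGxxxGxG window, the
    catalytic Ser / Y-x-x-x-K span / supporting Asn and the initiator Met
    are shielded from mutation, so a planted homolog at any identity still
    carries the family hallmarks; the template must then actually contain
    the glycine motif and a complete catalytic triad.
    """

    id: str
    protein: str
    keep_motifs: bool = True

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError("template protein must be non-empty")
        bad = set(self.protein) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues in template: {sorted(bad)}")
        if self.keep_motifs:
            if scan_gly_motif(self.protein) == ABSENT:
                raise ValueError(f"template {self.id}: TGxxxGxG motif not found")
            if scan_catalytic(self.protein)[0] == ABSENT:
                raise ValueError(f"template {self.id}: catalytic Ser-Tyr-Lys not found")

    def protected_positions(self) -> frozenset[int]:
        """Positions shielded from mutation (just the Met when keep_motifs unset)."""
        if not self.keep_motifs:
            return frozenset({0} if self.protein[0] == "M" else set())
        pos: set[int] = {0}
        g = scan_gly_motif(self.protein)
        pos.update(range(g, g + 8))
        ser, tyr, lys, asn = scan_catalytic(self.protein)
        pos.update(range(tyr, lys + 1))
        pos.add(ser)
        if asn != ABSENT:
            pos.add(asn)
        return frozenset(pos)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted gene (family member or decoy)."""

    contig_id: str
    gene_id: str
    start: int  # 0-based half-open, forward strand, CDS incl. stop codon
    end: int
    strand: str
    planted_identity: float  # percent vs the parent template (0 for decoys)
    is_family: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("planted CDS length must be divisible by 3")


@dataclass
class ContigSet:
    """Named DNA sequences, optionally with the planting truth table."""

    sequences: dict[str, str]
    truth: list[TruthRecord] = field(default_factory=list)

    def items(self):
        return self.sequences.items()

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "ContigSet":
        seqs: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        seqs[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
        if name is not None:
            seqs[name] = "".join(chunks)
        return cls(sequences=seqs)

    def write_truth_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "contig_id\tgene_id\tstart\tend\tstrand\tplanted_identity\tis_family\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.contig_id}\t{t.gene_id}\t{t.start}\t{t.end}\t{t.strand}"
                    f"\t{t.planted_identity:.1f}\t{int(t.is_family)}\n"
                )


def default_templates() -> list[GeneTemplate]:
    """The three bundled seed proteins as motif-protected templates."""
    return [GeneTemplate(name, prot, keep_motifs=True) for name, prot in SEED_PROTEINS.items()]


def generate_contigs(
    n: int,
    length_mean: float = 1500.0,
    length_sd: float = 300.0,
    gc: float = 0.5,
    seed: int = 0,
) -> ContigSet:
    """Draw ``n`` random contigs with i.i.d. bases at the requested GC.

    Lengths are normal(length_mean, length_sd) rounded and truncated at
    300 bp.  Identical arguments and seed give identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if length_mean < 300:
        raise ValueError("length_mean must be >= 300")
    if length_sd < 0:
        raise ValueError("length_sd must be >= 0")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    width = max(5, len(str(n)))
    for i in range(n):
        length = max(300, int(round(rng.normal(length_mean, length_sd)))) if length_sd else int(length_mean)
        seq = "".join(rng.choice(bases, size=length, p=probs))
        seqs[f"contig_{i + 1:0{width}d}"] = seq
    return ContigSet(sequences=seqs)


def mutate_protein(template: GeneTemplate, target_identity: float, seed: int = 0) -> str:
    """Mint a homolog at a requested percent identity to its template.

    Mutation is substitution-only at positions sampled without replacement
    outside the protected set, so the output has the template's length and
    a positional identity equal to the target up to rounding; the global-
    alignment identity measured downstream agrees within about two points.
    """
    if not 10.0 <= target_identity <= 100.0:
        raise ValueError("target_identity must lie in [10, 100]")
    protein = template.protein
    length = len(protein)
    protected = template.protected_positions()
    n_sub = int(round(length * (1.0 - target_identity / 100.0)))
    free = [i for i in range(length) if i not in protected]
    if n_sub > len(free):
        raise InfeasibleTargetError(
            f"target {target_identity}% needs {n_sub} substitutions but only "
            f"{len(free)} unprotected positions exist"
        )
    rng = np.random.default_rng(seed)
    sites = rng.choice(len(free), size=n_sub, replace=False)
    out = list(protein)
    for idx in sites:
        i = free[int(idx)]
        alternatives = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def shuffle_decoy(template: GeneTemplate, seed: int = 0) -> str:
    """Fisher-Yates shuffle of the template body (initiator Met kept).

    Same residue composition, destroyed order: a composition-only
    classifier cannot tell it from family, an alignment-based one can.
    """
    rng = np.random.default_rng(seed)
    body = list(template.protein[1:])
    rng.shuffle(body)
    return template.protein[0] + "".join(body)


def reverse_translate(protein: str, usage: dict[str, str] | None = None) -> str:
    table = usage or CODON_USAGE
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"no codon for residue {exc.args[0]!r}") from exc


def plant_genes(
    contigs: ContigSet,
    templates: list[GeneTemplate],
    identities: list[float],
    strand_policy: str = "both",
    code: int = 11,
    seed: int = 0,
    n_decoys: int = 0,
    usage: dict[str, str] | None = None,
) -> tuple[ContigSet, list[TruthRecord]]:
    """Write divergence-controlled family genes and shuffled decoys into contigs.

    Each entry of ``identities`` plants one gene derived from the templates
    in round-robin order; ``n_decoys`` additional shuffled-template ORFs are
    planted with ``is_family=False``.  Every insert is ATG..TAA preceded by
    an in-frame TAA guard, placed uniformly at random on a strand allowed by
    ``strand_policy`` ('both' or 'forward'), never overlapping another
    insert.  Returns the modified contigs and the truth table (also stored
    on the returned ContigSet).
    """
    if strand_policy not in ("both", "forward"):
        raise ValueError("strand_policy must be 'both' or 'forward'")
    if templates and not all(isinstance(t, GeneTemplate) for t in templates):
        raise TypeError("templates must be GeneTemplate instances")
    rng = np.random.default_rng(seed)
    seqs = {k: list(v) for k, v in contigs.sequences.items()}
    occupied: dict[str, list[tuple[int, int]]] = {k: [] for k in seqs}
    truth: list[TruthRecord] = []

    jobs: list[tuple[str, str, float, bool]] = []
    for g, ident in enumerate(identities):
        tpl = templates[g % len(templates)]
        protein = mutate_protein(tpl, ident, seed=int(rng.integers(2**31)))
        jobs.append((f"plant_{g + 1:03d}_{tpl.id}", protein, float(ident), True))
    for d in range(n_decoys):
        tpl = templates[d % len(templates)] if templates else None
        if tpl is None:
            break
        protein = shuffle_decoy(tpl, seed=int(rng.integers(2**31)))
        jobs.append((f"decoy_{d + 1:03d}_{tpl.id}", protein, 0.0, False))

    for gene_id, protein, ident, is_family in jobs:
        cds = reverse_translate(protein, usage) + STOP_CODON
        insert = STOP_CODON + cds  # leading in-frame guard stop
        placed = False
        for _ in range(200):
            cid = list(seqs)[int(rng.integers(len(seqs)))]
            room = len(seqs[cid]) - len(insert)
            if room < 0:
                continue
            offset = int(rng.integers(room + 1))
            span = (offset, offset + len(insert))
            if any(not (span[1] <= a or span[0] >= b) for a, b in occupied[cid]):
                continue
            strand = "+" if strand_policy == "forward" else ("+", "-")[int(rng.integers(2))]
            payload = insert if strand == "+" else revcomp(insert)
            seqs[cid][span[0] : span[1]] = list(payload)
            occupied[cid].append(span)
            if strand == "+":
                start, end = offset + 3, offset + len(insert)
            else:
                start, end = offset, offset + len(cds)
            truth.append(
                TruthRecord(cid, gene_id, start, end, strand, ident, is_family)
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place {gene_id}: contigs too crowded/short")

    out = ContigSet(sequences={k: "".join(v) for k, v in seqs.items()}, truth=truth)
    # construction invariant: each recorded slice translates back to its protein
    for rec, (_, protein, _, _) in zip(truth, jobs):
        dna = out.sequences[rec.contig_id][rec.start : rec.end]
        if rec.strand == "-":
            dna = revcomp(dna)
        assert translate(dna, code) == protein + "*"
    return out, truth
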