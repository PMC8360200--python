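"""Sequence hallmarks of the SDR family: glycine motif and catalytic residues.

Classical SDRs carry an N-terminal glycine-rich loop (TGxxxGxG) that binds
the NAD(P)H cofactor, and a catalytic Ser-Tyr-Lys constellation in which
the Lys sits exactly four residues after the Tyr (the Y-x-x-x-K geometry);
an upstream Asn is often counted as a fourth, supporting residue (the
"tetrad").  The scanners below locate these features by pattern and
spacing.  The Y-x-x-x-K spacing is fixed - it is the family's anchor -
while the Ser and Asn windows are configurable, since their exact offsets
vary across the family.

Absence of the Asn lowers only the tetrad flag; it never rejects a
candidate on its own.  All reported positions are 0-based indices into the
unmodified input protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

ABSENT = -1


@dataclass(frozen=True)
class MotifReport:
    """Motif scan outcome for one protein; positions are -1 when absent."""

    orf_id: str
    gly_pos: int
    ser_pos: int
    tyr_pos: int
    lys_pos: int
    asn_pos: int
    gly_pass: bool
    tetrad_pass: bool

    @property
    def triad_pass(self) -> bool:
        return self.ser_pos != ABSENT and self.tyr_pos != ABSENT and self.lys_pos != ABSENT


def scan_gly_motif(protein: str, window: tuple[int, int] = (0, 60)) -> int:
    """Leftmost TGxxxGxG match whose T lies inside the N-terminal window.

    Returns the 0-based position of the T, or -1 when absent.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    lo, hi = window
    for i in range(max(0, lo), min(hi, len(protein) - 7)):
        if (
            protein[i] == "T"
            and protein[i + 1] == "G"
            and protein[i + 5] == "G"
            and protein[i + 7] == "G"
        ):
            return i
    return ABSENT


def scan_catalytic(
    protein: str,
    ser_gap: tuple[int, int] = (10, 25),
    asn_gap: tuple[int, int] = (20, 60),
) -> tuple[int, int, int, int]:
    """Locate the Ser-Tyr-Lys constellation (plus supporting Asn).

    Every Tyr with a Lys exactly 4 positions downstream is considered in
    order; the first such pair that also has a Ser ``ser_gap`` residues
    upstream of the Tyr is accepted (the nearest qualifying Ser is
    reported).  A supporting Asn is then sought ``asn_gap`` residues
    upstream of the Ser.  Returns (ser, tyr, lys, asn) positions with -1
    for any absent residue; without a qualifying Ser the triad is absent
    even if a Y-x-x-x-K pair exists.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    for y in range(len(protein) - 4):
        if protein[y] != "Y" or protein[y + 4] != "K":
            continue
        ser = ABSENT
        for gap in range(ser_gap[0], ser_gap[1] + 1):
            pos = y - gap
            if pos >= 0 and protein[pos] == "S":
                ser = pos
                break  # nearest Ser upstream of this Tyr
        if ser == ABSENT:
            continue
        asn = ABSENT
        for gap in range(asn_gap[0], asn_gap[1] + 1):
            pos = ser - gap
            if pos >= 0 and protein[pos] == "N":
                asn = pos
                break
        return ser, y, y + 4, asn
    return ABSENT, ABSENT, ABSENT, ABSENT


def scan_protein(
    orf_id: str,
    protein: str,
    gly_window: tuple[int, int] = (0, 60),
    ser_gap: tuple[int, int] = (10, 25),
    asn_gap: tuple[int, int] = (20, 60),
) -> MotifReport:
    gly = scan_gly_motif(protein, gly_window)
    ser, tyr, lys, asn = scan_catalytic(protein, ser_gap, asn_gap)
    return MotifReport(
        orf_id=orf_id,
        gly_pos=gly,
        ser_pos=ser,
        tyr_pos=tyr,
        lys_pos=lys,
        asn_pos=asn,
        gly_pass=gly != ABSENT,
        tetrad_pass=ser != ABSENT and asn != ABSENT,
    )


def qc_table(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    **kwargs,
) -> list[MotifReport]:
    """One report per input protein, input order preserved."""
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    return [scan_protein(name, seq, **kwargs) for name, seq in items]


QC_TABLE_COLUMNS = [
    "orf_id", "gly_pos", "ser_pos", "tyr_pos", "lys_pos", "asn_pos",
    "gly_pass", "tetrad_pass",
]


def write_qc_table(reports: Iterable[MotifReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(QC_TABLE_COLUMNS) + "\n")
        for r in reports:
            fh.write(
                f"{r.orf_id}\t{r.gly_pos}\t{r.ser_pos}\t{r.tyr_pos}\t{r.lys_pos}"
                f"\t{r.asn_pos}\t{int(r.gly_pass)}\t{int(r.tetrad_pass)}\n"
            )
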