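"""Pairwise global identity and greedy dereplication of family hits.

Percent identity is computed from a Needleman-Wunsch global alignment
(EMBOSS-needle-style penalties) with the full alignment length, gap columns
included, as the denominator; the shorter-sequence denominator is available
by flag since conventions differ between tools.  Hits are then clustered
greedily in CD-HIT style - longest sequence first, each sequence joining
the first cluster whose representative it matches at or above the
threshold - and one representative per cluster is carried forward as the
non-redundant panel.

The default threshold is 99%: a pair of family members at 98% identity is
deliberately kept as two distinct panel entries, so the collapse point must
sit above 98.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .align import needleman_wunsch


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over named proteins."""

    ids: tuple[str, ...]
    values: np.ndarray  # shape (n, n), percent

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values shape must match number of ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be 100")
        if self.values.min() < 0 or self.values.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def off_diagonal(self) -> np.ndarray:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]

    def reorder(self, order: Iterable[str]) -> "IdentityMatrix":
        order = list(order)
        idx = [self.ids.index(i) for i in order]
        return IdentityMatrix(tuple(order), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{v:.1f}" for v in self.values[i])
                fh.write(f"{name}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "IdentityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        values = np.array([[float(v) for v in r[1:]] for r in rows])
        return cls(tuple(header), values)


@dataclass(frozen=True)
class Cluster:
    """One dereplication cluster; the representative is a member."""

    members: tuple[str, ...]
    representative: str
    threshold_used: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


def global_identity(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
) -> float:
    """Percent identity from an optimal global alignment.

    ``denominator`` selects the convention: "alignment" (full alignment
    length including gap columns; default) or "shorter" (length of the
    shorter input sequence).
    """
    res = needleman_wunsch(a, b, matrix, gap_open, gap_extend)
    if denominator == "alignment":
        return res.identity
    if denominator == "shorter":
        matches = sum(
            1 for x, y in zip(res.aligned_a, res.aligned_b) if x == y and x != "-"
        )
        return 100.0 * matches / min(len(a), len(b))
    raise ValueError("denominator must be 'alignment' or 'shorter'")


def identity_matrix(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    **kwargs,
) -> IdentityMatrix:
    """All-vs-all global identity; each pair computed once and mirrored."""
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    ids = [name for name, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(items)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(items[i][1], items[j][1], **kwargs)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(tuple(ids), values)


def cluster_greedy(
    matrix: IdentityMatrix,
    threshold: float = 99.0,
    lengths: Mapping[str, int] | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering at a percent-identity threshold.

    Ids are processed longest-sequence-first (ties broken lexicographically;
    without ``lengths`` all sequences rank equal, i.e. pure lexicographic
    order).  Each id joins the first existing cluster whose representative
    it matches at >= threshold, otherwise it founds a new cluster and
    becomes its representative.  The clusters partition the input ids.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    order = sorted(
        matrix.ids, key=lambda i: (-(lengths[i] if lengths else 0), i)
    )
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for name in order:
        for rep in reps:
            if matrix.get(name, rep) >= threshold:
                members[rep].append(name)
                break
        else:
            reps.append(name)
            members[name] = [name]
    return [
        Cluster(tuple(members[rep]), rep, float(threshold)) for rep in reps
    ]


def pick_representative(
    cluster: Cluster,
    lengths: Mapping[str, int] | None = None,
    policy: str = "longest",
) -> str:
    """Deterministic representative choice: longest member, ties by id."""
    if policy == "first":
        return cluster.members[0]
    if policy != "longest":
        raise ValueError("policy must be 'longest' or 'first'")
    return min(
        cluster.members, key=lambda m: (-(lengths[m] if lengths else 0), m)
    )


def write_cluster_table(clusters: Iterable[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tmember\n")
        for k, c in enumerate(clusters, start=1):
            for m in c.members:
                fh.write(f"cluster_{k}\t{c.representative}\t{m}\n")
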