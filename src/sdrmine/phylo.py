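"""Comparative view of the candidate panel: NJ tree, clades, heat-map order.

Distances are simply ``1 - identity/100``: the display is a similarity
summary, not an evolutionary-rate estimate, so no Poisson or Kimura
correction is applied by default (one is available by flag).  Trees are
built with the Saitou-Nei neighbor-joining algorithm, which reconstructs
additive distance matrices exactly; negative branch lengths - an NJ
artefact on non-additive inputs - are clamped to zero with the deficit
moved to the sister branch, the common practice.

The tree is serialised to Newick, cut into ``k`` clades by removing the
longest branches, and used to derive a deterministic leaf ordering for
heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .derep import IdentityMatrix


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def preorder(self) -> list["TreeNode"]:
        out = [self]
        for child in self.children:
            out.extend(child.preorder())
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be 0")


def distance_from_identity(m: IdentityMatrix, correction: str = "none") -> DistanceMatrix:
    """d(i,j) = 1 - identity/100, optionally Poisson-corrected (-ln p)."""
    p = 1.0 - m.values / 100.0
    np.fill_diagonal(p, 0.0)
    if correction == "poisson":
        with np.errstate(divide="ignore"):
            p = -np.log(np.clip(1.0 - p, 1e-12, None))
        np.fill_diagonal(p, 0.0)
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'poisson'")
    return DistanceMatrix(m.ids, p)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    At each step the pair minimising the Q-criterion is joined (ties broken
    by the smallest (i, j) index pair); branch lengths come from the
    standard two-point formulas with negatives clamped to zero and the
    deficit moved to the sister branch.  The returned tree is unrooted with
    a trifurcating root node.  Additive matrices are reproduced exactly by
    leaf-to-leaf path lengths.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    dist = d.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] < best[0]:
                    best = (q[ai, aj], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = dist[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        new_d = 0.5 * (dist[i, active] + dist[j, active] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        k = dist.shape[0] - 1
        dist[k, active] = new_d
        dist[active, k] = new_d
        dist[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]
    # join the last three under a trifurcating root with closed-form lengths
    i, j, k = active
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = max(0.0, 0.5 * (dist[i, j] + dist[i, k] - dist[j, k]))
    nodes[j].length = max(0.0, 0.5 * (dist[i, j] + dist[j, k] - dist[i, k]))
    nodes[k].length = max(0.0, 0.5 * (dist[i, k] + dist[j, k] - dist[i, j]))
    return root


def _newick_label(name: str) -> str:
    if any(ch in name for ch in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: TreeNode, precision: int = 5) -> str:
    """Serialise to Newick with branch lengths; labels quoted when needed."""

    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf():
            body = _newick_label(node.name or "")
        else:
            body = "(" + ",".join(render(c, True) for c in node.children) + ")"
            if node.name:
                body += _newick_label(node.name)
        if with_length:
            body += f":{node.length:.{precision}f}"
        return body

    return render(tree, False) + ";"


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    names = sorted(tree.leaf_names())
    index = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    values = np.zeros((n, n))

    def below(node: TreeNode) -> dict[str, float]:
        """depth of each descendant leaf below node, accumulating pairs."""
        if node.is_leaf():
            return {node.name: 0.0}
        depths: dict[str, float] = {}
        child_maps = []
        for child in node.children:
            sub = {nm: depth + child.length for nm, depth in below(child).items()}
            child_maps.append(sub)
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for nm1, d1 in child_maps[a].items():
                    for nm2, d2 in child_maps[b].items():
                        values[index[nm1], index[nm2]] = d1 + d2
                        values[index[nm2], index[nm1]] = d1 + d2
        for sub in child_maps:
            depths.update(sub)
        return depths

    below(tree)
    return DistanceMatrix(tuple(names), values)


def topology_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as smaller leaf sets) - topology fingerprint."""
    all_leaves = frozenset(tree.leaf_names())
    splits: set[frozenset[str]] = set()
    for node in tree.preorder():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) > 1 and len(other) > 1:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def assign_clades(tree: TreeNode, k: int = 3) -> dict[str, str]:
    """Partition the leaves into ``k`` clades by cutting the longest branches.

    Internal branches are cut longest-first (ties by preorder position);
    leaf branches are considered only when the internal branches cannot
    yield ``k`` groups (e.g. ``k`` close to the number of leaves).  A cut
    is kept only if it increases the number of leaf-bearing groups, and
    cutting proceeds until ``k`` groups exist.  Labels ``clade_1..k`` are
    assigned in leaf traversal order, so the result is stable.
    """
    leaves = tree.leaf_names()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(leaves):
        raise ValueError("k cannot exceed the number of leaves")
    order = tree.preorder()
    pos = {id(node): i for i, node in enumerate(order)}
    candidates = sorted(
        (node for node in order if node is not tree),
        key=lambda nd: (nd.is_leaf(), -nd.length, pos[id(nd)]),
    )
    parent_of = {}
    for node in order:
        for child in node.children:
            parent_of[id(child)] = node

    cut: set[int] = set()

    def group_of(leaf: TreeNode) -> int:
        """id of the topmost uncut ancestor component root for this leaf."""
        node = leaf
        while id(node) in parent_of and id(node) not in cut:
            node = parent_of[id(node)]
        return id(node)

    def n_groups() -> int:
        return len({group_of(leaf) for leaf in tree.leaves()})

    ci = 0
    while n_groups() < k and ci < len(candidates):
        node = candidates[ci]
        ci += 1
        before = n_groups()
        cut.add(id(node))
        if n_groups() <= before:
            cut.remove(id(node))
    labels: dict[str, str] = {}
    group_label: dict[int, str] = {}
    for leaf in tree.leaves():
        g = group_of(leaf)
        if g not in group_label:
            group_label[g] = f"clade_{len(group_label) + 1}"
        labels[leaf.name] = group_label[g]
    return labels


def heatmap_order(tree: TreeNode) -> list[str]:
    """Leaf order for heat-map display.

    Depth-first traversal with children visited smaller-subtree-first,
    ties broken by the lexicographically smallest leaf label in the
    subtree; the result is a permutation of the leaf ids.
    """

    def key(node: TreeNode) -> tuple[int, str]:
        names = node.leaf_names()
        return (len(names), min(names))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf():
            return [node.name]
        out: list[str] = []
        for child in sorted(node.children, key=key):
            out.extend(walk(child))
        return out

    return walk(tree)


def write_clade_table(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclade\n")
        for name, clade in labels.items():
            fh.write(f"{name}\t{clade}\n")
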