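"""Neighbor joining, Newick export, clades and heat-map ordering."""

import io

import numpy as np
import pytest

from sdrmine.derep import IdentityMatrix, identity_matrix
from sdrmine.phylo import (
    DistanceMatrix,
    TreeNode,
    assign_clades,
    distance_from_identity,
    heatmap_order,
    neighbor_joining,
    to_newick,
    topology_splits,
    tree_distances,
)
from sdrmine.synthetic import default_templates, mutate_protein


def random_additive_instance(rng, n_taxa: int):
    """A random binary tree and its exact leaf-to-leaf distance matrix.

    Distances are computed here by walking ancestor chains, independently
    of the package's tree utilities.
    """
    names = [f"t{i}" for i in range(n_taxa)]
    lengths: dict[str, float] = {}
    parents: dict[str, str] = {}
    counter = [0]

    def join(x, y):
        counter[0] += 1
        new = f"internal{counter[0]}"
        for child in (x, y):
            parents[child] = new
            lengths[child] = float(rng.uniform(0.05, 1.0))
        return new

    roots = list(names)
    while len(roots) > 2:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        new = join(roots[i], roots[j])
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [new]
    join(roots[0], roots[1])

    dist = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            chain_a: dict[str, float] = {}
            node, acc = names[a], 0.0
            while node in parents:
                acc += lengths[node]
                node = parents[node]
                chain_a[node] = acc
            node, acc, d = names[b], 0.0, None
            while node in parents:
                acc += lengths[node]
                node = parents[node]
                if node in chain_a:
                    d = acc + chain_a[node]
                    break
            dist[a, b] = dist[b, a] = d
    return names, dist


class TestDistanceFromIdentity:
    def test_arithmetic(self):
        m = IdentityMatrix(
            ("a", "b"), np.array([[100.0, 11.0], [11.0, 100.0]])
        )
        d = distance_from_identity(m)
        assert d.values[0, 1] == pytest.approx(0.89)
        assert d.values[0, 0] == 0.0
        assert np.allclose(d.values, d.values.T)

    def test_identity_100_gives_zero(self):
        m = IdentityMatrix(("a", "b"), np.array([[100.0, 100.0], [100.0, 100.0]]))
        assert distance_from_identity(m).values[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.6, 0.8, 0.4
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["B"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["C"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_recovers_random_additive_trees(self, rng):
        for trial in range(10):
            names, dist = random_additive_instance(rng, int(rng.integers(5, 11)))
            tree = neighbor_joining(DistanceMatrix(tuple(names), dist))
            recon = tree_distances(tree)
            order = [recon.ids.index(n) for n in names]
            assert np.max(np.abs(recon.values[np.ix_(order, order)] - dist)) < 1e-9

    def test_ultrametric_pairs_are_sisters(self):
        # two tight pairs (A,B) and (C,D), far apart
        names = ("A", "B", "C", "D")
        dist = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(names, dist))
        splits = topology_splits(tree)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(5):
            n = 6
            arr = rng.uniform(0.1, 1.0, size=(n, n))
            arr = (arr + arr.T) / 2
            np.fill_diagonal(arr, 0.0)
            tree = neighbor_joining(
                DistanceMatrix(tuple(f"x{i}" for i in range(n)), arr)
            )
            assert all(node.length >= 0 for node in tree.preorder() if node is not tree)


class TestNewick:
    def test_two_leaf_star(self):
        root = TreeNode(
            children=[TreeNode("A", 0.1), TreeNode("B", 0.2)]
        )
        assert to_newick(root) == "(A:0.10000,B:0.20000);"

    def test_round_trip_through_independent_parser(self, rng):
        import dendropy

        names, dist = random_additive_instance(rng, 10)
        tree = neighbor_joining(DistanceMatrix(tuple(names), dist))
        newick = to_newick(tree, precision=9)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    dist[i, j], abs=1e-6
                )

    def test_labels_with_spaces_are_quoted(self):
        root = TreeNode(children=[TreeNode("sp one", 0.1), TreeNode("B", 0.2)])
        assert to_newick(root).startswith("('sp one'")


@pytest.fixture(scope="module")
def two_family_matrix():
    """Six proteins from two well-separated families (three members each)."""
    tpls = default_templates()
    panel = {}
    for i, t in enumerate((92.0, 85.0, 78.0)):
        panel[f"famA_{i}"] = mutate_protein(tpls[0], t, seed=40 + i)
    for i, t in enumerate((90.0, 83.0, 76.0)):
        panel[f"famB_{i}"] = mutate_protein(tpls[1], t, seed=50 + i)
    return identity_matrix(panel)


class TestCladesAndOrdering:

    def test_k1_and_kn_edge_cases(self, two_family_matrix):
        tree = neighbor_joining(distance_from_identity(two_family_matrix))
        n = len(two_family_matrix.ids)
        assert len(set(assign_clades(tree, 1).values())) == 1
        assert len(set(assign_clades(tree, n).values())) == n

    def test_two_planted_families_split_into_two_clades(self, two_family_matrix):
        tree = neighbor_joining(distance_from_identity(two_family_matrix))
        clades = assign_clades(tree, 2)
        groups = {}
        for name, clade in clades.items():
            groups.setdefault(clade, set()).add(name.split("_")[0])
        assert sorted(map(tuple, groups.values())) == [("famA",), ("famB",)]

    def test_family_members_contiguous_in_heatmap_order(self, two_family_matrix):
        tree = neighbor_joining(distance_from_identity(two_family_matrix))
        order = heatmap_order(tree)
        families = [name.split("_")[0] for name in order]
        assert sorted(order) == sorted(two_family_matrix.ids)
        # runs of equal family labels: exactly two blocks
        blocks = 1 + sum(1 for a, b in zip(families, families[1:]) if a != b)
        assert blocks == 2

    def test_clades_invariant_to_input_order(self, two_family_matrix, rng):
        perm = list(two_family_matrix.ids)
        rng.shuffle(perm)
        shuffled = two_family_matrix.reorder(perm)
        t1 = neighbor_joining(distance_from_identity(two_family_matrix))
        t2 = neighbor_joining(distance_from_identity(shuffled))
        c1 = assign_clades(t1, 2)
        c2 = assign_clades(t2, 2)
        groups1 = {frozenset(k for k, v in c1.items() if v == lab) for lab in set(c1.values())}
        groups2 = {frozenset(k for k, v in c2.items() if v == lab) for lab in set(c2.values())}
        assert groups1 == groups2

    def test_invalid_k_rejected(self, two_family_matrix):
        tree = neighbor_joining(distance_from_identity(two_family_matrix))
        with pytest.raises(ValueError):
            assign_clades(tree, 0)
        with pytest.raises(ValueError):
            assign_clades(tree, 99)
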