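"""tree_infer: JC distances, neighbor joining, bootstrap, Newick import."""

import math
import random

import numpy as np
import pytest

from ceseek.tree_infer import (Alignment, SATURATION_CEILING, bootstrap_support,
                               jc_distance, jc_distance_matrix, nj, read_newick)

from conftest import topology_bipartitions


class TestJcDistance:
    def test_identical_sequences_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_03(self):
        a = "A" * 100
        b = "C" * 30 + "A" * 70
        assert jc_distance(a, b) == pytest.approx(-0.75 * math.log(0.6))

    def test_gap_sites_excluded(self):
        assert jc_distance("AC-T", "ACGT") == 0.0

    def test_saturation_ceiling(self):
        assert jc_distance("A" * 10, "C" * 10) == SATURATION_CEILING

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            jc_distance("--N", "AC-")

    def test_symmetry(self):
        a, b = "ACGTTGCAAC", "ACTTTGCTAC"
        assert jc_distance(a, b) == jc_distance(b, a)


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        stree = nj(D, ["A", "B", "C"])
        lengths = {child.taxon.label: child.edge.length
                   for child in stree.tree.seed_node.child_nodes()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # ((A,B),(C,D)) with all five branches of length 1
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
                     dtype=float)
        stree = nj(D, labels)
        assert topology_bipartitions(stree) == {frozenset({"C", "D"})}

    def test_least_squares_confirms_best_quartet(self):
        # independent check: AB|CD minimises the least-squares fit among the
        # three quartet topologies for the additive matrix above
        D = {("A", "B"): 2, ("A", "C"): 3, ("A", "D"): 3,
             ("B", "C"): 3, ("B", "D"): 3, ("C", "D"): 2}

        def lsq(pair1, pair2):
            # for quartet (x,y)|(u,v): internal = (dxu+dyv+dxv+dyu)/4 - (dxy+duv)/2
            (x, y), (u, v) = pair1, pair2
            d = lambda a, b: D[tuple(sorted((a, b)))]
            internal = (d(x, u) + d(y, v) + d(x, v) + d(y, u)) / 4 - (d(x, y) + d(u, v)) / 2
            return internal

        fits = {"AB|CD": lsq(("A", "B"), ("C", "D")),
                "AC|BD": lsq(("A", "C"), ("B", "D")),
                "AD|BC": lsq(("A", "D"), ("B", "C"))}
        assert max(fits, key=fits.get) == "AB|CD"

    def test_label_permutation_invariance(self):
        rng = random.Random(7)
        labels = ["A", "B", "C", "D", "E"]
        D = np.array([[0, 2, 4, 6, 6], [2, 0, 4, 6, 6], [4, 4, 0, 4, 4],
                      [6, 6, 4, 0, 2], [6, 6, 4, 2, 0]], dtype=float)
        base = topology_bipartitions(nj(D, labels))
        perm = list(range(5))
        rng.shuffle(perm)
        Dp = D[np.ix_(perm, perm)]
        assert topology_bipartitions(nj(Dp, [labels[i] for i in perm])) == base

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(np.zeros((2, 2)), ["A", "B"])

    def test_agrees_with_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining on additive input
        skbio = pytest.importorskip("skbio")
        rng = random.Random(11)
        for _ in range(10):
            stree_true, labels, D = _random_additive(rng, rng.randint(5, 8))
            ours = topology_bipartitions(nj(D, labels))
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, labels))
            sk = {frozenset({t.name for t in clade.tips()})
                  for clade in sk_tree.non_tips()}
            all_labels = frozenset(labels)
            ref = min(all_labels)
            sk_canon = {frozenset(all_labels - s) if ref in s else s
                        for s in sk if 2 <= len(s) <= len(labels) - 2}
            assert sk_canon == ours


def _random_additive(rng: random.Random, n: int):
    """Random binary tree on n taxa -> (SupportTree, labels, distance matrix)."""
    import dendropy

    from ceseek.tree_infer import SupportTree

    labels = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace()
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        node.edge.length = rng.uniform(0.2, 1.5)
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.2, 1.5)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    taxa = {t.label: t for t in tns}
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return SupportTree(tree), labels, D


@pytest.mark.parametrize("seed", range(20))
def test_nj_recovers_random_additive_topologies(seed):
    rng = random.Random(seed)
    stree_true, labels, D = _random_additive(rng, rng.randint(5, 8))
    assert topology_bipartitions(nj(D, labels)) == topology_bipartitions(stree_true)


class TestBootstrap:
    @staticmethod
    def _clean_quartet():
        return Alignment({"A_1": "A" * 40, "B_1": "A" * 40,
                          "C_1": "T" * 40, "D_1": "T" * 40})

    def test_unanimous_columns_give_full_support(self):
        from ceseek.tree_infer import iter_bipartitions
        stree = bootstrap_support(self._clean_quartet(), n_reps=50, seed=0)
        supports = [int(node.label) for _side, node in iter_bipartitions(stree)]
        assert supports == [100]

    def test_single_replicate_support_binary(self):
        aln = Alignment({"A_1": "AAAATTTT", "B_1": "AAAATTAT",
                         "C_1": "TTTTAAAA", "D_1": "TTTTATAA"})
        stree = bootstrap_support(aln, n_reps=1, seed=3)
        from ceseek.tree_infer import iter_bipartitions
        for _side, node in iter_bipartitions(stree):
            assert int(node.label) in {0, 100}

    def test_fixed_seed_reproducible(self):
        aln = Alignment({"A_1": "ACGTACGTAC", "B_1": "ACGTACTTAC",
                         "C_1": "GCTTACGTAA", "D_1": "GCTTACGCAA"})
        t1 = bootstrap_support(aln, n_reps=30, seed=9).as_newick()
        t2 = bootstrap_support(aln, n_reps=30, seed=9).as_newick()
        assert t1 == t2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._clean_quartet(), n_reps=0, seed=0)

    def test_supports_within_percent_range(self):
        rng = np.random.default_rng(4)
        rows = {f"s{i}_g": "".join(rng.choice(list("ACGT"), 30)) for i in range(6)}
        stree = bootstrap_support(Alignment(rows), n_reps=20, seed=1)
        from ceseek.tree_infer import iter_bipartitions
        for _side, node in iter_bipartitions(stree):
            assert 0 <= int(node.label) <= 100


class TestReadNewick:
    def test_supports_parsed(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A_g1:1,A_g2:1)95:1,(B_g1:1,C_g1:1)80:1);\n")
        stree = read_newick(path)
        labels = {node.label for node in stree.tree.preorder_node_iter()
                  if not node.is_leaf() and node.label}
        assert labels == {"95", "80"}

    def test_fractional_supports_normalised(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A_g1:1,A_g2:1)0.95:1,(B_g1:1,C_g1:1)0.8:1);\n")
        stree = read_newick(path)
        labels = {node.label for node in stree.tree.preorder_node_iter()
                  if not node.is_leaf() and node.label}
        assert labels == {"95", "80"}

    def test_species_token_convention(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((Aaz_WP_0123:1,Aaz_WP_9:1)90:1,(B_g1:1,C_g1:1)80:1);\n")
        stree = read_newick(path)
        assert stree.species_of("Aaz_WP_0123") == "Aaz"
        assert set(stree.leaves_by_species()) == {"Aaz", "B", "C"}


class TestAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            Alignment({"a": "ACGT", "b": "ACG"})

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            Alignment({"a": "ACGT"})

    def test_distance_matrix_symmetric_zero_diagonal(self):
        aln = Alignment({"a": "ACGTAC", "b": "ACTTAC", "c": "GCTTAC"})
        D, labels = jc_distance_matrix(aln)
        assert labels == ["a", "b", "c"]
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
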