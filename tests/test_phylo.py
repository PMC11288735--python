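"""p-distances, neighbor-joining, and bootstrap supports."""

import dendropy
import numpy as np
import pytest

from centeline.errors import CentelineError
from centeline.phylo import (
    AlignedBlock,
    bipartitions,
    bootstrap_support,
    nj_tree,
    pdistance,
)


class TestPDistance:
    def test_identical_rows_zero(self):
        block = AlignedBlock(["a", "b", "c"], ["ACGT" * 5] * 3)
        assert (pdistance(block) == 0).all()

    def test_five_of_100_mismatches(self):
        r1 = "A" * 100
        r2 = "A" * 95 + "C" * 5
        block = AlignedBlock(["a", "b", "c"], [r1, r2, r1])
        assert pdistance(block)[0, 1] == pytest.approx(0.05)

    def test_gap_columns_skipped_hand_count(self):
        # 10 columns; pair (a,b): comparable at cols 0,1,2,5,6,7,8,9 (8 cols),
        # mismatches at cols 2 and 9 -> 2/8
        block = AlignedBlock(
            ["a", "b", "c"],
            ["ACGT-AACGT", "ACT--AACGA", "ACGTTAACGT"],
        )
        D = pdistance(block, gap_handling="pairwise")
        assert D[0, 1] == pytest.approx(2 / 8)

    def test_complete_deletion_drops_any_gap_column(self):
        block = AlignedBlock(
            ["a", "b", "c"],
            ["ACGT-AACGT", "ACT--AACGA", "ACGTTAACGT"],
        )
        D = pdistance(block, gap_handling="complete")
        # columns 3,4 dropped for everyone: 8 columns compared for every pair
        assert D[0, 2] == pytest.approx(0.0)
        assert D[0, 1] == pytest.approx(2 / 8)

    def test_zero_comparable_columns_is_error(self):
        block = AlignedBlock(["a", "b", "c"], ["A---", "-C--", "GGGG"])
        with pytest.raises(CentelineError):
            pdistance(block)


def _random_additive_tree(rng, n_taxa):
    """Random topology + branch lengths; returns (dendropy tree, distance matrix, names)."""
    names = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, taxon_namespace=taxa,
        rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = rng.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_taxa, n_taxa))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            D[i, j] = pdm.patristic_distance(ti, tj)
    return tree, D, names


def _dendropy_bipartitions(tree):
    names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(names)
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(names) - 2:
            out.add(side if ref not in side else frozenset(names - side))
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.5], [0.4, 0.5, 0]])
        tree = nj_tree(D, ["A", "B", "C"])
        lengths = {child.name: blen for child, blen in tree.children}
        assert lengths["A"] == pytest.approx((0.2 + 0.4 - 0.5) / 2)
        assert lengths["B"] == pytest.approx((0.2 + 0.5 - 0.4) / 2)
        assert lengths["C"] == pytest.approx((0.4 + 0.5 - 0.2) / 2)

    def test_additive_quartet_recovers_true_split(self):
        # ((A,B),(C,D)) with internal branch 3
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
        )
        tree = nj_tree(D, ["A", "B", "C", "D"])
        assert frozenset(["C", "D"]) in bipartitions(tree) or frozenset(["A", "B"]) in bipartitions(tree)

    def test_star_tree_zero_internal_branch(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(D, list("ABCD"))
        internal = [blen for child, blen in tree.children if not child.is_leaf]
        assert all(b == pytest.approx(0.0, abs=1e-12) for b in internal)

    def test_recovers_random_additive_topologies_up_to_8_taxa(self):
        """NJ is consistent on additive matrices (checked against the generating tree)."""
        import random

        for seed, n in [(1, 5), (2, 6), (3, 7), (4, 8), (5, 8), (6, 8)]:
            rng = random.Random(seed)
            true_tree, D, names = _random_additive_tree(rng, n)
            ours = nj_tree(D, names)
            assert bipartitions(ours) == _dendropy_bipartitions(true_tree)

    def test_agrees_with_dendropy_nj_on_additive_matrix(self):
        import random

        rng = random.Random(10)
        _, D, names = _random_additive_tree(rng, 7)
        ours = bipartitions(nj_tree(D, names))
        csv = "," + ",".join(names) + "\n"
        for i, nm in enumerate(names):
            csv += nm + "," + ",".join(str(x) for x in D[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        theirs = _dendropy_bipartitions(pdm.nj_tree())
        assert ours == theirs

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(D, list("ABC"))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            D = rng.uniform(0.1, 1.0, size=(6, 6))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            tree = nj_tree(D, [f"x{i}" for i in range(6)])

            def walk(node):
                for child, blen in node.children:
                    assert blen >= 0
                    walk(child)

            walk(tree)


class TestBootstrap:
    def test_perfect_split_gets_full_support(self):
        block = AlignedBlock(list("ABCD"), ["AAAA", "AAAA", "TTTT", "TTTT"])
        st = bootstrap_support(block, n_reps=200, seed=1)
        assert st.supports[frozenset(["C", "D"])] == 100.0

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(5)
        rows = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)]) for _ in range(5)]
        block = AlignedBlock([f"t{i}" for i in range(5)], rows)
        a = bootstrap_support(block, n_reps=100, seed=3)
        b = bootstrap_support(block, n_reps=100, seed=3)
        assert a.supports == b.supports

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(6)
        base = "ACGTACGTACGTACGTACGTACGTACGTACGT"

        def mut(s, k, seed):
            r = np.random.default_rng(seed)
            s = list(s)
            for p in r.choice(len(s), size=k, replace=False):
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s)

        names = ["a", "b", "c", "d", "e"]
        rows = [base, mut(base, 2, 1), mut(base, 10, 2), mut(base, 11, 3), mut(base, 20, 4)]
        st1 = bootstrap_support(AlignedBlock(names, rows), n_reps=150, seed=9)
        order = [3, 1, 4, 0, 2]
        st2 = bootstrap_support(
            AlignedBlock([names[i] for i in order], [rows[i] for i in order]),
            n_reps=150,
            seed=9,
        )
        # same bipartitions exist; supports agree within resampling noise
        assert set(st1.supports) == set(st2.supports)
        for bip in st1.supports:
            assert abs(st1.supports[bip] - st2.supports[bip]) <= 12.0

    def test_fifty_fifty_conflict_near_half_support(self):
        """Two equally frequent column classes supporting conflicting quartet
        splits give ~50% support (binomial resampling expectation)."""
        colA = ["A", "A", "T", "T"]  # supports AB|CD
        colB = ["A", "T", "A", "T"]  # supports AC|BD
        rows = ["".join(colA[i] * 20 + colB[i] * 20) for i in range(4)]
        block = AlignedBlock(list("ABCD"), rows)
        st = bootstrap_support(block, n_reps=400, seed=11, cutoff=0.0)
        total = sum(st.supports.values())
        (support,) = st.supports.values()
        assert abs(support - 50.0) < 3 * 100 * np.sqrt(0.25 / 400) + 5

    def test_collapse_below_cutoff_creates_polytomy(self):
        colA = ["A", "A", "T", "T", "T"]
        rng = np.random.default_rng(13)
        rows = ["".join(colA[i] + "ACGT"[rng.integers(0, 4)] * 1 for _ in range(30)) for i in range(5)]
        # rows built with weak signal; low-support branches must vanish
        block = AlignedBlock(list("ABCDE"), rows)
        st = bootstrap_support(block, n_reps=100, seed=2, cutoff=50.0)

        def max_depth(node, d=0):
            if node.is_leaf:
                return d
            return max(max_depth(c, d + 1) for c, _ in node.children)

        for bip, sup in st.supports.items():
            if sup < 50.0:
                assert bip not in bipartitions(st.tree)

    def test_zero_replicates_rejected(self):
        block = AlignedBlock(list("ABC"), ["AC", "AC", "GT"])
        with pytest.raises(ValueError):
            bootstrap_support(block, n_reps=0)
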