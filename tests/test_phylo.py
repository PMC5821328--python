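import math
from importlib import resources

import numpy as np
import pytest

from oracles import random_additive_tree
from virowinnow import phylo
from virowinnow.phylo import MsAlignment, neighbor_joining, pairwise_distances


class TestAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            MsAlignment(["a", "b", "c"], ["AAA", "AA", "AAA"])

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            MsAlignment(["a", "b"], ["AAA", "AAA"])

    def test_mask_restricts_columns(self):
        aln = MsAlignment(
            ["a", "b", "c"], ["AAAA", "AATT", "AAAA"], mask=[True, True, False, False]
        )
        d = pairwise_distances(aln, model="p")
        assert d[0, 1] == 0.0  # masked columns carry the differences


class TestDistances:
    def test_identical_rows(self):
        aln = MsAlignment(["a", "b", "c"], ["MKV" * 10] * 3)
        assert np.all(pairwise_distances(aln, "p") == 0)

    def test_p_distance_definition(self):
        row_a = "A" * 100
        row_b = "A" * 90 + "C" * 10
        aln = MsAlignment(["a", "b", "c"], [row_a, row_b, row_a])
        d = pairwise_distances(aln, "p")
        assert d[0, 1] == pytest.approx(0.10)

    def test_poisson_correction(self):
        row_a = "A" * 100
        row_b = "A" * 90 + "C" * 10
        aln = MsAlignment(["a", "b", "c"], [row_a, row_b, row_a])
        d = pairwise_distances(aln, "poisson")
        # frozen arbitrary-precision value of -ln(0.9)
        assert d[0, 1] == pytest.approx(0.105360515657826, rel=1e-12)

    def test_pairwise_deletion_of_gaps(self):
        aln = MsAlignment(["a", "b", "c"], ["AAC--AAAAA", "AACAAAA-AA", "AAAAAAAAAA"])
        d = pairwise_distances(aln, "p")
        # 7 comparable sites between a and b, all equal
        assert d[0, 1] == 0.0

    def test_poisson_at_least_p(self):
        rng = np.random.default_rng(0)
        AA = "ACDEFGHIKLMNPQRSTVWY"
        base = [AA[i] for i in rng.integers(0, 20, 60)]
        rows = []
        for _ in range(4):
            s = list(base)
            for i in rng.choice(60, 15, replace=False):
                s[i] = AA[int(rng.integers(0, 20))]
            rows.append("".join(s))
        aln = MsAlignment([f"t{i}" for i in range(4)], rows)
        dp = pairwise_distances(aln, "p")
        dpois = pairwise_distances(aln, "poisson")
        assert np.all(dpois >= dp)
        off_diag = ~np.eye(4, dtype=bool)
        assert np.all((dpois[off_diag] == dp[off_diag]) == (dp[off_diag] == 0))

    def test_saturated_pair_rejected(self):
        aln = MsAlignment(["a", "b", "c"], ["AAAA", "CCCC", "AAAA"])
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distances(aln, "poisson")


def _branch_lengths(tree):
    """{frozenset(leaves below edge) or leaf name: length} for every edge."""
    out = {}

    def walk(node):
        for child, bl in node.children:
            leaves = child.leaves()
            key = leaves[0] if len(leaves) == 1 else frozenset(leaves)
            out[key] = bl
            walk(child)

    walk(tree.root)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        bl = _branch_lengths(tree)
        assert bl["a"] == pytest.approx(1.0)
        assert bl["b"] == pytest.approx(2.0)
        assert bl["c"] == pytest.approx(3.0)

    def test_four_taxon_additive_example(self):
        # tree ((A:1,B:2):1,(C:3,D:1)): additive path-length matrix
        names = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(d, names)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        bl = _branch_lengths(tree)
        assert bl["A"] == pytest.approx(1.0)
        assert bl["B"] == pytest.approx(2.0)
        assert bl["C"] == pytest.approx(3.0)
        assert bl["D"] == pytest.approx(1.0)
        internal = next(v for k, v in bl.items() if isinstance(k, frozenset))
        assert internal == pytest.approx(1.0)
        assert tree.clamped == []

    def test_additive_recovery_random_trees(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            dist, names, true_bps = random_additive_tree(n, rng)
            tree = neighbor_joining(dist, names)
            assert tree.bipartitions() == true_bps

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, ["a", "b", "c"])

    def test_ultrametric_tie_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(d, ["a", "b", "c", "d"]).newick()
        t2 = neighbor_joining(d, ["a", "b", "c", "d"]).newick()
        assert t1 == t2

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(7)
        dist, names, _ = random_additive_tree(6, rng)
        perm = list(rng.permutation(len(names)))
        tree1 = neighbor_joining(dist, names)
        tree2 = neighbor_joining(dist[np.ix_(perm, perm)], [names[i] for i in perm])
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_negative_branches_clamped_and_logged(self):
        # non-additive matrix known to yield a negative NJ branch length
        d = np.array(
            [
                [0.0, 1.7235, 1.2755, 0.712],
                [1.7235, 0.0, 1.176, 0.4315],
                [1.2755, 1.176, 0.0, 0.2355],
                [0.712, 0.4315, 0.2355, 0.0],
            ]
        )
        tree = neighbor_joining(d, ["a", "b", "c", "d"])
        bl = _branch_lengths(tree)
        assert all(v >= 0 for v in bl.values())
        assert tree.clamped and tree.clamped[0][1] < 0  # original value logged


def _two_clade_alignment():
    rng = np.random.default_rng(5)
    AA = "ACDEFGHIKLMNPQRSTVWY"
    L = 120
    base = [AA[i] for i in rng.integers(0, 20, L)]
    names = ["a1", "a2", "a3", "b1", "b2", "b3", "out1", "out2"]
    rows = []
    diag_a = {int(i): "W" if base[i] != "W" else "Y" for i in range(0, 50)}
    diag_b = {int(i): "H" if base[i] != "H" else "Q" for i in range(50, 100)}
    for name in names:
        s = list(base)
        if name.startswith("a"):
            for i, r in diag_a.items():
                s[i] = r
        elif name.startswith("b"):
            for i, r in diag_b.items():
                s[i] = r
        for i in rng.choice(L, 2, replace=False):
            s[i] = AA[int(rng.integers(0, 20))]
        rows.append("".join(s))
    return MsAlignment(names, rows)


class TestBootstrap:
    def test_clear_clades_get_high_support(self):
        aln = _two_clade_alignment()
        tree = phylo.bootstrap(aln, n_reps=100, seed=2)
        all_taxa = set(aln.names)
        supports = {frozenset(n.leaves()): n.support for n in tree.internal_nodes()}
        for clade in ({"a1", "a2", "a3"}, {"b1", "b2", "b3"}):
            # an unrooted clade may appear as either side of its bipartition
            matching = [
                s for k, s in supports.items()
                if set(k) == clade or set(k) == all_taxa - clade
            ]
            assert matching, f"clade {clade} not in tree"
            assert max(matching) >= 95.0

    def test_zero_reps_leaves_supports_unset(self):
        aln = _two_clade_alignment()
        tree = phylo.bootstrap(aln, n_reps=0, seed=0)
        assert all(n.support is None for n in tree.internal_nodes())

    def test_seed_determinism(self):
        aln = _two_clade_alignment()
        t1 = phylo.bootstrap(aln, n_reps=50, seed=9).newick()
        t2 = phylo.bootstrap(aln, n_reps=50, seed=9).newick()
        assert t1 == t2

    def test_supports_in_range_and_replicates_logged(self):
        aln = _two_clade_alignment()
        tree = phylo.bootstrap(aln, n_reps=25, seed=1)
        for node in tree.internal_nodes():
            assert node.support is None or 0.0 <= node.support <= 100.0
        assert len(tree.replicate_columns) == 25


class TestToyFixtureAndNewick:
    def test_packaged_alignment_main_split(self, tmp_path):
        ref = resources.files("virowinnow.data") / "rdrp_toy_alignment.fasta"
        path = tmp_path / "aln.fasta"
        path.write_text(ref.read_text())
        aln = MsAlignment.from_fasta(path)
        assert len(aln.names) == 8
        tree = phylo.bootstrap(aln, n_reps=100, seed=0)
        clade_a = frozenset({"SINV5_like", "ABPV_like", "IAPV_like", "KBV_like"})
        supports = {
            frozenset(n.leaves()): n.support for n in tree.internal_nodes()
        }
        # the A/B split is the only strongly supported bipartition
        main = [s for k, s in supports.items() if k == clade_a or k == frozenset(aln.names) - clade_a]
        assert main and main[0] >= 95.0

    def test_newick_parses_with_dendropy(self, tmp_path):
        import dendropy

        aln = _two_clade_alignment()
        tree = phylo.bootstrap(aln, n_reps=10, seed=0)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(aln.names)

    def test_distance_tsv(self, tmp_path):
        aln = _two_clade_alignment()
        d = pairwise_distances(aln, "p")
        out = tmp_path / "d.tsv"
        phylo.write_distance_tsv(d, aln.names, out)
        lines = out.read_text().splitlines()
        assert len(lines) == len(aln.names) + 1

    def test_phylip_parser(self, tmp_path):
        path = tmp_path / "aln.phy"
        path.write_text("3 6\nTaxA MKVLAG\nTaxB MKVLAC\nTaxC MKVACG\n")
        aln = MsAlignment.from_phylip(path)
        assert aln.names == ["TaxA", "TaxB", "TaxC"]
        assert aln.rows[2] == "MKVACG"
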