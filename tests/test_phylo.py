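"""NJ phylogeny: distances, additive recovery, bootstrap, grouping."""

import numpy as np
import pytest

from ccchsurvey import phylo
from ccchsurvey import synthetic_data as sd


def random_additive_matrix(n_taxa, rng):
    """Distances from a random binary tree with positive branch lengths."""
    nodes = [({i}, {i: 0.0}) for i in range(n_taxa)]  # (leafset, depth map)
    dist = np.zeros((n_taxa, n_taxa))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (la, da), (lb, db) = nodes[i], nodes[j]
        ea, eb = rng.uniform(0.05, 1.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[x, y] = dist[y, x] = dx + ea + dy + eb
        merged = {x: d + ea for x, d in da.items()}
        merged.update({y: d + eb for y, d in db.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((la | lb, merged))
    return dist


class TestPDistance:
    def test_identical_rows_are_zero(self):
        aln = phylo.Alignment({"a": "ACDE", "b": "ACDE"})
        assert phylo.p_distance(aln).values[0, 1] == 0.0

    def test_half_mismatches(self):
        aln = phylo.Alignment({"a": "AAAA", "b": "AATT"})
        assert phylo.p_distance(aln).values[0, 1] == 0.5

    def test_pairwise_deletion_hand_count(self):
        # comparable sites: positions 1 and 3 only -> 0 mismatches / 2
        aln = phylo.Alignment({"a": "A-CD", "b": "AAC-"})
        dm = phylo.p_distance(aln)
        assert dm.values[0, 1] == 0.0
        assert dm.compared_sites[0, 1] == 2

    def test_no_comparable_sites_is_an_error(self):
        aln = phylo.Alignment({"a": "A--", "b": "-AA", "c": "AAA"})
        with pytest.raises(ValueError, match="no comparable sites"):
            phylo.p_distance(aln)

    def test_distances_within_unit_interval(self):
        rng = np.random.default_rng(0)
        rows = {
            f"t{i}": "".join(rng.choice(list("ACDEFG-"), size=50)) for i in range(6)
        }
        dm = phylo.p_distance(phylo.Alignment(rows))
        assert ((dm.values >= 0) & (dm.values <= 1)).all()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        taxa, P = tree.path_lengths()
        np.testing.assert_allclose(P, D)
        lengths = {ch.name: ch.length for ch in tree.root.children}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 7.0}

    def test_four_taxon_cherry_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        taxa, P = tree.path_lengths()
        np.testing.assert_allclose(P, D)
        assert frozenset("AB") in {s for s in tree.canonical_splits()} or frozenset(
            "CD"
        ) in {s for s in tree.canonical_splits()}

    @pytest.mark.parametrize("seed", range(100))
    def test_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        D = random_additive_matrix(8, rng)
        ids = [f"t{i}" for i in range(8)]
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        _, P = tree.path_lengths()
        np.testing.assert_allclose(P, D, atol=1e-9)

    def test_matches_skbio_topology(self):
        skbio_tree_mod = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(7)
        D = random_additive_matrix(7, rng)
        ids = [f"t{i}" for i in range(7)]
        mine = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        ref = skbio_tree_mod.nj(SkbioDM(D, ids))
        ref_splits = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if "t0" in side:
                side = frozenset(ids) - side
            if 1 < len(side) < len(ids) - 1:
                ref_splits.add(side)
        assert mine.canonical_splits() == ref_splits

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
            )

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(3)
        # noisy (non-additive) matrix can yield negative NJ estimates
        D = random_additive_matrix(6, rng)
        D += rng.uniform(0, 0.3, size=D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = phylo.neighbor_joining(
            phylo.DistanceMatrix([f"t{i}" for i in range(6)], D)
        )

        def walk(n):
            assert n.length >= 0
            for ch in n.children:
                walk(ch)

        walk(tree.root)


class TestBootstrap:
    def test_congruent_signal_gives_full_support(self):
        # two perfectly congruent blocks separating {a,b} from {c,d,e}
        rows = {
            "a": "AAAAAAAAAA",
            "b": "AAAAAAAAAA",
            "c": "TTTTTTTTTT",
            "d": "TTTTTTTTTT",
            "e": "TTTTTGGGGG",
        }
        tree = phylo.bootstrap(phylo.Alignment(rows), n_reps=100, seed=1)
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_zero_replicates_leaves_support_undefined(self):
        rows, _ = sd.generate_clade_alignment([3, 3], length=60, seed=1)
        tree = phylo.bootstrap(phylo.Alignment(rows), n_reps=0, seed=1)
        assert all(n.support is None for n in tree.internal_nodes())

    def test_reproducibility_and_taxon_order_invariance(self):
        rows, _ = sd.generate_clade_alignment([3, 3], length=120, seed=4)
        aln1 = phylo.Alignment(rows)
        t1 = phylo.bootstrap(aln1, n_reps=200, seed=5)
        t2 = phylo.bootstrap(aln1, n_reps=200, seed=5)
        sup = lambda t: {
            side: n.support for side, n in t.bipartitions().items()
        }
        assert sup(t1) == sup(t2)
        # permuted taxon input order: same split supports
        rows_rev = dict(reversed(list(rows.items())))
        t3 = phylo.bootstrap(phylo.Alignment(rows_rev), n_reps=200, seed=5)
        anchor = sorted(rows)[0]
        full = frozenset(rows)

        def canon(t):
            out = {}
            for side, n in t.bipartitions().items():
                c = full - side if anchor in side else side
                if 1 < len(c) < len(full) - 1:
                    out[c] = n.support
            return out

        assert canon(t1) == canon(t3)


class TestGroups:
    def _supported_quartet(self):
        rows = {
            "A": "AAAAAAAAAA" + "ACGT" * 5,
            "B": "AAAAAAAAAA" + "ACGT" * 5,
            "C": "TTTTTTTTTT" + "GTCA" * 5,
            "D": "TTTTTTTTTT" + "GTCA" * 5,
        }
        return phylo.bootstrap(phylo.Alignment(rows), n_reps=100, seed=2)

    def test_quartet_yields_both_flanking_clades(self):
        groups = phylo.assign_groups(self._supported_quartet())
        by_label = {}
        for t, g in groups.items():
            by_label.setdefault(g, set()).add(t)
        assert set(map(frozenset, by_label.values())) == {
            frozenset("AB"),
            frozenset("CD"),
        }

    def test_all_below_threshold_means_all_ungrouped(self):
        tree = self._supported_quartet()
        groups = phylo.assign_groups(tree, threshold=100.0)  # strict > 100
        assert all(g is None for g in groups.values())

    def test_planted_clades_recovered(self):
        rows, truth = sd.generate_clade_alignment([4, 4, 4], length=200, seed=8)
        tree = phylo.bootstrap(phylo.Alignment(rows), n_reps=200, seed=8)
        groups = phylo.assign_groups(tree)
        label_map = {}
        for taxon, g in groups.items():
            assert g is not None
            label_map.setdefault(g, set()).add(truth[taxon])
        # each recovered group is exactly one planted clade
        assert all(len(v) == 1 for v in label_map.values())
        assert len(label_map) == 3


class TestSisterPairs:
    def test_balanced_quartet_has_two_cherries(self):
        a = phylo.TreeNode(name="A")
        b = phylo.TreeNode(name="B")
        c = phylo.TreeNode(name="C")
        d = phylo.TreeNode(name="D")
        ab = phylo.TreeNode(children=[a, b])
        cd = phylo.TreeNode(children=[c, d])
        tree = phylo.PhyloTree(phylo.TreeNode(children=[ab, cd]))
        assert [(x, y) for x, y, _ in phylo.sister_pairs(tree)] == [("A", "B"), ("C", "D")]

    def test_caterpillar_has_single_cherry(self):
        a = phylo.TreeNode(name="A")
        b = phylo.TreeNode(name="B")
        ab = phylo.TreeNode(children=[a, b])
        abc = phylo.TreeNode(children=[ab, phylo.TreeNode(name="C")])
        root = phylo.TreeNode(children=[abc, phylo.TreeNode(name="D")])
        assert [(x, y) for x, y, _ in phylo.sister_pairs(phylo.PhyloTree(root))] == [
            ("A", "B")
        ]

    def test_planted_cherries_recovered(self):
        # 10 cherries: pairs of near-identical rows, distinct between pairs
        rng = np.random.default_rng(12)
        rows = {}
        for i in range(10):
            base = "".join(rng.choice(list("ACDEFGHIKL"), size=100))
            rows[f"p{i}x"] = base
            mutated = list(base)
            mutated[0] = "W" if base[0] != "W" else "Y"
            rows[f"p{i}y"] = "".join(mutated)
        tree = phylo.build_tree(phylo.Alignment(rows))
        got = {(x, y) for x, y, _ in phylo.sister_pairs(tree)}
        want = {(f"p{i}x", f"p{i}y") for i in range(10)}
        assert want <= got
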