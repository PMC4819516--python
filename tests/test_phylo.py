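"""Distances, neighbor joining, rooting, parsimony mapping, support, markers."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from rhodate import phylo, simdata, treeio
from rhodate.errors import ConfigError, DataError

from conftest import CLADE_A, CLADE_B, build_htree, htree_on_truth, toy_matrix


class TestPairwiseDistance:
    def test_hand_enumerated_toy(self):
        """i derived at {1,2,3}, j derived at {3,4}, site 5 missing in j over a
        10-site universe: 3 discordant out of 9 comparable."""
        m = toy_matrix(
            ["i", "j"], [1, 2, 3, 4, 5],
            [[1, 1, 1, 0, 0], [0, 0, 1, 1, 0]],
            masks={"j": [5]}, universe_size=10,
        )
        assert phylo.pairwise_distance(m, "i", "j") == pytest.approx(3 / 9)

    def test_self_distance_zero(self):
        m = toy_matrix(["i", "j"], [1], [[1], [0]], universe_size=4)
        assert phylo.pairwise_distance(m, "i", "i") == 0.0

    def test_symmetry_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            calls = rng.integers(-1, 2, size=(4, 8)).astype(np.int8)
            calls[0, :] = 1  # keep every site variant
            m = toy_matrix(list("abcd"), list(range(1, 9)), calls,
                           universe_size=20)
            D = phylo.distance_matrix(m)
            assert np.allclose(D, D.T)

    def test_no_shared_callable_sites_names_pair(self):
        m = toy_matrix(
            ["i", "j"], [1, 2],
            [[1, -1], [-1, 1]],
            masks={"i": [2], "j": [1]}, universe_size=2,
        )
        with pytest.raises(DataError, match="'i' and 'j'"):
            phylo.pairwise_distance(m, "i", "j")

    def test_brute_force_equivalence(self):
        """Exact match against a site-by-site loop on explicit mask arrays."""
        rng = np.random.default_rng(3)
        ids = list("abcde")
        universe = 30
        positions = sorted(rng.choice(universe, size=9, replace=False) + 1)
        calls = rng.integers(0, 2, size=(5, 9)).astype(np.int8)
        calls[0] = 1
        masks = {s: sorted(rng.choice(universe, size=5, replace=False) + 1)
                 for s in ids}
        m = toy_matrix(ids, positions, calls, masks, universe)
        full = {s: np.ones(universe, bool) for s in ids}
        for s in ids:
            for p in masks[s]:
                full[s][p - 1] = False
        geno = {s: np.zeros(universe, np.int8) for s in ids}
        for k, p in enumerate(positions):
            for i, s in enumerate(ids):
                geno[s][p - 1] = calls[i, k]
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i >= j:
                    continue
                num = den = 0
                for p in range(universe):
                    if full[a][p] and full[b][p]:
                        den += 1
                        if geno[a][p] != geno[b][p]:
                            num += 1
                assert phylo.pairwise_distance(m, a, b) == pytest.approx(num / den)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = phylo.neighbor_joining(D, ["A", "B", "C"])
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("grouping", [("AB", "CD"), ("AC", "BD"), ("AD", "BC")])
    def test_recovers_additive_quartets(self, grouping):
        """NJ finds the generating quartet for every possible topology."""
        pair = set(grouping[0])
        labels = list("ABCD")
        # distances from a tree with internal branch 2, terminal branches 1
        D = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i != j:
                    same = ({x, y} == pair) or ({x, y} == set(grouping[1]))
                    D[i, j] = 2.0 if same else 4.0
        tree = phylo.neighbor_joining(D, labels)
        bips = phylo.unrooted_bipartitions(tree)
        assert frozenset(pair) in bips

    def test_equal_distances_deterministic(self):
        D = np.ones((5, 5)) - np.eye(5)
        t1 = phylo.neighbor_joining(D, list("abcde")).as_string(schema="newick")
        t2 = phylo.neighbor_joining(D, list("abcde")).as_string(schema="newick")
        assert t1 == t2

    def test_negative_branch_clamped_deficit_moved(self):
        """A distance matrix forcing a negative NJ branch yields length 0 with
        the deficit moved to the sibling (pair sum preserved)."""
        D = np.array([
            [0.0, 0.1, 2.0, 2.1],
            [0.1, 0.0, 2.1, 2.0],
            [2.0, 2.1, 0.0, 0.1],
            [2.1, 2.0, 0.1, 0.0],
        ])
        tree = phylo.neighbor_joining(D, list("abcd"))
        for lf in tree.leaf_node_iter():
            assert lf.edge.length >= 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(DataError, match="symmetric"):
            phylo.neighbor_joining(D, list("abc"))

    def test_matches_scikit_bio_on_random_additive_matrices(self):
        """Cross-check topologies against the independent skbio implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.random((7, 5))
            labels = [f"t{i}" for i in range(7)]
            D = np.abs(pts[:, None, :] - pts[None, :, :]).sum(axis=2)
            mine = phylo.unrooted_bipartitions(phylo.neighbor_joining(D, labels))
            theirs = dendropy.Tree.get(data=str(skbio_nj(DistanceMatrix(D, labels))),
                                       schema="newick")
            assert mine == phylo.unrooted_bipartitions(theirs)


class TestRooting:
    def _simple_tree(self):
        D = np.array([
            [0.0, 2.0, 8.0, 8.0],
            [2.0, 0.0, 8.0, 8.0],
            [8.0, 8.0, 0.0, 2.0],
            [8.0, 8.0, 2.0, 0.0],
        ])
        return phylo.neighbor_joining(D, ["a1", "a2", "o1", "o2"])

    def test_root_splits_outgroup(self):
        tree = phylo.root_by_outgroup(self._simple_tree(), ["o1", "o2"])
        kids = [treeio.clade_leafset(c) for c in tree.seed_node.child_nodes()]
        assert frozenset(["o1", "o2"]) in kids
        assert frozenset(["a1", "a2"]) in kids

    def test_leafset_unchanged_and_idempotent(self):
        tree = phylo.root_by_outgroup(self._simple_tree(), ["o1", "o2"])
        again = phylo.root_by_outgroup(tree, ["o1", "o2"])
        assert set(treeio.leaf_labels(again)) == {"a1", "a2", "o1", "o2"}
        kids = [treeio.clade_leafset(c) for c in again.seed_node.child_nodes()]
        assert frozenset(["o1", "o2"]) in kids

    def test_nonmonophyletic_outgroup_rejected(self):
        with pytest.raises(DataError, match="not monophyletic"):
            phylo.root_by_outgroup(self._simple_tree(), ["a1", "o1"])

    def test_recovers_true_root_bipartition(self, demo_full):
        htree = build_htree(demo_full)
        kids = [treeio.clade_leafset(c) for c in htree.tree.seed_node.child_nodes()]
        assert frozenset(["OUT1"]) in kids
        assert frozenset(CLADE_A + CLADE_B) in kids


class TestParsimonyMapping:
    def test_singleton_assigned_to_terminal_branch(self):
        m = toy_matrix(list("abc"), [1], [[1], [0], [0]], universe_size=5)
        tree = treeio.parse_tree("((a:1,b:1):1,c:2);")
        ht = phylo.map_mutations_parsimony(tree, m)
        counts = ht.branch_counts()
        assert counts[frozenset(["a"])] == 1
        assert sum(counts.values()) == 1

    def test_clade_site_assigned_to_stem(self):
        m = toy_matrix(list("abcd"), [1], [[1], [1], [0], [0]], universe_size=5)
        tree = treeio.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        ht = phylo.map_mutations_parsimony(tree, m)
        assert ht.branch_counts()[frozenset(["a", "b"])] == 1

    def test_homoplasic_site_flagged_and_excluded(self):
        m = toy_matrix(list("abcd"), [1, 2], [[1, 1], [0, 1], [1, 0], [0, 0]],
                       universe_size=5)
        tree = treeio.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        ht = phylo.map_mutations_parsimony(tree, m)
        assert list(ht.homoplasic_cols) == [0]   # a+c derived needs 2 changes
        assert sum(ht.branch_counts().values()) == 1

    def test_full_coverage_counts_equal_ground_truth(self):
        cfg = simdata.SimConfig(
            tree_spec=simdata.two_clade_newick(n_a=3, n_b=3), L=1_000_000, seed=31)
        data = simdata.simulate_snv_dataset(cfg)
        ht = htree_on_truth(data)
        assert ht.n_homoplasic == 0
        truth = {k: v for k, v in data.truth.branch_counts().items() if v}
        mapped = {k: v for k, v in ht.branch_counts().items() if v}
        assert mapped == truth

    def test_counts_sum_to_non_homoplasic_sites(self, demo_data):
        ht = htree_on_truth(demo_data)
        total = sum(ht.branch_counts().values())
        assert total == demo_data.matrix.n_sites - ht.n_homoplasic \
            - len(ht.uninformative_cols)

    def test_missing_calls_keep_mutation_on_carrier_path(self):
        """Derived in a, missing in sibling b: the change lands on either a's
        terminal branch or the ab stem, both on a's root path."""
        m = toy_matrix(list("abc"), [1], [[1], [-1], [0]], universe_size=5)
        tree = treeio.parse_tree("((a:1,b:1):1,c:2);")
        ht = phylo.map_mutations_parsimony(tree, m)
        hits = [k for k, v in ht.branch_counts().items() if v]
        assert hits in ([frozenset(["a"])], [frozenset(["a", "b"])])


class TestBootstrapSupport:
    def test_single_replicate_is_all_or_nothing(self, demo_data):
        sup = phylo.bootstrap_support(demo_data.matrix, [CLADE_A], n_reps=1, seed=0)
        assert sup[0].support in (0.0, 100.0)

    def test_deterministic_given_seed(self, demo_data):
        s1 = phylo.bootstrap_support(demo_data.matrix, [CLADE_A], n_reps=10, seed=4)
        s2 = phylo.bootstrap_support(demo_data.matrix, [CLADE_A], n_reps=10, seed=4)
        assert s1[0].support == s2[0].support

    def test_unsupported_clade_gets_low_support(self):
        """With only singleton sites there is no clade signal: an arbitrary
        two-leaf clade is found at the random-resolution baseline, below 100."""
        n = 6
        ids = [f"s{i}" for i in range(n)]
        calls = np.eye(n, dtype=np.int8)
        m = toy_matrix(ids, list(range(1, n + 1)), calls, universe_size=40)
        sup = phylo.bootstrap_support(m, [["s0", "s1"]], n_reps=50, seed=9)
        assert sup[0].support < 100.0


class TestMarkers:
    @staticmethod
    def marker_table():
        return phylo.MarkerTable(pd.DataFrame({
            "marker": ["M130", "M347", "M210", "M526", "P308", "M186"],
            "position": [100, 200, 300, 400, 500, 600],
            "haplogroup": ["C", "C", "C", "K", "S", "M"],
            "parent": ["", "M130", "M130", "", "M526", "M526"],
        }))

    def test_deepest_derived_marker_wins(self):
        mt = self.marker_table()
        calls = {100: 1, 200: 1}
        assert phylo.assign_haplogroup(calls, mt) == "C-M347"

    def test_m186_labels_m_haplogroup(self):
        mt = self.marker_table()
        assert phylo.assign_haplogroup({400: 1, 600: 1}, mt) == "M-M186"

    def test_no_derived_markers_unassigned(self):
        assert phylo.assign_haplogroup({100: 0, 400: -1},
                                       self.marker_table()) == "unassigned"

    def test_missing_intermediate_tolerated(self):
        # M347 derived, M130 missing entirely
        assert phylo.assign_haplogroup({200: 1}, self.marker_table()) == "C-M347"

    def test_incompatible_derived_calls_rejected(self):
        with pytest.raises(DataError, match="incompatible"):
            phylo.assign_haplogroup({200: 1, 600: 1}, self.marker_table())

    def test_duplicate_positions_rejected(self):
        with pytest.raises(DataError, match="unique"):
            phylo.MarkerTable(pd.DataFrame({
                "marker": ["a", "b"], "position": [1, 1],
                "haplogroup": ["X", "Y"], "parent": ["", ""],
            }))

    def test_matrix_assignment(self, demo_data):
        """Markers placed on the true clade stems label every sample."""
        truth = demo_data.truth
        stem_a = truth.branch_sites[frozenset(CLADE_A)]
        stem_b = truth.branch_sites[frozenset(CLADE_B)]
        mt = phylo.MarkerTable(pd.DataFrame({
            "marker": ["MA", "MB"],
            "position": [int(stem_a[0]), int(stem_b[0])],
            "haplogroup": ["C", "C5"],
            "parent": ["", ""],
        }))
        got = phylo.assign_haplogroups(demo_data.matrix, mt)
        for s in CLADE_A:
            assert got[s] in ("C-MA", "unassigned")  # unassigned iff masked
        high_cov = [s for s in CLADE_A if demo_data.config.coverage_of(s) == 1.0]
        assert all(got[s] == "C-MA" for s in high_cov)
        assert got["OUT1"] == "unassigned"


class TestMonophylyProperty:
    def test_deep_clades_monophyletic_at_full_scale(self):
        """Clades split 54 kya at L=1e7 are monophyletic in the NJ tree."""
        ok = 0
        for seed in range(10):
            data = simdata.simulate_snv_dataset(
                simdata.demo_config(seed=100 + seed, L=10_000_000))
            ht = build_htree(data)
            ok += ht.is_monophyletic(CLADE_A) and ht.is_monophyletic(CLADE_B)
        assert ok == 10
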