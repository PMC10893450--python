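"""NJ gene trees, minimal-duplication rooting, LCA reconciliation and
WGD calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
import wgdscan as w
from wgdscan.reconcile import (
    GeneTree, SpeciesTree, TreeNode, neighbor_joining, species_of_gene,
)

SP_NEWICK = "((A:1,B:1)AB:1,(C:1,O:1)CO:1)R;"


@pytest.fixture(scope="module")
def stree():
    return SpeciesTree(SP_NEWICK)


def gene_tree_from_newick(nwk):
    return GeneTree(root=TreeNode.from_newick(nwk), rooted=True)


class TestSpeciesTree:
    def test_nodes_and_masks(self, stree):
        assert set(stree.nodes) == {"A", "B", "C", "O", "AB", "CO", "R"}
        assert stree.mask["AB"] == stree.mask["A"] | stree.mask["B"]
        assert stree.mask["R"] == sum(stree.tip_mask(t) for t in "ABCO")

    def test_lca_queries(self, stree):
        assert stree.lca_of_mask(stree.tip_mask("A")).name == "A"
        assert stree.lca_of_mask(stree.tip_mask("A") | stree.tip_mask("B")).name == "AB"
        assert stree.lca_of_mask(stree.tip_mask("A") | stree.tip_mask("C")).name == "R"

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTree("(A:1,B:1,C:1)R;")


class TestNeighborJoining:
    def test_recovers_additive_four_leaf_topology(self):
        # additive distances on ((a,b),(c,d)): internal edge length 2
        labels = ["a", "b", "c", "d"]
        dist = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ], dtype=float)
        root = neighbor_joining(dist, labels)
        splits = set()
        for n in root.walk():
            if not n.is_leaf and n is not root:
                splits.add(frozenset(l.name for l in n.leaves()))
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits
        # least-squares check against the 3 possible unrooted topologies:
        # the ab|cd split is the only one consistent with the distances
        assert frozenset({"a", "c"}) not in splits
        assert frozenset({"a", "d"}) not in splits

    def test_three_leaves_unique_topology(self):
        dist = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        root = neighbor_joining(dist, ["x", "y", "z"])
        assert len(root.children) == 3
        assert sorted(l.name for l in root.leaves()) == ["x", "y", "z"]

    def test_identical_sequences_resolve_deterministically(self):
        dist = np.zeros((4, 4))
        labels = ["p", "q", "r", "s"]
        t1 = neighbor_joining(dist, labels).newick()
        t2 = neighbor_joining(dist, labels).newick()
        assert t1 == t2

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_build_from_cds(self, clean_dataset):
        fam = sorted(set(clean_dataset.families.values()))[0]
        cds = {g: s for sp in clean_dataset.collections.values()
               for g, s in sp.items() if clean_dataset.families[g] == fam}
        tree = w.build_nj_gene_tree(cds)
        assert not tree.rooted
        assert sorted(l.name for l in tree.root.leaves()) == sorted(cds)


class TestRooting:
    def test_congruent_tree_roots_to_zero_duplications(self, stree):
        nwk = "((a1:1,b1:1):1,(c1:1,o1:1):1);"
        unrooted = GeneTree(root=TreeNode.from_newick(nwk), rooted=False)
        rooted = w.root_gene_tree(unrooted, stree,
                                  species_of=lambda g: g[0].upper())
        events = w.reconcile(rooted, stree, species_of=lambda g: g[0].upper())
        assert events == []

    def test_single_duplication_recovered(self, stree):
        # true history: duplication at AB retained in both species
        nwk = "(((a1:1,b1:1):1,(a2:1,b2:1):1):1,o1:2);"
        unrooted = GeneTree(root=TreeNode.from_newick(nwk), rooted=False)
        rooted = w.root_gene_tree(unrooted, stree,
                                  species_of=lambda g: g[0].upper())
        events = w.reconcile(rooted, stree, species_of=lambda g: g[0].upper())
        assert len(events) == 1
        assert events[0].species_node == "AB"
        assert events[0].type == "AB_AB"

    def test_single_species_family_maps_to_tip(self, stree):
        nwk = "((a1:1,a2:1):1,a3:2);"
        unrooted = GeneTree(root=TreeNode.from_newick(nwk), rooted=False)
        rooted = w.root_gene_tree(unrooted, stree,
                                  species_of=lambda g: "A")
        events = w.reconcile(rooted, stree, species_of=lambda g: "A")
        assert all(e.species_node == "A" for e in events)
        assert len(events) == 2


class TestReconcile:
    def test_congruent_single_copy_family_has_no_events(self, stree):
        gt = gene_tree_from_newick("((a1:1,b1:1):1,(c1:1,o1:1):1);")
        events = w.reconcile(gt, stree, species_of=lambda g: g[0].upper())
        assert events == []

    def test_abab_duplication_at_mrca(self, stree):
        gt = gene_tree_from_newick("(((a1:1,b1:1):1,(a2:1,b2:1):1):1,o1:2);")
        events = w.reconcile(gt, stree, species_of=lambda g: g[0].upper())
        assert len(events) == 1
        assert (events[0].species_node, events[0].type) == ("AB", "AB_AB")

    def test_single_species_duplication_maps_to_tip(self, stree):
        # LCA mapping places the (a1,a2) duplication at tip A, not at
        # MRCA(A,B): only species A retains both copies
        gt = gene_tree_from_newick("((a1:1,a2:1):1,b1:2);")
        events = w.reconcile(gt, stree, species_of=lambda g: g[0].upper())
        assert len(events) == 1
        assert (events[0].species_node, events[0].type) == ("A", "other")

    def test_partial_retention_at_mrca_typed_other(self, stree):
        # duplication at MRCA(A,B) where one copy survives only in A
        gt = gene_tree_from_newick("(((a1:1,b1:1):1,a2:2):1,o1:3);")
        events = w.reconcile(gt, stree, species_of=lambda g: g[0].upper())
        assert len(events) == 1
        assert (events[0].species_node, events[0].type) == ("AB", "other")

    def test_low_support_duplications_discarded(self, stree):
        gt = gene_tree_from_newick("(((a1:1,b1:1)30:1,(a2:1,b2:1)90:1)95:1,o1:2);")
        # the duplication node is the one with support 95 (maps to AB like
        # its children); drop it by raising the threshold above 95
        ev_kept = w.reconcile(gt, stree, support_threshold=50,
                              species_of=lambda g: g[0].upper())
        ev_dropped = w.reconcile(gt, stree, support_threshold=96,
                                 species_of=lambda g: g[0].upper())
        assert len(ev_kept) == 1
        assert len(ev_dropped) == 0

    def test_unknown_species_reported(self, stree):
        gt = gene_tree_from_newick("((x1:1,b1:1):1,o1:2);")
        with pytest.raises(KeyError, match="X"):
            w.reconcile(gt, stree, species_of=lambda g: g[0].upper())

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle_on_random_trees(self, stree, seed):
        """LCA reconciliation equals a naive oracle on random gene trees."""
        gen = np.random.default_rng(seed)
        n_leaves = int(gen.integers(2, 9))
        species = [str(s) for s in gen.choice(list("ABCO"), size=n_leaves)]
        counts = {}
        leaves = []
        for s in species:
            counts[s] = counts.get(s, 0) + 1
            leaves.append(TreeNode(name=f"{s.lower()}{counts[s]}"))
        while len(leaves) > 1:
            i, j = sorted(gen.choice(len(leaves), size=2, replace=False))
            parent = TreeNode()
            parent.add(leaves[i])
            parent.add(leaves[j])
            leaves = [l for k, l in enumerate(leaves) if k not in (i, j)] + [parent]
        gt = GeneTree(root=leaves[0], rooted=True)
        sp_of = lambda g: g[0].upper()
        events = w.reconcile(gt, stree, species_of=sp_of)
        got = sorted(
            (frozenset(l.name for l in e.gene_node.leaves()), e.species_node, e.type)
            for e in events
        )
        expected = oracles.reconcile_oracle(gt.root, stree.root, sp_of)
        assert got == expected


class TestSummaryAndCalling:
    def test_empty_events_all_zero(self, stree):
        summary = w.summarize_gd([], 100, stree)
        assert (summary.table["gd_count"] == 0).all()
        flagged = w.call_wgd(summary)
        assert not flagged.table["wgd_flag"].any()

    def test_abab_percent_arithmetic(self, stree):
        gt_ab = gene_tree_from_newick("(((a1:1,b1:1):1,(a2:1,b2:1):1):1,o1:2);")
        gt_other = gene_tree_from_newick("(((a1:1,b1:1):1,a2:2):1,o1:3);")
        events = []
        for i in range(4):
            events += w.reconcile(gt_ab, stree, family=f"f{i}",
                                  species_of=lambda g: g[0].upper())
        for i in range(6):
            events += w.reconcile(gt_other, stree, family=f"g{i}",
                                  species_of=lambda g: g[0].upper())
        summary = w.summarize_gd(events, 10, stree)
        row = summary.table.loc["AB"]
        assert row["gd_count"] == 10
        assert row["abab_percent"] == pytest.approx(40.0)

    @pytest.mark.parametrize(
        "gd,ratio,abab,expected",
        [
            (500, 5.0, 60.0, 1),      # criterion 1
            (1200, 5.5, 25.0, 2),     # criterion 2
            (450, 10.0, 90.0, None),  # 450 is not > 450: strict inequality
            (451, 4.5, 90.0, None),   # ratio not strictly above 4.5
            (2000, 6.0, 15.0, None),  # abab too low for either
        ],
    )
    def test_dual_threshold_criteria(self, stree, gd, ratio, abab, expected):
        n_families = int(round(100 * gd / ratio))
        table = w.summarize_gd([], n_families, stree).table
        table.loc["AB", ["gd_count", "gd_ratio", "abab_percent"]] = [gd, ratio, abab]
        summary = w.ReconciliationSummary(table=table, n_families=n_families)
        flagged = w.call_wgd(summary, criteria="paper")
        hit = flagged.table.loc["AB", "criterion_hit"]
        assert (hit if pd.notna(hit) else None) == expected

    def test_root_never_autoflagged(self, stree):
        table = w.summarize_gd([], 1000, stree).table
        table.loc["R", ["gd_count", "gd_ratio", "abab_percent"]] = [5000, 500.0, 90.0]
        summary = w.ReconciliationSummary(table=table, n_families=1000)
        flagged = w.call_wgd(summary, criteria="paper")
        assert not flagged.table.loc["R", "wgd_flag"]

    def test_scaled_mode_rescales_counts_only(self, stree):
        # 500 families: scaled criterion 1 needs gd > 22.5, same ratio/abab
        table = w.summarize_gd([], 500, stree).table
        table.loc["AB", ["gd_count", "gd_ratio", "abab_percent"]] = [30, 6.0, 80.0]
        summary = w.ReconciliationSummary(table=table, n_families=500)
        assert w.call_wgd(summary, criteria="scaled").table.loc["AB", "wgd_flag"]
        assert not w.call_wgd(summary, criteria="paper").table.loc["AB", "wgd_flag"]


class TestExtractDuplicates:
    def test_cross_subtree_pairs(self, stree):
        gt = gene_tree_from_newick("(((a1:1,b1:1):1,(a2:1,b2:1):1):1,o1:2);")
        events = w.reconcile(gt, stree, family="f1",
                             species_of=lambda g: g[0].upper())
        pairs = w.extract_wgd_duplicates(events, "AB",
                                         species_of=lambda g: g[0].upper())
        assert ("f1", "AB", "A", "a1", "a2") in pairs
        assert ("f1", "AB", "B", "b1", "b2") in pairs
        assert len(pairs) == 2

    def test_node_without_events_warns_empty(self, stree, caplog):
        assert w.extract_wgd_duplicates([], "AB") == []

    def test_planted_dataset_pairs_match_truth(self, planted_dataset,
                                               four_taxon_newick):
        from wgdscan.pipeline import reconcile_dataset

        stree = SpeciesTree(four_taxon_newick)
        events, _ = reconcile_dataset(planted_dataset, stree)
        pairs = w.extract_wgd_duplicates(events, "AB")
        truth = planted_dataset.truth
        wgd_truth = {
            tuple(sorted((a, b)))
            for a, b, o in zip(truth.gene_a, truth.gene_b, truth.origin)
            if o == "e1" and a.split("|")[0] == b.split("|")[0]
        }
        got = {(a, b) for (_f, _n, _s, a, b) in pairs}
        if got:
            precision = len(got & wgd_truth) / len(got)
            assert precision >= 0.9
        assert len(got & wgd_truth) >= 0.8 * len(wgd_truth)
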