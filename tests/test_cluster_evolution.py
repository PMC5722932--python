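import numpy as np
import pytest

import syntenycamp as sc
from syntenycamp.cluster_evolution import (
    PresenceMatrix,
    build_presence_matrix,
    classify_disruption,
    date_node,
    dollo_reconstruct,
    reconcile_duplications,
)
from syntenycamp.datasets import CNIDARIAN_BILATERIAN_CLADE, HUMAN_CLUSTERS
from syntenycamp.genome_io import GeneRecord, GenomeAnnotation
from syntenycamp.microsynteny import PairCriteria, detect_pairs
from syntenycamp.trees import SpeciesTree

from conftest import brute_force_duplications, exhaustive_dollo_min_losses, random_binary_tree


def gene(gid, start, end, scaffold="1", strand="+", family="other", group="", species="sp"):
    return GeneRecord(gid, species, scaffold, start, end, strand, group or gid, family)


class TestBuildPresenceMatrix:
    def test_detected_pairs_marked_present(self, human_annotation):
        pairs = {"H_sapiens": detect_pairs(human_annotation), "other_sp": []}
        m = build_presence_matrix(pairs, HUMAN_CLUSTERS, missing_policy="absent")
        assert all(m.state(c, "H_sapiens") == "present" for c in HUMAN_CLUSTERS)
        assert all(m.state(c, "other_sp") == "absent" for c in HUMAN_CLUSTERS)

    def test_unknown_policy_for_missing(self, human_annotation):
        pairs = {"sp1": []}
        m = build_presence_matrix(pairs, HUMAN_CLUSTERS, missing_policy="unknown")
        assert all(m.state(c, "sp1") == "unknown" for c in HUMAN_CLUSTERS)

    def test_empty_pair_sets_all_absent(self):
        m = build_presence_matrix({"a": [], "b": []}, HUMAN_CLUSTERS)
        assert (m.df == "absent").all().all()

    def test_unmappable_pair_raises(self, human_annotation):
        pairs = {"H_sapiens": detect_pairs(human_annotation)}
        with pytest.raises(ValueError, match="no cluster label"):
            build_presence_matrix(pairs, {"only": ("X", "Y")})


class TestDolloReconstruct:
    def test_gain_at_cnidarian_bilaterian_ancestor(self, fig1_presence, fig1_tree):
        rec = dollo_reconstruct(fig1_presence, fig1_tree, "primordial")
        assert rec.gain_branch == CNIDARIAN_BILATERIAN_CLADE
        assert frozenset({"D_melanogaster"}) in rec.losses

    def test_all_present_gain_at_root_no_losses(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        m = PresenceMatrix.from_dict(
            {"c": {s: "present" for s in "ABCD"}}, ["c"], list("ABCD")
        )
        rec = dollo_reconstruct(m, tree, "c")
        assert rec.gain_branch == tree.root
        assert rec.losses == frozenset()

    def test_unknown_leaves_do_not_become_losses(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        m = PresenceMatrix.from_dict(
            {"c": {"A": "present", "B": "unknown", "C": "present", "D": "unknown"}},
            ["c"], list("ABCD"),
        )
        rec = dollo_reconstruct(m, tree, "c")
        assert rec.losses == frozenset()
        assert rec.ancestral_state[frozenset("B")] == "present"

    def test_no_present_leaf_rejected(self, fig1_tree):
        m = PresenceMatrix.from_dict({"c": {}}, ["c"], sorted(fig1_tree.leaves))
        with pytest.raises(ValueError, match="no present leaf"):
            dollo_reconstruct(m, fig1_tree, "c")

    def test_losses_never_on_path_to_present_leaf(self, fig1_presence, fig1_tree):
        for cluster in fig1_presence.clusters:
            rec = dollo_reconstruct(fig1_presence, fig1_tree, cluster)
            present = fig1_presence.leaves_in_state(cluster, "present")
            for leaf in present:
                path = fig1_tree.path_to_root(frozenset([leaf]))
                assert not (set(path) & rec.losses)

    def test_adding_present_leaf_moves_gain_rootward(self, fig1_tree):
        base = {"H_sapiens": "present", "L_oculatus": "present"}
        m1 = PresenceMatrix.from_dict({"c": base}, ["c"], sorted(fig1_tree.leaves))
        g1 = dollo_reconstruct(m1, fig1_tree, "c").gain_branch
        m2 = PresenceMatrix.from_dict(
            {"c": {**base, "N_vectensis": "present"}}, ["c"], sorted(fig1_tree.leaves)
        )
        g2 = dollo_reconstruct(m2, fig1_tree, "c").gain_branch
        assert g1 <= g2

    def test_matches_exhaustive_minimum(self):
        """Loss count equals the exhaustive minimum over all single-gain
        placements, over random trees of <= 8 leaves and random states."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            tree = random_binary_tree(rng, n)
            leaves = sorted(tree.leaves)
            states = rng.choice(["present", "absent", "unknown"], size=n, p=[0.45, 0.35, 0.2])
            if "present" not in states:
                states[int(rng.integers(n))] = "present"
            assignment = dict(zip(leaves, states))
            m = PresenceMatrix.from_dict({"c": assignment}, ["c"], leaves)
            rec = dollo_reconstruct(m, tree, "c")
            oracle = exhaustive_dollo_min_losses(
                tree,
                [l for l, s in assignment.items() if s == "present"],
                [l for l, s in assignment.items() if s == "absent"],
            )
            assert len(rec.losses) == oracle


class TestReconcileDuplications:
    def test_three_paralog_tree_two_duplications(self, fig1_tree):
        from syntenycamp.datasets import VERTEBRATES, cluster_tree_fig2

        for nesting in ("PDIA1-first", "PDIA2-first"):
            ctree, leaf_map = cluster_tree_fig2(nesting)
            rec = reconcile_duplications(ctree, fig1_tree, leaf_map)
            assert rec.duplication_count == 2
            vert = fig1_tree.mrca(VERTEBRATES)
            assert all(rec.lca_map[n] == vert for n in rec.duplication_nodes)

    def test_congruent_trees_no_duplications(self):
        sp = SpeciesTree.from_newick("((A,B),(C,D));")
        ct = SpeciesTree.from_newick("((a,b),(c,d));")
        rec = reconcile_duplications(ct, sp, {"a": "A", "b": "B", "c": "C", "d": "D"})
        assert rec.duplication_count == 0

    def test_polytomy_rejected(self):
        sp = SpeciesTree.from_newick("((A,B),C);")
        ct = SpeciesTree.from_newick("(a,b,c);")
        with pytest.raises(ValueError, match="polytomy"):
            reconcile_duplications(ct, sp, {"a": "A", "b": "B", "c": "C"})

    def test_unmapped_leaf_rejected(self):
        sp = SpeciesTree.from_newick("(A,B);")
        ct = SpeciesTree.from_newick("(a,b);")
        with pytest.raises(KeyError, match="without species mapping"):
            reconcile_duplications(ct, sp, {"a": "A"})

    def test_child_swap_and_relabel_invariance(self):
        sp = SpeciesTree.from_newick("((A,B),C);")
        ct1 = SpeciesTree.from_newick("((x1,y1),((x2,y2),z));")
        ct2 = SpeciesTree.from_newick("(((y2,x2),z),(y1,x1));")
        lm = {"x1": "A", "y1": "B", "x2": "A", "y2": "B", "z": "C"}
        r1 = reconcile_duplications(ct1, sp, lm)
        r2 = reconcile_duplications(ct2, sp, lm)
        assert r1.duplication_count == r2.duplication_count

    def test_brute_force_oracle_random_trees(self):
        """Duplication sets match an independent path-intersection LCA
        reconciliation on random binary trees up to 8 leaves."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            n_sp = int(rng.integers(2, 6))
            sp = random_binary_tree(rng, n_sp, labels=[f"S{i}" for i in range(n_sp)])
            n_gene = int(rng.integers(2, 9))
            gene_labels = [f"g{i}" for i in range(n_gene)]
            ct = random_binary_tree(rng, n_gene, labels=gene_labels)
            leaf_map = {g: f"S{int(rng.integers(n_sp))}" for g in gene_labels}
            rec = reconcile_duplications(ct, sp, leaf_map)
            assert rec.duplication_nodes == frozenset(brute_force_duplications(ct, sp, leaf_map))


class TestClassifyDisruption:
    members = {"c": ("PDI_c", "GDI_c")}
    criteria = PairCriteria()

    def test_same_scaffold_megabase_apart_is_unlinked(self):
        ann = GenomeAnnotation("fly", [
            gene("p", 1_000, 2_000, family="PDI", group="PDI_c"),
            gene("g", 2_000_000, 2_001_000, family="RhoGDI", group="GDI_c"),
        ])
        call = classify_disruption("fly", "c", ann, self.criteria, self.members)
        assert call.mode == "unlinked_same_scaffold"

    def test_different_scaffold_unlinked(self):
        ann = GenomeAnnotation("sp", [
            gene("p", 1_000, 2_000, family="PDI", group="PDI_c"),
            gene("g", 1_000, 2_000, scaffold="2", family="RhoGDI", group="GDI_c"),
        ])
        call = classify_disruption("sp", "c", ann, self.criteria, self.members)
        assert call.mode == "unlinked_different_scaffold"

    def test_partner_unannotated_is_one_gene_lost(self):
        # mirrors a genome carrying only the RhoGDI member of a pair
        ann = GenomeAnnotation("coelacanth", [
            gene("g", 1_000, 2_000, family="RhoGDI", group="GDI_c"),
        ])
        call = classify_disruption("coelacanth", "c", ann, self.criteria, self.members)
        assert call.mode == "one_gene_lost"

    def test_both_members_missing(self):
        ann = GenomeAnnotation("sp", [gene("bg", 10, 20)])
        call = classify_disruption("sp", "c", ann, self.criteria, self.members)
        assert call.mode == "both_genes_lost"

    def test_intact_pair(self):
        ann = GenomeAnnotation("sp", [
            gene("p", 1_000, 2_000, family="PDI", group="PDI_c"),
            gene("g", 2_500, 3_500, family="RhoGDI", group="GDI_c"),
        ])
        call = classify_disruption("sp", "c", ann, self.criteria, self.members)
        assert call.mode == "intact"


class TestDateNode:
    def test_annotated_ancestor_age(self, fig1_tree):
        assert date_node(fig1_tree, CNIDARIAN_BILATERIAN_CLADE) == 820.0

    def test_unannotated_node_is_unknown(self, fig1_tree):
        assert date_node(fig1_tree, fig1_tree.root) is None

    def test_leaf_annotated_zero(self):
        tree = SpeciesTree.from_newick("(A,B);", ages={frozenset("A"): 0.0})
        assert date_node(tree, {"A"}) == 0.0

    def test_missing_node_rejected(self, fig1_tree):
        with pytest.raises(KeyError):
            date_node(fig1_tree, {"H_sapiens", "N_vectensis"})
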