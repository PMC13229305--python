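"""Neighbor-joining, rooting, bootstrap and strain-clade extraction."""

import dendropy
import numpy as np
import pytest

from fawstrain.phylo import (
    DistanceMatrix,
    _nontrivial_bipartitions,
    bootstrap_support,
    distance_matrix,
    extract_strain_clade,
    nj_tree,
    node_supports,
    root_with_outgroup,
)
from fawstrain.seqdata import HostClass, MarkerAlignment, SequenceRecord

from conftest import small_config


def tip_lengths(tree):
    return {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }


def bipartition_set(tree):
    return set(_nontrivial_bipartitions(tree).values())


def make_alignment(segment, seqs_by_id, outgroup_id=None):
    records = [SequenceRecord(sid, segment.marker, s) for sid, s in seqs_by_id.items()]
    return MarkerAlignment(
        segment, records, list(range(1, len(records[0].residues) + 1)), outgroup_id
    )


class TestNJTree:
    def test_three_taxon_pendant_lengths(self):
        d = np.array([[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = tip_lengths(tree)
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_matrix_exactly_recovered(self):
        # true unrooted tree: (A,B)|(C,D) with pendant 0.1/0.2/0.3/0.4,
        # internal edge 0.1
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.3, 0.5, 0.6],
                [0.3, 0.0, 0.6, 0.7],
                [0.5, 0.6, 0.0, 0.7],
                [0.6, 0.7, 0.7, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(taxa, d))
        assert frozenset({"C", "D"}) in bipartition_set(tree) or frozenset(
            {"A", "B"}
        ) in bipartition_set(tree)
        lengths = tip_lengths(tree)
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.3)
        assert lengths["D"] == pytest.approx(0.4)
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal == pytest.approx([0.1])

    def test_all_zero_matrix_degenerate_but_valid(self):
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4))))
        assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == ["a", "b", "c", "d"]
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    @staticmethod
    def random_binary_tree(rng, n):
        """Random binary tree with strictly positive branch lengths."""
        labels = [f"L{i}" for i in range(n)]
        ns = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node.taxon = ns.get_taxon(labels[0])
        leaves = [tree.seed_node]
        next_label = 1
        while next_label < n:
            leaf = leaves.pop(int(rng.integers(0, len(leaves))))
            taxon = leaf.taxon
            leaf.taxon = None
            a = leaf.new_child(taxon=taxon, edge_length=float(rng.uniform(0.05, 0.5)))
            b = leaf.new_child(
                taxon=ns.get_taxon(labels[next_label]),
                edge_length=float(rng.uniform(0.05, 0.5)),
            )
            next_label += 1
            leaves.extend([a, b])
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = float(rng.uniform(0.05, 0.5))
        tree.is_rooted = False
        return tree, labels

    def test_recovers_random_additive_trees(self, rng):
        """NJ reproduces any additive matrix exactly (100 random 6-10 leaf trees)."""
        for _ in range(100):
            n = int(rng.integers(6, 11))
            true_tree, labels = self.random_binary_tree(rng, n)
            ns = true_tree.taxon_namespace
            pdm_true = true_tree.phylogenetic_distance_matrix()
            dist = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    dist[a, b] = dist[b, a] = pdm_true.patristic_distance(
                        ns.get_taxon(labels[a]), ns.get_taxon(labels[b])
                    )
            nj = nj_tree(DistanceMatrix(labels, dist))
            pdm_nj = nj.phylogenetic_distance_matrix()
            ns2 = nj.taxon_namespace
            for a in range(n):
                for b in range(a + 1, n):
                    got = pdm_nj.patristic_distance(
                        ns2.get_taxon(labels[a]), ns2.get_taxon(labels[b])
                    )
                    assert got == pytest.approx(dist[a, b], abs=1e-9)
            assert bipartition_set(nj) == bipartition_set(true_tree)


class TestRooting:
    def make_tree(self):
        d = np.array(
            [
                [0.0, 0.3, 0.5, 0.9],
                [0.3, 0.0, 0.6, 1.0],
                [0.5, 0.6, 0.0, 1.1],
                [0.9, 1.0, 1.1, 0.0],
            ]
        )
        return nj_tree(DistanceMatrix(["A", "B", "C", "OG"], d))

    def test_ingroup_is_taxa_minus_outgroup(self):
        rooted = root_with_outgroup(self.make_tree(), "OG")
        ingroup = {
            lf.taxon.label for lf in rooted.leaf_node_iter() if lf.taxon.label != "OG"
        }
        assert ingroup == {"A", "B", "C"}
        # root splits the outgroup pendant edge in half
        og = [lf for lf in rooted.leaf_node_iter() if lf.taxon.label == "OG"][0]
        assert og.parent_node is rooted.seed_node

    def test_rerooting_idempotent(self):
        r1 = root_with_outgroup(self.make_tree(), "OG")
        r2 = root_with_outgroup(r1, "OG")
        assert bipartition_set(r1) == bipartition_set(r2)
        assert {lf.taxon.label: lf.edge.length for lf in r1.leaf_node_iter()} == {
            lf.taxon.label: lf.edge.length for lf in r2.leaf_node_iter()
        }

    def test_unknown_outgroup_raises(self):
        with pytest.raises(ValueError, match="nope"):
            root_with_outgroup(self.make_tree(), "nope")

    def test_simulated_two_clade_cohort_separates_at_root(self):
        from fawstrain.simulate import OUTGROUP_ID, simulate_cohort

        cfg = small_config(seed=4, n=6, male_fraction=0.0, host_misassignment_rate=0.0,
                           strain_divergence=0.08)
        co = simulate_cohort(cfg)
        seg = cfg.segment_defs[0]
        recs = co.sequences[seg.segment_name]
        aln = MarkerAlignment(
            seg, recs, list(range(1, seg.segment_length_nominal + 1)), OUTGROUP_ID
        )
        rooted = root_with_outgroup(nj_tree(distance_matrix(aln)), OUTGROUP_ID)
        truth = co.truth[co.truth["segment"] == seg.segment_name]
        strain_of = dict(zip(truth["specimen_id"], truth["true_strain"]))
        # the planted C clade must be monophyletic in the rooted tree,
        # i.e. it arises from a single branchpoint
        c_tips = {s for s, v in strain_of.items() if v == "C"}
        clades = set()
        for node in rooted.preorder_node_iter():
            if not node.is_leaf():
                clades.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
        assert frozenset(c_tips) in clades


class TestBootstrap:
    def make_informative_alignment(self, toy_segment, rng, n_per_clade=4, n_diag=10):
        L = toy_segment.segment_length_nominal
        base = "".join(rng.choice(list("ACGT"), L))
        clade_seq = list(base)
        diag_cols = rng.choice(L, size=n_diag, replace=False)
        for c in diag_cols:
            clade_seq[c] = {"A": "G", "G": "A", "C": "T", "T": "C"}[clade_seq[c]]
        def with_noise(src):
            noisy = list(src)
            for j in rng.choice(L, size=2, replace=False):
                if j not in diag_cols:
                    noisy[j] = rng.choice([c for c in "ACGT" if c != noisy[j]])
            return "".join(noisy)

        seqs = {}
        for i in range(n_per_clade):
            seqs[f"r{i}"] = with_noise(base)
        for i in range(n_per_clade):
            seqs[f"c{i}"] = with_noise(clade_seq)
        return make_alignment(toy_segment, seqs), {f"c{i}" for i in range(n_per_clade)}

    def test_identical_sequences_supports_zero_no_crash(self, toy_segment):
        aln = make_alignment(toy_segment, {f"s{i}": "ACGT" * 15 for i in range(5)})
        tree = bootstrap_support(aln, B=10, seed=1)
        for bip, support in node_supports(tree).items():
            assert support == 0.0

    def test_same_seed_same_supports(self, toy_segment, rng):
        aln, _ = self.make_informative_alignment(toy_segment, rng)
        t1 = bootstrap_support(aln, B=25, seed=9)
        t2 = bootstrap_support(aln, B=25, seed=9)
        assert node_supports(t1) == node_supports(t2)

    def test_b_zero_rejected(self, toy_segment):
        aln = make_alignment(toy_segment, {f"s{i}": "ACGT" * 15 for i in range(4)})
        with pytest.raises(ValueError, match="B"):
            bootstrap_support(aln, B=0)

    def test_planted_clade_full_support(self, toy_segment, rng):
        """10 fixed diagnostic columns: the clade survives every resample."""
        aln, clade = self.make_informative_alignment(toy_segment, rng, n_diag=10)
        tree = bootstrap_support(aln, B=100, seed=3)
        supports = node_supports(tree)
        all_tips = {r.specimen_id for r in aln.records}
        key = frozenset(clade)
        if min(all_tips) in key:
            key = frozenset(all_tips - clade)
        assert supports[key] == 100.0

    def test_supports_invariant_to_taxon_order(self, toy_segment, rng):
        aln, _ = self.make_informative_alignment(toy_segment, rng)
        reversed_aln = MarkerAlignment(
            aln.segment, list(reversed(aln.records)), list(aln.column_map), None
        )
        s1 = node_supports(bootstrap_support(aln, B=20, seed=5))
        s2 = node_supports(bootstrap_support(reversed_aln, B=20, seed=5))
        assert s1 == s2


class TestExtractStrainClade:
    def tree_from_newick(self, s):
        return dendropy.Tree.get(data=s, schema="newick")

    def test_concordant_labels_perfect_partition(self):
        tree = self.tree_from_newick("((c1:1,c2:1,c3:1):1,(r1:1,r2:1):1):0;")
        labels = {
            "c1": HostClass.C_HOST,
            "c2": HostClass.C_HOST,
            "c3": HostClass.C_HOST,
            "r1": HostClass.R_HOST,
            "r2": HostClass.R_HOST,
        }
        part = extract_strain_clade(tree, labels)
        assert part.c_clade_ids == frozenset({"c1", "c2", "c3"})
        assert part.purity == 1.0 and part.recall == 1.0

    def test_one_discordant_tip_purity(self):
        tips = [f"c{i}" for i in range(10)] + ["rx"]
        newick = "((" + ",".join(f"{t}:1" for t in tips) + "):1,(r1:1,r2:1):1):0;"
        tree = self.tree_from_newick(newick)
        labels = {t: HostClass.C_HOST for t in tips[:-1]}
        labels.update({"rx": HostClass.R_HOST, "r1": HostClass.R_HOST, "r2": HostClass.R_HOST})
        part = extract_strain_clade(tree, labels)
        assert part.c_clade_ids == frozenset(tips)
        assert part.purity == pytest.approx(10 / 11)
        assert part.recall == 1.0

    def test_degenerate_labeling_rejected(self):
        tree = self.tree_from_newick("((a:1,b:1):1,(c:1,d:1):1):0;")
        labels = {t: HostClass.C_HOST for t in "abcd"}
        with pytest.raises(ValueError, match="degenerate"):
            extract_strain_clade(tree, labels)

    def test_selected_clade_is_monophyletic(self):
        tree = self.tree_from_newick("(((c1:1,c2:1):1,r1:1):1,(r2:1,c3:1):1):0;")
        labels = {
            "c1": HostClass.C_HOST,
            "c2": HostClass.C_HOST,
            "c3": HostClass.C_HOST,
            "r1": HostClass.R_HOST,
            "r2": HostClass.R_HOST,
        }
        part = extract_strain_clade(tree, labels)
        # the chosen set must be exactly some internal node's tip set
        clades = set()
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                clades.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
        assert part.c_clade_ids in clades

    def test_misassigned_cohort_purity_recall_band(self):
        """At 5% host misassignment, mean purity/recall stay in [0.90, 1.0]."""
        from fawstrain.simulate import OUTGROUP_ID, simulate_cohort

        purities, recalls = [], []
        for seed in range(12):
            cfg = small_config(
                seed=seed, n=8, male_fraction=0.0, host_misassignment_rate=0.05
            )
            co = simulate_cohort(cfg)
            seg = cfg.segment_defs[0]
            recs = co.sequences[seg.segment_name]
            aln = MarkerAlignment(
                seg, recs, list(range(1, seg.segment_length_nominal + 1)), OUTGROUP_ID
            )
            rooted = root_with_outgroup(nj_tree(distance_matrix(aln)), OUTGROUP_ID)
            labels = {s.id: s.host_class for s in co.specimens}
            part = extract_strain_clade(rooted, labels)
            purities.append(part.purity)
            recalls.append(part.recall)
        assert 0.90 <= np.mean(purities) <= 1.0
        assert 0.90 <= np.mean(recalls) <= 1.0
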