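import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from mitolocus.alignment_io import TaxonomyTable
from mitolocus.distances import DistanceMatrix
from mitolocus.errors import InputError, TreeError
from mitolocus.phylogeny import congruence, max_pure_subset, nj_tree


def tree_from_newick(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def path_length_matrix(tree, ids):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return mat


def rf_distance(newick_a, newick_b):
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=ns, preserve_underscores=True
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=ns, preserve_underscores=True
    )
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def random_additive_tree(n_taxa, rng):
    """Random binary unrooted tree with branch lengths in [0.1, 1]."""
    labels = [f"t{i}" for i in range(n_taxa)]
    newick_parts = {label: label for label in labels}
    active = list(labels)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        merged = f"({newick_parts[a]}:{la:.4f},{newick_parts[b]}:{lb:.4f})"
        key = a + b
        newick_parts[key] = merged
        active = [x for x in active if x not in (a, b)] + [key]
    a, b, c = active
    la, lb, lc = rng.uniform(0.1, 1.0, size=3)
    newick = (
        f"({newick_parts[a]}:{la:.4f},{newick_parts[b]}:{lb:.4f},"
        f"{newick_parts[c]}:{lc:.4f});"
    )
    return newick, labels


class TestNJ:
    def test_four_taxon_additive_exact_recovery(self):
        # matrix built from path lengths of ((A:1,B:2):1,(C:3,D:4):1)
        truth = "((A:1,B:2):1,(C:3,D:4):1);"
        tree = tree_from_newick(truth)
        ids = ["A", "B", "C", "D"]
        mat = DistanceMatrix(ids, path_length_matrix(tree, ids), "k2p")
        result = nj_tree(mat)
        out = result.as_string(schema="newick")
        assert rf_distance(out, truth) == 0
        # branch lengths recovered: pairwise path lengths match the input
        assert np.allclose(
            path_length_matrix(result, ids), mat.values, atol=1e-9
        )

    def test_three_taxon_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(DistanceMatrix(ids, d, "k2p"))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        # three-point formulas: a=(dab+dac-dbc)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_two_taxa_rejected(self):
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))

    def test_nonfinite_entry_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d, "k2p"))

    def test_tie_deterministic(self):
        # ultrametric with exchangeable taxa: repeated runs identical
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 1.0
        mat = DistanceMatrix(list("abcd"), d, "k2p")
        s1 = nj_tree(mat).as_string(schema="newick")
        s2 = nj_tree(mat).as_string(schema="newick")
        assert s1 == s2

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_randomized_additive_recovery(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            truth, labels = random_additive_tree(n_taxa, rng)
            tree = tree_from_newick(truth)
            mat = DistanceMatrix(labels, path_length_matrix(tree, labels), "k2p")
            result = nj_tree(mat)
            assert rf_distance(result.as_string(schema="newick"), truth) == 0

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        truth, labels = random_additive_tree(7, rng)
        tree = tree_from_newick(truth)
        values = path_length_matrix(tree, labels)
        ours = nj_tree(DistanceMatrix(labels, values, "k2p"))
        theirs = skbio_nj(SkbioDM(values, labels))
        assert (
            rf_distance(ours.as_string(schema="newick"), str(theirs)) == 0
        )


def simple_taxonomy(assignments):
    """assignments: sample_id -> (species, genus, family, order, superorder)."""
    rows = [
        {
            "sample_id": sid,
            "subspecies": "",
            "species": v[0],
            "genus": v[1],
            "family": v[2],
            "order": v[3],
            "superorder": v[4],
        }
        for sid, v in assignments.items()
    ]
    return TaxonomyTable(pd.DataFrame(rows))


class TestMaxPureSubset:
    def test_monophyletic_group_returned_whole(self):
        tree = tree_from_newick("((a,b),(c,d),e);")
        assert max_pure_subset(tree, {"a", "b"}) == {"a", "b"}

    def test_grafted_leaves_excluded(self):
        # group {a,b,c,d} with d grafted away among outsiders
        tree = tree_from_newick("(((a,b),c),((d,x),y),z);")
        assert max_pure_subset(tree, {"a", "b", "c", "d"}) == {"a", "b", "c"}

    def test_singleton_group(self):
        tree = tree_from_newick("((a,b),(c,d),e);")
        assert max_pure_subset(tree, {"e"}) == {"e"}

    def test_complement_side_considered(self):
        # the pure side for {c,d,e} is the complement of the (a,b) clade
        tree = tree_from_newick("((a,b),(c,d),e);")
        assert max_pure_subset(tree, {"c", "d", "e"}) == {"c", "d", "e"}

    def test_unknown_leaf_rejected(self):
        tree = tree_from_newick("((a,b),(c,d),e);")
        with pytest.raises(TreeError):
            max_pure_subset(tree, {"zz"})


class TestCongruence:
    def make_perfect_case(self):
        tree = tree_from_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        tax = simple_taxonomy(
            {
                sid: (
                    f"sp_{sid}",
                    f"g_{sid[0]}",
                    f"fam_{sid[0]}",
                    "ord_" + ("ab" if sid[0] in "ab" else "cd"),
                    "sup_all",
                )
                for sid in ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"]
            }
        )
        return tree, tax

    def test_perfect_tree_scores_100_everywhere(self):
        tree, tax = self.make_perfect_case()
        for rank in ("superorder", "order", "family", "genus"):
            for variant in ("per_sample", "species_collapsed"):
                report = congruence(tree, tax, rank, variant)
                assert report.overall_percent == pytest.approx(100.0)

    def test_partial_group_percentage(self):
        # 3-of-4 of family "fam_a" cluster; a2 is grafted among outsiders
        tree = tree_from_newick("(((a1,a3),a4),((a2,x1),x2),y1);")
        tax = simple_taxonomy(
            {
                sid: (f"sp_{sid}", "g", "fam_a" if sid.startswith("a") else "fam_x", "o", "s")
                for sid in ["a1", "a2", "a3", "a4", "x1", "x2", "y1"]
            }
        )
        report = congruence(tree, tax, "family", "per_sample")
        score = {g.label: g for g in report.groups}["fam_a"]
        assert score.n_members == 4 and score.n_correct == 3
        assert score.percent == pytest.approx(75.0)

    def test_subspecies_clade_counts_once_when_collapsed(self, bear_taxonomy):
        # five bear samples U1,U2,U3 conspecific; collapsed variant prunes
        tree = tree_from_newick("(((U1,U2),U3),(H1,B1));")
        per_sample = congruence(tree, bear_taxonomy, "genus", "per_sample")
        collapsed = congruence(tree, bear_taxonomy, "genus", "species_collapsed")
        ursus_ps = {g.label: g for g in per_sample.groups}["Ursus"]
        ursus_sc = {g.label: g for g in collapsed.groups}["Ursus"]
        assert ursus_ps.n_members == 3 and ursus_ps.n_correct == 3
        assert ursus_sc.n_members == 1 and ursus_sc.n_correct == 1

    def test_invariant_under_rerooting_and_leaf_order(self):
        tree, tax = self.make_perfect_case()
        scrambled = tree_from_newick("((d2,d1),((b2,b1),(a2,a1)),(c2,c1));")
        for rank in ("order", "family"):
            assert congruence(tree, tax, rank).overall_percent == pytest.approx(
                congruence(scrambled, tax, rank).overall_percent
            )

    def test_removing_outside_leaf_keeps_percents(self):
        tree = tree_from_newick("(((a1,a2),a3),((x1,x2),y1));")
        tax = simple_taxonomy(
            {
                sid: (f"sp_{sid}", "g", "fam_a" if sid.startswith("a") else "fam_x", "o", "s")
                for sid in ["a1", "a2", "a3", "x1", "x2", "y1"]
            }
        )
        pruned = tree.extract_tree_with_taxa_labels(["a1", "a2", "a3", "x1", "x2"])
        before = {g.label: g.percent for g in congruence(tree, tax, "family").groups}
        after = {g.label: g.percent for g in congruence(pruned, tax, "family").groups}
        assert after["fam_a"] == before["fam_a"]

    def test_unknown_rank_rejected(self):
        tree, tax = self.make_perfect_case()
        with pytest.raises(InputError):
            congruence(tree, tax, "tribe")
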