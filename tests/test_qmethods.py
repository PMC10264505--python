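import itertools
import random

import dendropy
import numpy as np
import pytest
from dendropy.simulate import treesim

from asaq.errors import MissingWeightError, UndefinedDistanceError
from asaq.qmethods import (
    QuartetWeightTable,
    binarize_weights,
    canonical_split_index,
    compute_weight_table,
    nj_paralinear,
    qp_build,
    rf_distance,
    run_and_consense,
    topological_leaf_distances,
    wil_build,
    wo_build,
)
from asaq.simulate import GMInstance, twelve_taxon_trees


def random_binary_tree(n_leaves, seed):
    tns = dendropy.TaxonNamespace([f"t{j}" for j in range(n_leaves)])
    return treesim.birth_death_tree(
        1.0, 0.0, num_extant_tips=n_leaves, taxon_namespace=tns, rng=random.Random(seed)
    )


class TestWeightTable:
    def test_tsv_roundtrip(self, tmp_path):
        t = QuartetWeightTable(["a", "b", "c", "d", "e"])
        t.set_weights(("a", "b", "c", "d"), [0.5, 0.3, 0.2], method="pl", tag="pl")
        t.set_weights(("a", "b", "c", "e"), [0.2, 0.2, 0.6], method="asaq", tag="saq")
        path = tmp_path / "w.tsv"
        t.to_tsv(path)
        back = QuartetWeightTable.from_tsv(path)
        assert np.allclose(back.get(("a", "b", "c", "d")), [0.5, 0.3, 0.2])
        assert back.meta(("a", "b", "c", "e")) == ("asaq", "saq")

    def test_missing_quartet_raises(self):
        t = QuartetWeightTable(["a", "b", "c", "d", "e"])
        with pytest.raises(MissingWeightError):
            t.get(("a", "b", "c", "d"))

    def test_binarize(self):
        t = QuartetWeightTable(["a", "b", "c", "d"])
        t.set_weights(("a", "b", "c", "d"), [0.5, 0.3, 0.2])
        b = t.binarize()
        assert np.array_equal(b.get(("a", "b", "c", "d")), [1.0, 0.0, 0.0])

    def test_binarize_tie_breaks_canonically_and_is_idempotent(self):
        t = QuartetWeightTable(["a", "b", "c", "d"])
        t.set_weights(("a", "b", "c", "d"), [1 / 3, 1 / 3, 1 / 3])
        b = binarize_weights(t)
        assert np.array_equal(b.get(("a", "b", "c", "d")), [1.0, 0.0, 0.0])
        bb = binarize_weights(b)
        assert np.array_equal(bb.get(("a", "b", "c", "d")), b.get(("a", "b", "c", "d")))

    def test_wqfm_export(self, tmp_path):
        t = QuartetWeightTable(["a", "b", "c", "d"])
        t.set_weights(("a", "b", "c", "d"), [0.5, 0.3, 0.2])
        out = tmp_path / "q.wqfm"
        t.to_wqfm(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "((a,b),(c,d)); 0.5"
        assert len(lines) == 3

    def test_canonical_split_index(self):
        q = ("a", "b", "c", "d")
        assert canonical_split_index(q, ("a", "b")) == 0
        assert canonical_split_index(q, ("c", "d")) == 0
        assert canonical_split_index(q, ("b", "d")) == 1
        assert canonical_split_index(q, ("a", "d")) == 2


class TestBuilders:
    def test_four_taxa_returns_max_weight_quartet(self):
        t = QuartetWeightTable(["a", "b", "c", "d"])
        t.set_weights(("a", "b", "c", "d"), [0.1, 0.8, 0.1])
        tree = wo_build(t, seed=0)
        assert rf_distance(tree, "((a,c),(b,d));") == 0

    @pytest.mark.parametrize("build", [wo_build, qp_build, wil_build])
    def test_correct_weights_recover_reference_tree(self, build):
        ref = random_binary_tree(9, seed=5)
        table = QuartetWeightTable.from_tree(ref)
        for seed in range(3):
            assert rf_distance(build(table, seed=seed), ref) == 0

    def test_label_permutation_equivariance(self):
        """Renaming taxa consistently in the table permutes the output tree."""
        ref = random_binary_tree(7, seed=11)
        table = QuartetWeightTable.from_tree(ref)
        mapping = {f"t{j}": f"x{j}" for j in range(7)}
        renamed = QuartetWeightTable([mapping[t] for t in table.taxa])
        for k, w in table.items():
            renamed.set_weights(tuple(mapping[t] for t in k), w)
        t1 = wo_build(table, seed=3)
        t2 = wo_build(renamed, seed=3)
        nwk1 = t1.as_string(schema="newick")
        for old, new in mapping.items():
            nwk1 = nwk1.replace(old, new)
        assert rf_distance(nwk1, t2) == 0


class TestConsensus:
    def test_identical_replicates_return_that_tree(self):
        ref = random_binary_tree(8, seed=2)
        table = QuartetWeightTable.from_tree(ref)
        cons = run_and_consense("wo", table, n_replicates=5, seed=1)
        assert rf_distance(cons, ref) == 0

    def test_half_half_conflict_drops_the_split(self):
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data="((a,b),(c,d),(e,f));", schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data="((a,c),(b,d),(e,f));", schema="newick", taxon_namespace=tns)
        trees = dendropy.TreeList([t1] * 5 + [t2] * 5, taxon_namespace=tns)
        cons = trees.consensus(min_freq=0.5 + 1e-9)
        cons.is_rooted = False
        cons.encode_bipartitions()
        n_internal = sum(
            1
            for e in cons.preorder_edge_iter()
            if e.head_node.parent_node is not None and not e.head_node.is_leaf()
        )
        assert n_internal == 1  # only the (e,f) split survives


class TestRF:
    def test_identical_trees(self):
        ref = random_binary_tree(12, seed=4)
        assert rf_distance(ref, ref.as_string(schema="newick")) == 0

    def test_nni_neighbor_is_two(self):
        a = "((a,b),((c,d),(e,f)));"
        b = "((a,(c,d)),(b,(e,f)));"  # one NNI across the ab|cdef edge
        assert rf_distance(a, b) == 2

    def test_matches_brute_force_bipartitions(self):
        cat = "(a,(b,(c,(d,(e,(f,(g,h)))))));"
        bal = "(((a,b),(c,d)),((e,f),(g,h)));"

        def bips(nwk):
            tns = dendropy.TaxonNamespace()
            t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
            t.is_rooted = False
            t.encode_bipartitions()
            labels = sorted(l.taxon.label for l in t.leaf_node_iter())
            out = set()
            for e in t.preorder_edge_iter():
                if e.head_node.parent_node is None or e.head_node.is_leaf():
                    continue
                side = frozenset(
                    l.taxon.label for l in e.head_node.leaf_iter()
                )
                out.add(min(side, frozenset(labels) - side, key=sorted))
            return out

        expected = len(bips(cat) ^ bips(bal))
        assert rf_distance(cat, bal) == expected

    def test_leaf_set_mismatch_raises(self):
        with pytest.raises(ValueError):
            rf_distance("((a,b),(c,d));", "((a,b),(c,e));")

    def test_metric_properties_on_random_triples(self):
        trees = [random_binary_tree(8, seed=s).as_string(schema="newick") for s in range(3)]
        # relabel to a common taxon set is already true (t0..t7)
        d01 = rf_distance(trees[0], trees[1])
        d12 = rf_distance(trees[1], trees[2])
        d02 = rf_distance(trees[0], trees[2])
        assert d01 == rf_distance(trees[1], trees[0])
        assert d02 <= d01 + d12


class TestNJ:
    def test_recovers_tree_from_clean_simulated_data(self, rng):
        ref = twelve_taxon_trees("CC", 0.1)
        inst = GMInstance.from_tree(ref, rng)
        aln = inst.simulate_alignment(5000, rng)
        assert rf_distance(nj_paralinear(aln), ref) == 0

    def test_four_taxon_quartet(self, rng):
        from asaq.simulate import gm_quartet

        inst = gm_quartet((0.2, 0.2, 0.2, 0.2), 0.3, rng)
        aln = inst.simulate_alignment(5000, rng)
        assert rf_distance(nj_paralinear(aln), "((1,2),(3,4));") == 0


def test_compute_weight_table_covers_all_quartets(rng):
    inst = GMInstance.from_tree(twelve_taxon_trees("CC", 0.1), rng)
    aln = inst.simulate_alignment(500, rng)
    table = compute_weight_table(aln, method="pl")
    assert len(table) == len(list(itertools.combinations(range(12), 4))) == 495
    subset = [("seq0", "seq1", "seq2", "seq3"), ("seq0", "seq1", "seq2", "seq4")]
    small = compute_weight_table(aln, method="pl", quartets=subset)
    assert len(small) == 2


def test_phylip_distance_matrix_format(tmp_path, rng):
    from asaq.qmethods import paralinear_distance_matrix, write_phylip_distances
    from asaq.simulate import gm_quartet

    inst = gm_quartet((0.2, 0.2, 0.2, 0.2), 0.3, rng)
    aln = inst.simulate_alignment(1000, rng)
    labels, D = paralinear_distance_matrix(aln)
    out = tmp_path / "d.phy"
    write_phylip_distances(labels, D, out)
    lines = out.read_text().splitlines()
    assert lines[0].strip() == "4"
    assert len(lines) == 5
    first = lines[1].split()
    assert first[0] == labels[0] and float(first[1]) == 0.0


def test_topological_distances_match_tree_structure():
    tree = dendropy.Tree.get(data="((a,b),(c,d),(e,f));", schema="newick")
    labels, D = topological_leaf_distances(tree)
    i = {t: k for k, t in enumerate(labels)}
    assert D[i["a"], i["b"]] == 2
    assert D[i["a"], i["c"]] >= 3
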