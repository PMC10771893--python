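"""Distances, neighbor joining, bootstrap, consensus and Fitch scoring."""

import itertools
import math

import numpy as np
import pytest

from domaindrift import read_newick, synthetic_data as sd
from domaindrift.phylo import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    fitch_score,
    majority_rule_consensus,
    neighbor_joining,
)
from domaindrift.records import Msa, SeqRecord
from domaindrift.tree import PhyloTree, TreeNode


def msa_from(seqs: dict[str, str]) -> Msa:
    return Msa([SeqRecord(id=k, residues=v) for k, v in seqs.items()])


class TestDistanceMatrix:
    def test_identical_sequences_zero_under_every_model(self):
        msa = msa_from({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        for model in ("p", "JC", "K2P"):
            assert distance_matrix(msa, model).get("a", "b") == 0.0

    def test_p_distance_one_mismatch_in_ten(self):
        msa = msa_from({"a": "ACGTACGTAC", "b": "ACGTACGTAA"})
        assert distance_matrix(msa, "p").get("a", "b") == pytest.approx(0.1)

    def test_jc_correction_closed_form(self):
        msa = msa_from({"a": "ACGTACGTAC", "b": "ACGTACGTAA"})
        expected = -0.75 * math.log(1 - 0.4 / 3)
        d = distance_matrix(msa, "JC").get("a", "b")
        assert d == pytest.approx(expected)
        assert round(d, 4) == 0.1073

    def test_k2p_uses_transition_transversion_split(self):
        # 10 columns: 1 transition (A->G), 1 transversion (C->A)
        msa = msa_from({"a": "AAGTACGTAC", "b": "GAGTACGTAA"})
        P, Q = 0.1, 0.1
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert distance_matrix(msa, "K2P").get("a", "b") == pytest.approx(expected)

    def test_saturation_is_signaled_not_stored_as_infinity(self):
        msa = msa_from({"a": "AAAA", "b": "CCCC"})
        dm = distance_matrix(msa, "JC")
        assert frozenset(("a", "b")) in dm.saturated
        assert math.isnan(dm.get("a", "b"))

    def test_gapped_columns_use_pairwise_deletion(self):
        msa = msa_from({"a": "ACGT-CGTAC", "b": "ACGTACGTAA"})
        # 9 shared columns, 1 mismatch
        assert distance_matrix(msa, "p").get("a", "b") == pytest.approx(1 / 9)


def tree_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    ids = sorted(tree.leaf_names)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tree.path_length(ids[i], ids[j])
    return DistanceMatrix(ids=ids, d=d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(ids=list("ABC"), d=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = neighbor_joining(dm)
        # a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 3
        assert t.to_newick() == "(A:1.0,B:2.0,C:3.0);"

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:1.0,B:2.0):5.0,C:3.0,D:4.0);",
            "((A:1.0,B:2.0):2.5,(C:3.0,D:4.0):1.5,E:2.0);",
        ],
    )
    def test_additive_matrix_recovered_exactly(self, newick):
        truth = read_newick(newick)
        dm = tree_distance_matrix(truth)
        t = neighbor_joining(dm)
        assert t.bipartitions() == truth.bipartitions()
        for a, b in itertools.combinations(sorted(truth.leaf_names), 2):
            assert t.path_length(a, b) == pytest.approx(dm.get(a, b), abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(ids=["A", "B"], d=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_taxon_input_order_does_not_change_the_tree(self):
        truth = read_newick("((A:1.0,B:2.0):2.5,(C:3.0,D:4.0):1.5,E:2.0);")
        dm = tree_distance_matrix(truth)
        perm = [3, 0, 4, 1, 2]
        dm2 = DistanceMatrix(
            ids=[dm.ids[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
        )
        assert neighbor_joining(dm).to_newick() == neighbor_joining(dm2).to_newick()

    def test_matches_dendropy_on_a_generic_matrix(self):
        import dendropy

        rng = np.random.default_rng(5)
        truth = read_newick(
            "((A:0.11,B:0.23):0.31,((C:0.17,D:0.29):0.13,E:0.41):0.07,F:0.19);"
        )
        dm = tree_distance_matrix(truth)
        noisy = dm.d + rng.uniform(0, 0.01, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = neighbor_joining(DistanceMatrix(ids=dm.ids, d=noisy))

        csv = "," + ",".join(dm.ids) + "\n"
        for i, name in enumerate(dm.ids):
            csv += name + "," + ",".join(str(x) for x in noisy[i]) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=_io.StringIO(csv))
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        ref = {
            frozenset(str(t) for t in b.leafset_taxa(dtree.taxon_namespace))
            for b in dtree.bipartition_encoding
        }
        all_taxa = frozenset(str(t) for t in dtree.taxon_namespace)
        anchor = min(all_taxa)
        ref_splits = set()
        for side in ref:
            if anchor in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                ref_splits.add(frozenset(s.strip("'") for s in side))
        assert ours.bipartitions() == ref_splits

    def test_recovers_generating_topology_from_simulated_data(self):
        """NJ on JC distances recovers the 9-taxon generating tree in >= 19
        of 20 simulation seeds at 2000 codons."""
        truth_splits = sd.mammal_tree().bipartitions()
        hits = 0
        for seed in range(20):
            cfg = sd.SimulationConfig(tree=sd.mammal_tree(), n_codons=2000, seed=seed)
            res = sd.simulate_cds(cfg)
            t = neighbor_joining(distance_matrix(res.nucleotide, "JC"))
            hits += t.bipartitions() == truth_splits
        assert hits >= 19

    def test_longer_terminal_edge_is_recovered_as_longer(self):
        """A cherry taxon simulated with a longer terminal edge gets the
        longer NJ branch estimate (20 seeds, >= 90%)."""
        tree = read_newick("((H:0.06,C:0.015):0.03,(M:0.04,R:0.04):0.03);")
        hits = 0
        for seed in range(20):
            cfg = sd.SimulationConfig(tree=read_newick(tree.to_newick()), n_codons=2000, seed=seed)
            res = sd.simulate_cds(cfg)
            t = neighbor_joining(distance_matrix(res.nucleotide, "JC"))
            hits += t.find_leaf("H").length > t.find_leaf("C").length
        assert hits >= 18


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_one(self, mammal_result):
        res = bootstrap_support(mammal_result.nucleotide, n_reps=1, seed=3, model="JC")
        supports = [
            n.support
            for n in res.tree.root.traverse_preorder()
            if n.support is not None
        ]
        assert supports and set(supports) <= {0.0, 1.0}

    def test_unanimous_signal_gives_full_support(self):
        # every column supports the AB|CD split
        msa = msa_from(
            {"A": "AAAAAAAAAA", "B": "AAAAAAAAAA", "C": "CCCCCCCCCC", "D": "CCCCCCCCCG"}
        )
        res = bootstrap_support(msa, n_reps=25, seed=1, model="p")
        split_node = [
            n
            for n in res.tree.root.traverse_preorder()
            if n.support is not None
        ]
        assert all(n.support == 1.0 for n in split_node)

    def test_supports_equal_independent_bipartition_tally(self, mammal_result):
        res = bootstrap_support(mammal_result.nucleotide, n_reps=60, seed=7, model="JC")
        all_leaves = frozenset(res.tree.leaf_names)
        anchor = min(all_leaves)
        for node in res.tree.root.traverse_postorder():
            if node.support is None:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            tally = sum(side in t.bipartitions() for t in res.trees)
            assert node.support == pytest.approx(tally / len(res.trees))

    def test_deterministic_under_seed(self, mammal_result):
        a = bootstrap_support(mammal_result.nucleotide, n_reps=10, seed=5, model="JC")
        b = bootstrap_support(mammal_result.nucleotide, n_reps=10, seed=5, model="JC")
        assert a.tree.to_newick() == b.tree.to_newick()


class TestConsensus:
    def test_consensus_of_identical_trees_is_that_tree(self):
        t = read_newick("((A,B),(C,D),E);")
        cons = majority_rule_consensus([t.copy() for _ in range(4)], 0.5)
        assert cons.bipartitions() == t.bipartitions()
        supports = [
            n.support for n in cons.root.traverse_preorder() if n.support is not None
        ]
        assert all(s == 1.0 for s in supports)

    def test_minority_split_absent_at_cutoff(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,C),(B,D),E);")
        trees = [t1.copy(), t1.copy(), t2.copy(), t2.copy(), read_newick("((A,E),(B,C),D);")]
        cons = majority_rule_consensus(trees, 0.5)
        # every split occurs in at most 2/5 of the trees -> star consensus
        assert cons.bipartitions() == set()

    def test_two_to_one_majority_keeps_winner_at_two_thirds(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,C),(B,D),E);")
        cons = majority_rule_consensus([t1.copy(), t1.copy(), t2], 0.5)
        assert cons.bipartitions() == t1.bipartitions()
        supports = [
            n.support for n in cons.root.traverse_preorder() if n.support is not None
        ]
        assert all(s == pytest.approx(2 / 3) for s in supports)

    def test_inconsistent_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            majority_rule_consensus(
                [read_newick("((A,B),C,D);"), read_newick("((A,B),C,E);")]
            )

    def test_low_cutoff_rejected(self):
        with pytest.raises(ValueError):
            majority_rule_consensus([read_newick("((A,B),C,D);")], 0.3)


def enumerate_min_changes(tree: PhyloTree, states: dict[str, str], alphabet: str) -> int:
    """Brute-force minimum mutation count over all internal assignments."""
    internals = [n for n in tree.root.traverse_preorder() if not n.is_leaf]
    free_leaves = [n for n in tree.root.traverse_preorder() if n.is_leaf and states[n.name] == "-"]
    free = internals + free_leaves
    best = math.inf
    for combo in itertools.product(alphabet, repeat=len(free)):
        assign = {id(n): s for n, s in zip(free, combo)}
        for n in tree.root.traverse_preorder():
            if n.is_leaf and states[n.name] != "-":
                assign[id(n)] = states[n.name]
        changes = 0
        for n in tree.root.traverse_preorder():
            for child in n.children:
                changes += assign[id(n)] != assign[id(child)]
        best = min(best, changes)
    return int(best)


class TestFitch:
    def test_identical_sequences_score_zero(self):
        tree = read_newick("((A,B),(C,D));")
        msa = msa_from({k: "ACGT" for k in "ABCD"})
        assert fitch_score(tree, msa) == 0

    def test_single_column_two_state_split(self):
        tree = read_newick("((A,B),(C,D));")
        msa = msa_from({"A": "A", "B": "A", "C": "G", "D": "G"})
        assert fitch_score(tree, msa) == 1

    def test_leaf_mismatch_is_an_error(self):
        tree = read_newick("((A,B),(C,E));")
        msa = msa_from({k: "A" for k in "ABCD"})
        with pytest.raises(ValueError):
            fitch_score(tree, msa)

    def test_matches_exhaustive_enumeration_with_gaps(self):
        rng = np.random.default_rng(9)
        alphabet = "ACG"
        labels = list("ABCDE")
        for rep in range(8):
            # random rooted shape over 5 leaves via random sequential joins
            nodes = [TreeNode(name=l) for l in labels]
            while len(nodes) > 2:
                rng.shuffle(nodes)
                p = TreeNode()
                p.add_child(nodes.pop())
                p.add_child(nodes.pop())
                nodes.append(p)
            root = TreeNode()
            for n in nodes:
                root.add_child(n)
            tree = PhyloTree(root)
            cols = ["".join(rng.choice(list(alphabet + "-"), size=5)) for _ in range(6)]
            msa = msa_from({l: "".join(col[i] for col in cols) for i, l in enumerate(labels)})
            expected = sum(
                enumerate_min_changes(tree, dict(zip(labels, col)), alphabet)
                for col in cols
            )
            assert fitch_score(tree, msa) == expected

    def test_invariant_under_rerooting(self):
        msa = msa_from(
            {"A": "ACGGT", "B": "ACGTT", "C": "GCGTA", "D": "GTGAA", "E": "ATGAA"}
        )
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("(((C,D),E),A,B);")  # same unrooted topology
        assert t1.bipartitions() == t2.bipartitions()
        assert fitch_score(t1, msa) == fitch_score(t2, msa)
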