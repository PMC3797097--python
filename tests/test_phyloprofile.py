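import io
import math

import dendropy
import numpy as np
import pytest

from gidphylo.msa import MultipleAlignment
from gidphylo.phyloprofile import (
    MonophylyResult,
    annotated_taxonomy_report,
    bootstrap_support,
    dollo_reconstruct,
    monophyly_test,
    nj_tree,
    presence_matrix,
    protein_distance,
    read_taxonomy,
)

from oracles import dollo_min_losses


def _tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _random_rooted_tree(labels, rng):
    items = [f"{l}" for l in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return _tree(items[0] + ";")


class TestProteinDistance:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(
            ["a", "b", "c"], {"a": "MKVL", "b": "MKVL", "c": "WWWW"}
        )
        ids, dist = protein_distance(msa)
        assert dist[ids.index("a"), ids.index("b")] == 0.0

    def test_p_distance_fraction(self):
        rows = {"a": "A" * 100, "b": "A" * 90 + "W" * 10, "c": "C" * 100}
        ids, dist = protein_distance(MultipleAlignment(["a", "b", "c"], rows))
        assert dist[0, 1] == pytest.approx(0.10)

    def test_kimura_correction_formula(self):
        rows = {"a": "A" * 100, "b": "A" * 90 + "W" * 10, "c": "C" * 100}
        ids, dist = protein_distance(
            MultipleAlignment(["a", "b", "c"], rows), "kimura_protein"
        )
        assert dist[0, 1] == pytest.approx(-math.log(1 - 0.10 - 0.2 * 0.01), abs=1e-9)

    def test_no_comparable_columns_names_pair(self):
        rows = {"a": "AA--", "b": "--WW", "c": "AAWW"}
        with pytest.raises(ValueError, match="a and b"):
            protein_distance(MultipleAlignment(["a", "b", "c"], rows))


class TestNjTree:
    def test_three_taxon_closed_form(self):
        tree = nj_tree(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("newick", [
        "((A:1,B:2):1,(C:1,D:1):2);",
        "(((A:1,B:1):1,C:2):1,(D:1,E:2):1);",
        "((((A:1,B:2):1,(C:1,D:2):1):1,(E:1,F:1):2):1,(G:2,H:1):1);",
    ])
    def test_additive_matrix_recovers_topology(self, newick):
        source = _tree(newick)
        labels = sorted(t.label for t in source.taxon_namespace)
        pdm = source.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in source.taxon_namespace}
        n = len(labels)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    dist[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
        recovered = nj_tree(labels, dist)

        def splits(tree):
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            out = set()
            for node in tree.preorder_node_iter():
                if node.parent_node is None or node.is_leaf():
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 2 <= len(side) <= len(leaves) - 2:
                    out.add(min(side, leaves - side, key=lambda s: sorted(s)[0]))
            return out

        assert splits(source) == splits(recovered)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B", "C"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))

    def test_branch_lengths_non_negative(self, rng):
        for _ in range(10):
            n = 6
            coords = rng.random((n, 3))
            dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            tree = nj_tree([f"t{i}" for i in range(n)], dist)
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


class TestBootstrap:
    def _msa(self):
        rows = {
            "a1": "AAAAAAAAAACCCCCCCCCC",
            "a2": "AAAAAAAAAACCCCCCCCCC",
            "b1": "WWWWWWWWWWGGGGGGGGGG",
            "b2": "WWWWWWWWWWGGGGGGGGGT",
            "cc": "YYYYYYYYYYHHHHHHHHHH",
        }
        return MultipleAlignment(list(rows), rows)

    def test_identical_pair_has_full_support(self):
        tree = bootstrap_support(self._msa(), n_replicates=50, seed=1)
        supports = {}
        leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            supports[min(side, leaves - side, key=lambda s: sorted(s)[0])] = node.label
        key = min(frozenset({"a1", "a2"}), leaves - frozenset({"a1", "a2"}),
                  key=lambda s: sorted(s)[0])
        assert supports[key] == "100"

    def test_deterministic_under_fixed_seed(self):
        t1 = bootstrap_support(self._msa(), 30, seed=9)
        t2 = bootstrap_support(self._msa(), 30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_in_percentage_range(self):
        tree = bootstrap_support(self._msa(), 25, seed=3)
        for node in tree.preorder_node_iter():
            if node.label is not None and not node.is_leaf():
                assert 0 <= int(node.label) <= 100

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._msa(), 0, seed=1)


class TestMonophyly:
    def test_clean_groups(self):
        tree = dendropy.Tree.get(data="((a1,a2),(b1,b2),x);", schema="newick")
        result = monophyly_test(tree, {"a1": "a", "a2": "a", "b1": "b", "b2": "b", "x": "x"})
        assert result["a"].monophyletic and result["b"].monophyletic

    def test_interleaved_groups_list_intruders(self):
        tree = dendropy.Tree.get(data="(((a1,b1),a2),b2,x);", schema="newick")
        result = monophyly_test(tree, {"a1": "a", "a2": "a", "b1": "b", "b2": "b", "x": "x"})
        assert not result["a"].monophyletic
        assert "b1" in result["a"].intruders

    def test_unlabelled_leaf_rejected(self):
        tree = dendropy.Tree.get(data="((a1,a2),(b1,b2),x);", schema="newick")
        with pytest.raises(ValueError):
            monophyly_test(tree, {"a1": "a"})

    def test_planted_intruder_found(self):
        # one Rmnd5-like sequence generated inside the MAEA clade
        tree = dendropy.Tree.get(
            data="((m1,(m2,r3)),(r1,r2),x);", schema="newick"
        )
        labels = {"m1": "MAEA", "m2": "MAEA", "r1": "Rmnd5", "r2": "Rmnd5",
                  "r3": "Rmnd5", "x": "out"}
        result = monophyly_test(tree, labels)
        assert not result["MAEA"].monophyletic
        assert result["MAEA"].intruders == ("r3",)


class TestTaxonomyAndPresence:
    def test_newick_and_parent_child_agree(self):
        newick = read_taxonomy("((A,B)ab,(C,D)cd)root;")
        tsv = read_taxonomy(io.StringIO(
            "A\tab\nB\tab\nC\tcd\nD\tcd\nab\troot\ncd\troot\n"
        ))
        labels = lambda t: sorted(l.taxon.label for l in t.leaf_node_iter())
        assert labels(newick) == labels(tsv) == ["A", "B", "C", "D"]

    def test_presence_matrix_from_calls(self):
        from gidphylo.orthology import OrthologyCall

        taxonomy = read_taxonomy("((A,B),(C,D));")
        calls = [
            OrthologyCall("g1", "A", "TWA1", True, True, None, True, "orthologue"),
            OrthologyCall("g2", "B", "TWA1", True, False, None, True, "paralogue"),
        ]
        matrix = presence_matrix(calls, taxonomy)
        assert matrix.loc["A", "TWA1"]
        assert not matrix.loc["B", "TWA1"]  # paralogue does not set presence
        assert not matrix.loc["C"].any()
        report = annotated_taxonomy_report(matrix, taxonomy)
        assert report.splitlines()[1].startswith("A\t*")

    def test_unknown_species_rejected(self):
        from gidphylo.orthology import OrthologyCall

        taxonomy = read_taxonomy("((A,B),(C,D));")
        calls = [OrthologyCall("g", "ZZ", "TWA1", True, True, None, True, "orthologue")]
        with pytest.raises(ValueError):
            presence_matrix(calls, taxonomy)

    def test_empty_calls_all_false(self):
        matrix = presence_matrix([], read_taxonomy("((A,B),(C,D));"))
        assert not matrix.to_numpy().any()


class TestDollo:
    def test_gain_at_mrca_no_losses(self):
        tree = _tree("((A,B),(C,D));")
        rec = dollo_reconstruct(tree, {"A": True, "B": True, "C": False, "D": False})
        assert rec.gain_clade == frozenset({"A", "B"})
        assert rec.n_losses == 0
        assert not rec.states[frozenset({"A", "B", "C", "D"})]  # root absent

    def test_scattered_presence_forces_root_gain(self):
        tree = _tree("((A,B),(C,D));")
        rec = dollo_reconstruct(tree, {"A": True, "C": True, "B": False, "D": False})
        assert rec.gain_clade == frozenset({"A", "B", "C", "D"})
        assert set(rec.loss_clades) == {frozenset({"B"}), frozenset({"D"})}

    def test_absent_everywhere(self):
        rec = dollo_reconstruct(_tree("((A,B),(C,D));"), {})
        assert rec.gain_clade is None and rec.n_losses == 0

    def test_no_presence_outside_gain_clade(self):
        tree = _tree("(((A,B),C),(D,(E,F)));")
        rec = dollo_reconstruct(tree, {"A": True, "C": True})
        for leafset, present in rec.states.items():
            if present:
                assert leafset <= rec.gain_clade

    def test_loss_counts_match_bruteforce(self, rng):
        labels = list("ABCDEFGH")
        for _ in range(200):
            tree = _random_rooted_tree(labels, rng)
            presence = {l: bool(rng.random() < 0.5) for l in labels}
            expected = dollo_min_losses(tree, presence)
            rec = dollo_reconstruct(tree, presence)
            if expected is None:
                assert rec.gain_clade is None
            else:
                assert rec.n_losses == expected
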