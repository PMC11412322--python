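"""Midpoint rooting, species-overlap duplications, expansion calls,
family-size statistics."""

import itertools
from io import StringIO

import numpy as np
import pytest

from detoxrep.expansion import (
    call_expansions,
    duplication_nodes,
    family_size_distribution,
    gini,
    infer_ortholog_groups,
    midpoint_root,
    ortholog_relations,
    prune_to,
)
from detoxrep.io import read_tree


def tree(newick):
    return read_tree(StringIO(newick))


def sp_tree(newick):
    return read_tree(StringIO(newick), require_labels=False)


class TestMidpointRoot:
    def test_long_terminal_branch_is_bisected(self):
        # longest path D..A = 10+1+1+1 = 13; midpoint 6.5 from D, inside D's branch
        doc = tree("(A|a:1,(B|b:1,(C|c:1,D|d:10):1):1):0;")
        rooted = midpoint_root(doc)
        root_children = rooted.tree.root.clades
        d_child = [c for c in root_children if c.is_terminal() and c.name == "D|d"]
        assert d_child and d_child[0].branch_length == pytest.approx(6.5)

    def test_idempotent(self):
        doc = tree("((A|a:1,B|b:2):0.5,(C|c:4,D|d:1):0.5):0;")
        once = midpoint_root(doc)
        twice = midpoint_root(once)

        def leafsets(d):
            return {
                frozenset(l.name for l in c.get_terminals())
                for c in d.tree.find_clades()
            }

        assert leafsets(once) == leafsets(twice)

    def test_missing_branch_lengths(self):
        doc = tree("((A|a,B|b),C|c);")
        with pytest.raises(ValueError, match="branch lengths"):
            midpoint_root(doc)

    def test_zero_length_tree(self):
        doc = tree("((A|a:0,B|b:0):0,C|c:0):0;")
        with pytest.raises(ValueError, match="zero-length"):
            midpoint_root(doc)


class TestOrthologGroups:
    def test_ancient_duplication_yields_two_groups(self):
        doc = tree("((A|g1:1,B|g2:1):1,(A|g3:1,B|g4:1):1):0;")
        groups = infer_ortholog_groups(doc)
        assert sorted(sorted(g.members) for g in groups) == [
            ["A|g1", "B|g2"], ["A|g3", "B|g4"],
        ]

    def test_one_to_one_pair(self):
        groups = infer_ortholog_groups(tree("(A|g1:1,B|g2:1):0;"))
        assert len(groups) == 1 and sorted(groups[0].members) == ["A|g1", "B|g2"]

    def test_many_to_one_splits_duplicated_side(self):
        doc = tree("((A|g1:1,A|g2:1):1,B|g3:1):0;")
        groups = infer_ortholog_groups(doc)
        assert sorted(sorted(g.members) for g in groups) == [["A|g1"], ["A|g2"], ["B|g3"]]
        rel = ortholog_relations(doc)
        assert ("A|g1", "B|g3") in rel and ("A|g2", "B|g3") in rel
        assert ("A|g1", "A|g2") not in rel

    def test_pruning_to_full_length_leaves(self):
        doc = tree("((A|g1:1,A|frag:0.1):1,B|g3:1):0;")
        groups = infer_ortholog_groups(doc, full_length_ids={"g1", "g3"})
        assert sorted(sorted(g.members) for g in groups) == [["A|g1", "B|g3"]]

    def test_conservation_of_leaves(self, demo):
        for family, doc in demo.gene_trees.items():
            t = demo.truth
            full = set(
                t[(t.family == family) & (t.kind == "gene") & ~t.is_fragment].protein_id
            )
            groups = infer_ortholog_groups(doc, full)
            assert sum(len(g.members) for g in groups) == len(full)

    def test_brute_force_species_overlap_oracle(self):
        """Duplication labels match an exhaustive per-node check on random
        trees with <= 12 leaves."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(3, 13))
            labels = [f"{rng.choice(list('ABCD'))}|g{i}" for i in range(n)]
            nodes = [f"{l}:{rng.uniform(0.1, 1):.3f}" for l in labels]
            while len(nodes) > 1:  # random coalescence into a newick string
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1):.3f}"
                nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
                nodes.append(merged)
            doc = tree(nodes[0] + ";")
            got = duplication_nodes(doc)
            for clade in doc.tree.find_clades():
                if clade.is_terminal():
                    continue
                expect = any(
                    {l.name.split("|")[0] for l in a.get_terminals()}
                    & {l.name.split("|")[0] for l in b.get_terminals()}
                    for a, b in itertools.combinations(clade.clades, 2)
                )
                assert got[id(clade)] == expect


SPECIES3 = "((A:1,B:1):1,C:2):0;"
# the A+B pair is a named lineage within a 5-taxon roster
SPECIES5 = "(((A:1,B:1):1,(C:1,D:1):1):1,E:2):0;"


class TestCallExpansions:
    def test_species_specific(self):
        doc = tree("((((A|a1:.1,A|a2:.1):.1,A|a3:.1):1,B|b1:1):1,C|c1:2):0;")
        calls = call_expansions(doc, sp_tree(SPECIES3))
        assert len(calls) == 1
        (c,) = calls
        assert c.scope == "species_specific" and c.species == ("A",)
        assert c.copy_numbers == {"A": 3, "B": 1, "C": 1}

    def test_lineage_specific(self):
        doc = tree(
            "((((A|a1:.1,B|b1:.1):.1,(A|a2:.1,B|b2:.1):.1):1,"
            "(C|c1:1,D|d1:1):1):1,E|e1:2):0;"
        )
        (c,) = call_expansions(doc, sp_tree(SPECIES5))
        assert c.scope == "lineage_specific" and c.species == ("A", "B")
        assert c.copy_numbers == {"A": 2, "B": 2, "C": 1, "D": 1, "E": 1}

    def test_multi_copy_species_not_a_clade_is_none(self):
        doc = tree(
            "((((A|a1:.1,C|c1:.1):.1,(A|a2:.1,C|c2:.1):.1):1,"
            "(B|b1:1,D|d1:1):1):1,E|e1:2):0;"
        )
        calls = call_expansions(doc, sp_tree(SPECIES5))
        assert all(c.scope == "none" for c in calls)

    def test_ancient_duplication_separates_complexes(self):
        doc = tree("((A|g1:1,B|g2:1):1,(A|g3:1,B|g4:1):1):0;")
        calls = call_expansions(doc, sp_tree(SPECIES3))
        assert len(calls) == 2 and all(c.scope == "none" for c in calls)

    def test_single_copy_everywhere_is_none(self):
        doc = tree("((A|a1:1,B|b1:1):1,C|c1:2):0;")
        (c,) = call_expansions(doc, sp_tree(SPECIES3))
        assert c.scope == "none"

    def test_unknown_species_rejected(self):
        doc = tree("(A|a1:1,Z|z1:1):0;")
        with pytest.raises(ValueError, match="Z"):
            call_expansions(doc, sp_tree(SPECIES3))

    def test_fragment_leaves_never_change_calls(self, demo):
        for family, doc in demo.gene_trees.items():
            t = demo.truth
            sub = t[(t.family == family) & (t.kind == "gene")]
            full = set(sub[~sub.is_fragment].protein_id)
            with_frags = call_expansions(doc, demo.species_tree, full)
            pre_pruned = prune_to(
                doc, {l for l in doc.leaf_labels if l.split("|", 1)[1] in full}
            )
            without = call_expansions(pre_pruned, demo.species_tree, None)
            key = lambda calls: sorted(
                (c.scope, c.species, tuple(sorted(c.copy_numbers.items())))
                for c in calls
            )
            assert key(with_frags) == key(without)


class TestFamilySize:
    def test_top_share(self):
        out = family_size_distribution({"a": 10, "b": 1, "c": 1, "d": 1, "e": 1},
                                       top_k=(1,))
        assert out["top_k_share"][1] == pytest.approx(10 / 14)

    def test_uniform_counts_gini_zero(self):
        assert gini([4, 4, 4, 4]) == pytest.approx(0.0)

    def test_clan_fraction(self):
        out = family_size_distribution(
            {"CYP6": 40, "CYP9": 24, "CYP4": 26, "CYP12": 10},
            clans={"CYP3": ["CYP6", "CYP9"], "CYP4": ["CYP4"]},
        )
        assert out["clan_fractions"]["CYP3"] == pytest.approx(0.64)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            family_size_distribution({"a": 0, "b": 0})
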