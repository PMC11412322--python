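"""Hit-gated identification, length gating, fragment rescue, bookkeeping."""

from io import StringIO

import pytest

from detoxrep.io import HitRecord, ProteinRecord, read_tree
from detoxrep.repertoire import (
    DEFAULT_RULES,
    FamilyRule,
    identify_candidates,
    partition_by_length,
    repertoire_summary,
    rescue_fragments,
)


def blast_hit(q, evalue=1e-40, span=(1, 350)):
    return HitRecord(q, "REF", evalue, span[1] - span[0] + 1,
                     span[0], span[1], 1, span[1] - span[0] + 1, 100.0, "blast_tab")


def dom_hit(q, domain, evalue=1e-30, span=(5, 140)):
    return HitRecord(q, domain, evalue, span[1] - span[0] + 1,
                     span[0], span[1], 1, span[1] - span[0] + 1, 80.0, "hmmer_dom")


def protein(pid, length, species="spA"):
    return ProteinRecord(pid, species, "M" * length)


CYP = DEFAULT_RULES["CYP"]
GST = DEFAULT_RULES["GST"]


class TestIdentify:
    def test_single_qualifying_hit(self):
        drafts = identify_candidates([protein("g1", 400)], [blast_hit("g1")], CYP)
        (d,) = drafts
        assert d.coverage_aa == 350 and d.status == ""

    def test_evalue_gate(self):
        drafts = identify_candidates(
            [protein("g1", 400)], [blast_hit("g1", evalue=0.01)], CYP
        )
        assert drafts[0].status == "discarded_no_hit"

    def test_gst_requires_both_domains(self):
        p = protein("g1", 200)
        only_n = identify_candidates([p], [dom_hit("g1", "PF02798")], GST)
        assert only_n[0].status == "discarded_no_hit"
        both = identify_candidates(
            [p], [dom_hit("g1", "PF02798"), dom_hit("g1", "PF00043", span=(150, 195))],
            GST,
        )
        assert both[0].status == ""
        # domain evidence gates on polypeptide length, not hit span
        assert both[0].coverage_aa == 200

    def test_split_hsps_merge_coverage(self):
        hits = [blast_hit("g1", span=(1, 200)), blast_hit("g1", span=(150, 350))]
        drafts = identify_candidates([protein("g1", 400)], hits, CYP)
        assert drafts[0].coverage_aa == 350

    def test_disjoint_hsps_sum_coverage(self):
        hits = [blast_hit("g1", span=(1, 100)), blast_hit("g1", span=(201, 300))]
        drafts = identify_candidates([protein("g1", 400)], hits, CYP)
        assert drafts[0].coverage_aa == 200

    def test_unknown_protein_in_hits(self):
        with pytest.raises(ValueError, match="ghost"):
            identify_candidates([protein("g1", 400)], [blast_hit("ghost")], CYP)


class TestPartition:
    @pytest.mark.parametrize(
        "coverage,length_class,status",
        [(350, "full", "kept_full"), (210, "fragment", ""), (90, "fragment", "discarded_short")],
    )
    def test_cyp_length_gates(self, coverage, length_class, status):
        drafts = identify_candidates(
            [protein("g1", 400)], [blast_hit("g1", span=(1, coverage))], CYP
        )
        (d,) = partition_by_length(drafts, CYP)
        assert (d.length_class, d.status) == (length_class, status)

    def test_special_rescue_bypasses_floor(self):
        rule = FamilyRule("CCE", "blast_reference", special_rescue_ids=("Ace1_Ppap",))
        drafts = identify_candidates(
            [protein("Ace1_Ppap", 90)], [blast_hit("Ace1_Ppap", span=(1, 90))], rule
        )
        (d,) = partition_by_length(drafts, rule)
        assert d.status == "" and d.below_floor and d.length_class == "fragment"

    def test_raising_full_min_never_increases_fulls(self):
        prots = [protein(f"g{i}", 400) for i in range(6)]
        hits = [blast_hit(f"g{i}", span=(1, 250 + 30 * i)) for i in range(6)]
        n_full = []
        for full_min in (280, 320, 360):
            rule = FamilyRule("CYP", "blast_reference", full_min_aa=full_min)
            drafts = partition_by_length(identify_candidates(prots, hits, rule), rule)
            n_full.append(sum(1 for d in drafts if d.status == "kept_full"))
        assert n_full == sorted(n_full, reverse=True)


def tree_from(newick: str):
    return read_tree(StringIO(newick))


class TestRescue:
    def make_drafts(self, spec):
        """spec: list of (gene, species, coverage)."""
        prots = [protein(g, max(cov, 1) + 50, sp) for g, sp, cov in spec]
        hits = [blast_hit(g, span=(1, cov)) for g, _, cov in spec]
        drafts = identify_candidates(prots, hits, CYP)
        return partition_by_length(drafts, CYP)

    def test_fragment_discarded_when_full_present(self):
        drafts = self.make_drafts([("f1", "spA", 400), ("fr1", "spA", 200),
                                   ("f2", "spB", 380)])
        tree = tree_from("((spA|f1:0.1,spA|fr1:0.1):0.1,spB|f2:0.2):0;")
        final = {e.protein_id: e.status for e in rescue_fragments(drafts, tree, CYP)}
        assert final["fr1"] == "discarded_fragment_redundant_with_full"
        assert final["f1"] == "kept_full"

    def test_longest_fragment_wins(self):
        drafts = self.make_drafts([("f1", "spA", 400), ("frS", "spB", 150),
                                   ("frL", "spB", 210)])
        tree = tree_from("(spA|f1:0.1,(spB|frS:0.05,spB|frL:0.05):0.1):0;")
        final = {e.protein_id: e.status for e in rescue_fragments(drafts, tree, CYP)}
        assert final["frL"] == "rescued_fragment"
        assert final["frS"] == "discarded_fragment_not_longest"

    def test_length_tie_breaks_lexicographically(self):
        drafts = self.make_drafts([("f1", "spA", 400), ("frB", "spB", 200),
                                   ("frA", "spB", 200)])
        tree = tree_from("(spA|f1:0.1,(spB|frA:0.05,spB|frB:0.05):0.1):0;")
        final = {e.protein_id: e.status for e in rescue_fragments(drafts, tree, CYP)}
        assert final["frA"] == "rescued_fragment"
        assert final["frB"] == "discarded_fragment_not_longest"

    def test_missing_draft_in_tree(self):
        drafts = self.make_drafts([("f1", "spA", 400), ("fr1", "spB", 200)])
        tree = tree_from("(spA|f1:0.1,spB|other:0.1):0;")
        with pytest.raises(ValueError, match="fr1"):
            rescue_fragments(drafts, tree, CYP)

    def test_partition_law_on_synthetic_world(self, demo):
        from detoxrep.repertoire import STATUSES, curate_family

        for family, hits in demo.hits.items():
            entries = curate_family(
                demo.proteins, hits, demo.gene_trees[family], DEFAULT_RULES[family]
            )
            assert len(entries) == len(demo.proteins)
            assert all(e.status in STATUSES for e in entries)

    def test_rescue_safety_invariants(self, demo):
        from detoxrep.repertoire import curate_family

        for family, hits in demo.hits.items():
            entries = curate_family(
                demo.proteins, hits, demo.gene_trees[family], DEFAULT_RULES[family]
            )
            per_slot_rescued = {}
            full_slots = set()
            for e in entries:
                slot = (e.species, e.ortholog_group_id)
                if e.status == "kept_full":
                    full_slots.add(slot)
                elif e.status == "rescued_fragment":
                    per_slot_rescued[slot] = per_slot_rescued.get(slot, 0) + 1
            assert all(n == 1 for n in per_slot_rescued.values())
            assert not (set(per_slot_rescued) & full_slots)


class TestSummary:
    def test_cyp_bookkeeping_percentages(self):
        entries = (
            [_kept("spA", f"f{i}") for i in range(20)]
            + [_rescued("spA", f"r{i}") for i in range(5)]
        )
        s = repertoire_summary(entries)
        assert s["n_total"] == 25
        assert s["pct_full"] == 80.0 and s["pct_fragment"] == 20.0

    def test_two_decimal_display(self):
        entries = (
            [_kept("spA", f"f{i}") for i in range(271)]
            + [_rescued("spA", f"r{i}") for i in range(5)]
        )
        s = repertoire_summary(entries, display_decimals=2)
        assert s["pct_full_str"] == "98.20"

    def test_empty_family_no_division(self):
        s = repertoire_summary([])
        assert s["n_total"] == 0 and s["pct_full"] is None


def _kept(sp, pid):
    from detoxrep.repertoire import RepertoireEntry

    return RepertoireEntry(pid, sp, "CYP", 350, "full", "kept_full")


def _rescued(sp, pid):
    from detoxrep.repertoire import RepertoireEntry

    return RepertoireEntry(pid, sp, "CYP", 200, "fragment", "rescued_fragment")
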