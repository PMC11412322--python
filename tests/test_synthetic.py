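"""Generator contracts: determinism, planted-truth consistency, decoys."""

import numpy as np
import pytest

from detoxrep.io import write_fasta
from detoxrep.repertoire import DEFAULT_RULES, identify_candidates
from detoxrep.synthetic import (
    ExpansionPlan,
    FamilyPlan,
    SyntheticSpec,
    default_spec,
    generate_dataset,
    make_decoys,
)


def small_spec(seed=0, **plan_kwargs):
    kwargs = dict(
        n_subfamilies=3, redundancy_rate=0.0, near_duplicate_rate=0.0,
        n_redundant_with_full_fragments=0, n_competing_fragment_pairs=0,
        fragment_rate=0.0,
    )
    kwargs.update(plan_kwargs)
    return SyntheticSpec(families=(FamilyPlan("CYP", **kwargs),), seed=seed, n_decoys=5)


class TestDeterminism:
    def test_same_seed_byte_identical_fasta(self, tmp_path):
        a, b = tmp_path / "a.faa", tmp_path / "b.faa"
        write_fasta(generate_dataset(default_spec(7)).proteins, a)
        write_fasta(generate_dataset(default_spec(7)).proteins, b)
        assert a.read_bytes() == b.read_bytes()

    def test_same_seed_identical_truth(self):
        t1 = generate_dataset(default_spec(7)).truth
        t2 = generate_dataset(default_spec(7)).truth
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        s1 = generate_dataset(small_spec(1)).proteins[0].sequence
        s2 = generate_dataset(small_spec(2)).proteins[0].sequence
        assert s1 != s2


class TestPlantedStructure:
    def test_fragment_rate_zero_means_full_length(self):
        ds = generate_dataset(small_spec())
        genes = ds.truth[ds.truth.kind == "gene"]
        assert not genes.is_fragment.any()
        by_id = {p.protein_id: p for p in ds.proteins}
        assert all(by_id[g].length_aa == 500 for g in genes.protein_id)

    def test_every_protein_has_one_truth_row(self, demo):
        ids = [p.protein_id for p in demo.proteins]
        assert sorted(ids) == sorted(demo.truth.protein_id)

    def test_species_specific_plan_recorded(self):
        spec = small_spec(
            expansions=(ExpansionPlan("CYPsf01", "species_specific", ("Ppap",), 3),)
        )
        ds = generate_dataset(spec)
        exp = ds.expected_expansions("CYP")["CYPsf01"]
        assert exp["scope"] == "species_specific"
        assert exp["copy_numbers"]["Ppap"] == 3

    def test_unknown_expansion_species_rejected(self):
        spec = small_spec(
            expansions=(ExpansionPlan("CYPsf01", "species_specific", ("Xenon",), 3),)
        )
        with pytest.raises(ValueError, match="Xenon"):
            generate_dataset(spec)

    def test_qualifying_hits_cover_every_true_member(self, demo):
        for family, hits in demo.hits.items():
            rule = DEFAULT_RULES[family]
            qualified = {
                h.query_id for h in hits if h.evalue <= rule.evalue_max
            }
            members = set(
                demo.truth[
                    (demo.truth.family == family) & (demo.truth.kind == "gene")
                ].protein_id
            )
            assert members <= qualified

    def test_cluster_geometry(self, demo):
        by_contig = {}
        for l in demo.loci:
            by_contig.setdefault(l.contig, []).append(l)
        for cid, members in demo.planted_clusters().items():
            contig = cid.split("#")[0]
            placed = sorted(
                (l for l in by_contig[contig] if l.gene_id in members),
                key=lambda l: l.start,
            )
            gaps = [b.start - a.start for a, b in zip(placed, placed[1:])]
            assert all(g <= 50_000 for g in gaps)


class TestDecoys:
    def test_zero_decoys(self):
        assert make_decoys(0) == []

    def test_decoys_absent_from_family_truth(self, demo):
        decoy_ids = set(demo.truth[demo.truth.is_decoy].protein_id)
        assert len(decoy_ids) == 50
        fam_rows = demo.truth[demo.truth.family != ""]
        assert not (decoy_ids & set(fam_rows.protein_id))

    def test_decoys_yield_zero_candidates(self, demo):
        decoys = [p for p in demo.proteins if p.protein_id.startswith("decoy")]
        for family, hits in demo.hits.items():
            rule = DEFAULT_RULES[family]
            decoy_hits = [h for h in hits if h.query_id.startswith("decoy")]
            drafts = identify_candidates(decoys, decoy_hits, rule)
            assert all(d.status == "discarded_no_hit" for d in drafts)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            make_decoys(-1)


class TestRedundancyPlants:
    def test_isoforms_are_close_to_parent(self, demo):
        from detoxrep.redundancy import local_identity

        by_id = {p.protein_id: p for p in demo.proteins}
        isoforms = [p for p in demo.proteins if p.protein_id.endswith(".iso1")]
        assert isoforms
        for iso in isoforms[:5]:
            parent = by_id[iso.protein_id[: -len(".iso1")]]
            assert local_identity(iso, parent) >= 0.993

    def test_near_duplicates_in_96_98_band(self, demo):
        from detoxrep.redundancy import local_identity

        by_id = {p.protein_id: p for p in demo.proteins}
        nears = [p for p in demo.proteins if p.protein_id.endswith(".near1")]
        assert nears
        for near in nears[:5]:
            parent = by_id[near.protein_id[: -len(".near1")]]
            assert 0.96 <= local_identity(near, parent) <= 0.98
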