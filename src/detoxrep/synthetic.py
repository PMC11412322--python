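"""Synthetic datasets with planted, machine-readable ground truth.

The generator emulates the statistical structure of transcriptome-derived
detoxification gene sets across a sand-fly-like species roster (11 ingroup
species, one dipteran outgroup), so every pipeline stage can be tested
against known answers without any downloads:

* a "Many and the Few" family-size distribution — most subfamilies carry one
  gene per species, a few are expanded to 4-12 copies;
* planted species-specific and lineage-specific expansions realized as
  duplication clades in the gene genealogies;
* fragmentary proteins (contiguous truncations) in three curation scenarios:
  a species' only representative (rescued), a fragment alongside a
  full-length member (discarded as redundant), and competing fragments
  (longest wins);
* isoform redundancy at >= 99.3% identity (collapses at the 99% threshold)
  and near-duplicates at ~97% (collapse only at 95%);
* tandem genomic clusters with intra-cluster gaps well under 50 kb and
  >= 200 kb between clusters;
* expression with one dominant paralog far above its duplicate (> 100-fold);
* generic orthogroups spanning universal to species-specific profiles.

Proteins are ancestor sequences mutated along the gene genealogy
(substitutions only; the only indels are the planted truncations), keeping
pairwise identities analytically controllable.  Everything is driven by one
integer seed: the same seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo

from . import io as dio
from .io import (
    ExpressionMatrix,
    GeneLocus,
    HitRecord,
    OrthogroupTable,
    ProteinRecord,
    TreeDoc,
)

__all__ = [
    "SANDFLY_SPECIES",
    "OUTGROUP",
    "DEFAULT_SPECIES_TREE_NEWICK",
    "ExpansionPlan",
    "ClusterPlan",
    "ExpressionPlan",
    "FamilyPlan",
    "SyntheticSpec",
    "Dataset",
    "default_spec",
    "generate_dataset",
    "make_decoys",
    "make_site_alignment",
    "generate_orthogroups",
]

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1").astype("U1")

SANDFLY_SPECIES = (
    "Ppap", "Pdub", "Pser", "Parg", "Pori", "Parab", "Pper", "Ptob",
    "Ssch", "Llon", "Lmig",
)
OUTGROUP = "Agam"

# 11 ingroup species in three genus-level groups plus one outgroup, with
# branch lengths; the ingroup forms the named clade "sandflies".
DEFAULT_SPECIES_TREE_NEWICK = (
    "(Agam:0.80,"
    "((((Ppap:0.10,Pdub:0.10):0.05,Pser:0.14):0.06,"
    "((Parg:0.12,Pori:0.12):0.04,"
    "(Parab:0.13,(Pper:0.09,Ptob:0.09):0.05):0.03):0.04):0.05,"
    "(Ssch:0.25,(Llon:0.08,Lmig:0.08):0.12):0.06):0.20);"
)

NAMED_CLADES = {
    "sandflies": frozenset(SANDFLY_SPECIES),
    "lutzomyia": frozenset({"Llon", "Lmig"}),
}

FAMILY_FULL_LEN = {"CYP": 500, "GST": 220, "UGT": 510, "CCE": 550, "ABC": 650}
FAMILY_EVIDENCE = {
    "CYP": "blast_reference",
    "GST": "hmm_domains",
    "UGT": "hmm_domains",
    "CCE": "hmm_domains",
    "ABC": "blast_reference",
}
FAMILY_DOMAINS = {
    "GST": ("PF02798", "PF00043"),
    "UGT": ("PF00201",),
    "CCE": ("PF00135",),
}
FAMILY_FULL_MIN = {"CYP": 300, "GST": 150, "UGT": 300, "CCE": 300, "ABC": 300}
# fragment shares emulating the printed full/incomplete breakdowns
FAMILY_FRAGMENT_RATE = {"CYP": 0.09, "GST": 0.02, "UGT": 0.17, "CCE": 0.18, "ABC": 0.07}


@dataclass(frozen=True)
class ExpansionPlan:
    subfamily: str
    kind: str  # {species_specific, lineage_specific}
    species: tuple[str, ...]
    copies: int  # copy number for each listed species

    def __post_init__(self) -> None:
        if self.kind not in ("species_specific", "lineage_specific"):
            raise ValueError(f"unknown expansion kind {self.kind!r}")
        if self.kind == "species_specific" and len(self.species) != 1:
            raise ValueError("species_specific expansion needs exactly one species")
        if self.kind == "lineage_specific" and len(self.species) < 2:
            raise ValueError("lineage_specific expansion needs >= 2 species")
        if self.copies < 2:
            raise ValueError("an expansion needs >= 2 copies")


@dataclass(frozen=True)
class ClusterPlan:
    contig: str
    subfamily: str
    species: str
    gap_range_bp: tuple[int, int] = (2_000, 30_000)


@dataclass(frozen=True)
class ExpressionPlan:
    dominant_subfamily: str
    competitor_subfamily: str
    fold: float = 150.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("dominance fold must be > 1")


@dataclass(frozen=True)
class FamilyPlan:
    family: str
    n_subfamilies: int = 6
    expansions: tuple[ExpansionPlan, ...] = ()
    fragment_rate: float | None = None  # default per family
    redundancy_rate: float = 0.06
    near_duplicate_rate: float = 0.03
    n_redundant_with_full_fragments: int = 1
    n_competing_fragment_pairs: int = 1
    cluster_plan: tuple[ClusterPlan, ...] = ()
    expression_plan: ExpressionPlan | None = None

    def subfamily_names(self) -> list[str]:
        return [f"{self.family}sf{i + 1:02d}" for i in range(self.n_subfamilies)]

    @property
    def effective_fragment_rate(self) -> float:
        if self.fragment_rate is not None:
            return self.fragment_rate
        return FAMILY_FRAGMENT_RATE[self.family]


@dataclass(frozen=True)
class SyntheticSpec:
    families: tuple[FamilyPlan, ...]
    seed: int = 0
    species_tree_newick: str = DEFAULT_SPECIES_TREE_NEWICK
    mutation_scale: float = 0.6  # substitutions per site per unit branch length
    n_decoys: int = 50
    n_orthogroups_per_category: int = 4


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The bundled demo world: all five families, with the kinds of
    expansions, clusters and dominance the analysis is built to detect."""
    return SyntheticSpec(
        seed=seed,
        families=(
            FamilyPlan(
                "CYP",
                n_subfamilies=8,
                expansions=(
                    ExpansionPlan("CYPsf01", "species_specific", ("Ppap",), 6),
                    ExpansionPlan("CYPsf02", "lineage_specific", ("Llon", "Lmig"), 4),
                ),
                cluster_plan=(
                    ClusterPlan("ctg_ppap_1", "CYPsf01", "Ppap"),
                    ClusterPlan("ctg_llon_1", "CYPsf02", "Llon"),
                ),
                expression_plan=ExpressionPlan("CYPsf03", "CYPsf04", fold=150.0),
            ),
            FamilyPlan(
                "GST",
                n_subfamilies=4,
                expansions=(
                    ExpansionPlan("GSTsf01", "lineage_specific", ("Llon", "Lmig"), 3),
                ),
            ),
            FamilyPlan("UGT", n_subfamilies=4),
            FamilyPlan(
                "CCE",
                n_subfamilies=4,
                expansions=(
                    ExpansionPlan("CCEsf01", "species_specific", ("Parg",), 3),
                ),
            ),
            FamilyPlan("ABC", n_subfamilies=5),
        ),
    )


# ---------------------------------------------------------------------------
# gene genealogy scaffolding


class _Node:
    __slots__ = ("children", "bl", "label", "meta")

    def __init__(self, children=None, bl=0.0, label=None, meta=None):
        self.children = children or []
        self.bl = bl
        self.label = label
        self.meta = meta or {}

    def leaves(self):
        if not self.children:
            yield self
        else:
            for ch in self.children:
                yield from ch.leaves()

    def newick(self) -> str:
        def fmt(node):
            if not node.children:
                return f"{node.label}:{node.bl:.6f}"
            inner = ",".join(fmt(ch) for ch in node.children)
            return f"({inner}):{node.bl:.6f}"

        inner = ",".join(fmt(ch) for ch in self.children)
        return f"({inner}):0.0;" if self.children else f"{self.label};"


def _clade_to_node(clade) -> _Node:
    if clade.is_terminal():
        return _Node(bl=clade.branch_length or 0.0, label=clade.name)
    return _Node(
        children=[_clade_to_node(ch) for ch in clade.clades],
        bl=clade.branch_length or 0.0,
    )


def _copy_node(node: _Node) -> _Node:
    return _Node(
        children=[_copy_node(ch) for ch in node.children],
        bl=node.bl,
        label=node.label,
        meta=dict(node.meta),
    )


def _caterpillar(copies: list[_Node], internal_bl: float = 0.08) -> _Node:
    """Chain subtree copies under nested duplication nodes."""
    assert len(copies) >= 2
    node = _Node(children=[copies[-2], copies[-1]], bl=internal_bl)
    for sub in reversed(copies[:-2]):
        node = _Node(children=[sub, node], bl=internal_bl)
    return node


def _find_clade_node(node: _Node, species: frozenset[str]) -> _Node | None:
    leaf_set = frozenset(l.label for l in node.leaves())
    if leaf_set == species:
        return node
    for ch in node.children:
        found = _find_clade_node(ch, species)
        if found is not None:
            return found
    return None


# ---------------------------------------------------------------------------
# sequence evolution


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.size) < p
    shifts = rng.integers(1, 20, size=int(mask.sum()))
    out[mask] = (out[mask] + shifts) % 20
    return out


def _mutate_exact(seq: np.ndarray, n_sites: int, rng: np.random.Generator,
                  margin: int = 10) -> np.ndarray:
    """Substitute exactly n_sites positions away from both termini, so the
    optimal local alignment keeps every column and the identity fraction is
    exact."""
    out = seq.copy()
    lo, hi = margin, seq.size - margin
    positions = rng.choice(np.arange(lo, hi), size=n_sites, replace=False)
    out[positions] = (out[positions] + rng.integers(1, 20, size=n_sites)) % 20
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(AA[seq])


# ---------------------------------------------------------------------------
# the generator


@dataclass
class Dataset:
    """Everything one synthetic world emits, in memory, plus writers."""

    species_tree: TreeDoc
    proteins: list[ProteinRecord]
    hits: dict[str, list[HitRecord]]  # per family
    gene_trees: dict[str, TreeDoc]  # per family
    loci: list[GeneLocus]
    orthogroups: OrthogroupTable
    orthogroup_totals: dict[str, int]
    tpm: ExpressionMatrix
    truth: pd.DataFrame
    og_truth: pd.DataFrame
    named_clades: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(NAMED_CLADES)
    )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["proteins"] = outdir / "proteins.faa"
        dio.write_fasta(self.proteins, paths["proteins"])
        paths["species_tree"] = outdir / "species_tree.nwk"
        dio.write_tree(self.species_tree, paths["species_tree"])
        for family, hits in self.hits.items():
            source = hits[0].source if hits else "blast_tab"
            suffix = "blast.tsv" if source == "blast_tab" else "domtbl.txt"
            p = outdir / f"{family}.{suffix}"
            dio.write_hits(hits, p)
            paths[f"hits_{family}"] = p
        for family, tree in self.gene_trees.items():
            p = outdir / f"{family}.nwk"
            dio.write_tree(tree, p)
            paths[f"tree_{family}"] = p
        paths["gff"] = outdir / "genes.gff3"
        dio.write_gff(self.loci, paths["gff"])
        paths["orthogroups"] = outdir / "orthogroups.tsv"
        dio.write_orthogroups(self.orthogroups, paths["orthogroups"])
        paths["tpm"] = outdir / "tpm.tsv"
        dio.write_tpm(self.tpm, paths["tpm"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["og_truth"] = outdir / "og_truth.tsv"
        self.og_truth.to_csv(paths["og_truth"], sep="\t", index=False)
        return paths

    # convenience views over the truth table -------------------------------

    def planted_repertoire(self, family: str) -> set[str]:
        t = self.truth
        return set(
            t[(t.family == family) & t.in_planted_repertoire].protein_id
        )

    def expected_status(self, family: str) -> dict[str, str]:
        t = self.truth
        sub = t[(t.family == family) & (t.expected_status != "")]
        return dict(zip(sub.protein_id, sub.expected_status))

    def expected_expansions(self, family: str) -> dict[str, dict]:
        """subfamily -> {scope, species, copy_numbers (full-length only)}."""
        t = self.truth
        sub = t[(t.family == family) & ~t.is_decoy & (t.kind == "gene")]
        out: dict[str, dict] = {}
        for subfam, rows in sub.groupby("subfamily"):
            full = rows[~rows.is_fragment & rows.in_planted_repertoire]
            copy_numbers = full.species.value_counts().to_dict()
            scope = rows.expansion_scope.iloc[0]
            species = tuple(
                sorted(s for s in rows.expansion_species.iloc[0].split(",") if s)
            )
            out[subfam] = {
                "scope": scope, "species": species, "copy_numbers": copy_numbers,
            }
        return out

    def redundancy_groups(self, level: str = "99") -> dict[str, set[str]]:
        col = f"redundancy_group_{level}"
        t = self.truth[self.truth[col] != ""]
        groups: dict[str, set[str]] = {}
        for pid, grp in zip(t.protein_id, t[col]):
            groups.setdefault(grp, set()).add(pid)
        return groups

    def planted_clusters(self) -> dict[str, set[str]]:
        t = self.truth[self.truth.cluster_id != ""]
        out: dict[str, set[str]] = {}
        for pid, cid in zip(t.protein_id, t.cluster_id):
            out.setdefault(cid, set()).add(pid)
        return out


def make_decoys(n: int, length_range: tuple[int, int] = (120, 600),
                seed: int | np.random.Generator = 0,
                species_roster: tuple[str, ...] = SANDFLY_SPECIES
                ) -> list[ProteinRecord]:
    """Random-composition proteins with no planted family signature."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        sp = species_roster[i % len(species_roster)]
        out.append(ProteinRecord(f"decoy{i + 1:03d}", sp, _to_str(_random_protein(rng, length))))
    return out


def _blast_hit(gene: str, family: str, length: int, rng: np.random.Generator
               ) -> HitRecord:
    evalue = 10.0 ** -float(rng.integers(20, 120))
    return HitRecord(
        query_id=gene, subject_id=f"REF_{family}", evalue=evalue,
        aln_len_aa=length, q_start=1, q_end=length, s_start=1, s_end=length,
        bitscore=round(1.9 * length, 1), source="blast_tab",
    )


def _domain_hits(gene: str, domains: tuple[str, ...], length: int,
                 rng: np.random.Generator) -> list[HitRecord]:
    hits = []
    n = len(domains)
    seg = length // n
    for i, dom in enumerate(domains):
        start = i * seg + 3
        end = min(length, (i + 1) * seg - 2)
        evalue = 10.0 ** -float(rng.integers(10, 60))
        hits.append(
            HitRecord(
                query_id=gene, subject_id=dom, evalue=evalue,
                aln_len_aa=end - start + 1, q_start=start, q_end=end,
                s_start=1, s_end=end - start + 1,
                bitscore=round(1.1 * (end - start), 1), source="hmmer_dom",
            )
        )
    return hits


def _build_family(plan: FamilyPlan, sandfly_root: _Node,
                  rng: np.random.Generator, mutation_scale: float):
    """Build one family: gene genealogy, sequences, truth rows."""
    full_len = FAMILY_FULL_LEN[plan.family]
    full_min = FAMILY_FULL_MIN[plan.family]
    frag_lo = 100
    expansion_by_subfam = {e.subfamily: e for e in plan.expansions}

    subfam_trees: list[_Node] = []
    leaf_meta: dict[str, dict] = {}  # gene_id -> metadata

    # --- choose fragment scenario slots over non-expanded subfamilies
    # (expression-plan subfamilies stay fully intact so every species keeps
    # its dominant/competitor pair)
    excluded = set(expansion_by_subfam)
    if plan.expression_plan is not None:
        excluded |= {
            plan.expression_plan.dominant_subfamily,
            plan.expression_plan.competitor_subfamily,
        }
    plain_subfams = [s for s in plan.subfamily_names() if s not in excluded]
    slots = [(sf, sp) for sf in plain_subfams for sp in SANDFLY_SPECIES]
    n_genes_planned = 0
    for sf in plan.subfamily_names():
        exp = expansion_by_subfam.get(sf)
        for sp in SANDFLY_SPECIES:
            n_genes_planned += exp.copies if exp and sp in exp.species else 1
    n_frag_only = min(
        len(slots), max(0, round(plan.effective_fragment_rate * n_genes_planned)
                        - plan.n_competing_fragment_pairs)
    )
    order = rng.permutation(len(slots))
    frag_only_slots = {slots[i] for i in order[:n_frag_only]}
    rest = [slots[i] for i in order[n_frag_only:]]
    competing_slots = set(rest[: plan.n_competing_fragment_pairs])
    rest = rest[plan.n_competing_fragment_pairs:]
    redundant_frag_slots = set(rest[: plan.n_redundant_with_full_fragments])

    for sf in plan.subfamily_names():
        exp = expansion_by_subfam.get(sf)
        counters: dict[str, int] = {}

        def new_gene(sp: str) -> str:
            counters[sp] = counters.get(sp, 0) + 1
            return f"{sf}_{sp}{counters[sp]}"

        def leaf_for(sp: str, bl: float, kind: str) -> _Node:
            gene = new_gene(sp)
            leaf_meta[gene] = {"species": sp, "subfamily": sf, "kind": kind}
            return _Node(bl=bl, label=f"{sp}|{gene}")

        def build(node: _Node) -> _Node:
            if not node.children:
                sp = node.label
                if exp and exp.kind == "species_specific" and sp in exp.species:
                    copies = [leaf_for(sp, 0.08, "full") for _ in range(exp.copies)]
                    cat = _caterpillar(copies)
                    cat.bl = node.bl
                    return cat
                slot = (sf, sp)
                if slot in frag_only_slots:
                    return _replace_with(leaf_for(sp, node.bl, "frag_rescued"))
                if slot in competing_slots:
                    a = leaf_for(sp, 0.08, "frag_compete")
                    b = leaf_for(sp, 0.08, "frag_compete")
                    pair = _Node(children=[a, b], bl=node.bl)
                    return pair
                if slot in redundant_frag_slots:
                    full = leaf_for(sp, 0.08, "full")
                    frag = leaf_for(sp, 0.08, "frag_redundant")
                    return _Node(children=[full, frag], bl=node.bl)
                return _replace_with(leaf_for(sp, node.bl, "full"))
            return _Node(
                children=[build(ch) for ch in node.children], bl=node.bl
            )

        def _replace_with(leaf: _Node) -> _Node:
            return leaf

        if exp and exp.kind == "lineage_specific":
            if _find_clade_node(sandfly_root, frozenset(exp.species)) is None:
                raise ValueError(
                    f"expansion species {exp.species} do not form a clade "
                    "in the species tree"
                )
            target_set = frozenset(exp.species)

            def build_lineage(node: _Node) -> _Node:
                if frozenset(l.label for l in node.leaves()) == target_set:
                    copies = []
                    for _ in range(exp.copies):
                        copies.append(build(_copy_node(node)))
                    cat = _caterpillar(copies)
                    cat.bl = node.bl
                    return cat
                if not node.children:
                    return build(node)
                return _Node(
                    children=[build_lineage(ch) for ch in node.children],
                    bl=node.bl,
                )

            subfam_trees.append(build_lineage(_copy_node(sandfly_root)))
        else:
            subfam_trees.append(build(_copy_node(sandfly_root)))

    family_tree = (
        subfam_trees[0] if len(subfam_trees) == 1
        else _caterpillar(subfam_trees, internal_bl=0.25)
    )

    # --- evolve sequences down the genealogy
    sequences: dict[str, np.ndarray] = {}
    ancestor = _random_protein(rng, full_len)

    def evolve(node: _Node, seq: np.ndarray) -> None:
        p = min(0.5, node.bl * mutation_scale)
        seq = _mutate(seq, p, rng)
        if not node.children:
            sequences[node.label.split("|", 1)[1]] = seq
        else:
            for ch in node.children:
                evolve(ch, seq)

    evolve(family_tree, ancestor)
    return family_tree, leaf_meta, sequences


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Emit one synthetic world: FASTA, hit tables, gene trees, GFF,
    orthogroup table, TPM matrix, and the truth table tying them together."""
    rng = np.random.default_rng(spec.seed)
    species_tree = dio.read_tree(StringIO(spec.species_tree_newick), require_labels=False)
    roster = {l.name for l in species_tree.tree.get_terminals()}
    for plan in spec.families:
        for exp in plan.expansions:
            missing = set(exp.species) - roster
            if missing:
                raise ValueError(
                    f"expansion references species absent from the species tree: "
                    f"{sorted(missing)}"
                )

    sandfly_clade = None
    for clade in species_tree.tree.find_clades():
        if frozenset(l.name for l in clade.get_terminals()) == frozenset(SANDFLY_SPECIES):
            sandfly_clade = clade
            break
    if sandfly_clade is None:
        raise ValueError("species tree lacks the sand fly ingroup clade")
    sandfly_root = _clade_to_node(sandfly_clade)
    sandfly_root.bl = 0.0

    proteins: list[ProteinRecord] = []
    hits: dict[str, list[HitRecord]] = {}
    gene_trees: dict[str, TreeDoc] = {}
    loci: list[GeneLocus] = []
    truth_rows: list[dict] = []
    tpm_gene_means: dict[str, tuple[str, float]] = {}  # gene -> (species, mean tpm)

    for plan in spec.families:
        family = plan.family
        full_min = FAMILY_FULL_MIN[family]
        family_tree, leaf_meta, sequences = _build_family(
            plan, sandfly_root, rng, spec.mutation_scale
        )
        gene_trees[family] = dio.read_tree(StringIO(family_tree.newick()))
        fam_hits: list[HitRecord] = []
        expansion_by_subfam = {e.subfamily: e for e in plan.expansions}

        # fragment length draws + per-slot winner bookkeeping
        compete_best: dict[tuple[str, str], tuple[int, str]] = {}
        emitted: dict[str, tuple[str, int, bool]] = {}  # gene -> (seq, len, is_frag)

        for gene, meta in leaf_meta.items():
            seq = sequences[gene]
            kind = meta["kind"]
            if kind.startswith("frag"):
                frag_len = int(rng.integers(100, full_min))
                start = int(rng.integers(0, seq.size - frag_len + 1))
                s = _to_str(seq[start : start + frag_len])
                is_frag = True
            else:
                s = _to_str(seq)
                is_frag = False
            emitted[gene] = (s, len(s), is_frag)
            if kind == "frag_compete":
                slot = (meta["subfamily"], meta["species"])
                cur = compete_best.get(slot)
                cand = (len(s), gene)
                # longest wins; ties break to the lexicographically smaller id
                if cur is None or (cand[0], _RevStr(cand[1])) > (cur[0], _RevStr(cur[1])):
                    compete_best[slot] = cand

        for gene, meta in leaf_meta.items():
            s, length, is_frag = emitted[gene]
            sp, sf, kind = meta["species"], meta["subfamily"], meta["kind"]
            proteins.append(ProteinRecord(gene, sp, s))
            if FAMILY_EVIDENCE[family] == "blast_reference":
                fam_hits.append(_blast_hit(gene, family, length, rng))
            else:
                fam_hits.extend(_domain_hits(gene, FAMILY_DOMAINS[family], length, rng))

            if kind == "full":
                status = "kept_full"
            elif kind == "frag_rescued":
                status = "rescued_fragment"
            elif kind == "frag_redundant":
                status = "discarded_fragment_redundant_with_full"
            else:  # frag_compete
                winner = compete_best[(sf, sp)][1]
                status = (
                    "rescued_fragment" if gene == winner
                    else "discarded_fragment_not_longest"
                )
            exp = expansion_by_subfam.get(sf)
            truth_rows.append(
                {
                    "protein_id": gene, "species": sp, "family": family,
                    "subfamily": sf, "kind": "gene", "is_fragment": is_frag,
                    "is_decoy": False,
                    "expected_status": status,
                    "in_planted_repertoire": status in ("kept_full", "rescued_fragment"),
                    "expansion_scope": exp.kind if exp else "none",
                    "expansion_species": ",".join(exp.species) if exp else "",
                    "redundancy_group_99": "", "redundancy_group_95": "",
                    "cluster_id": "", "contig": "", "start": 0, "end": 0,
                }
            )

        # --- isoform redundancy (>= 99.3% identity) and ~97% near-duplicates
        full_genes = [g for g, m in leaf_meta.items() if m["kind"] == "full"]
        n_iso = round(plan.redundancy_rate * len(full_genes))
        n_near = round(plan.near_duplicate_rate * len(full_genes))
        chosen = [str(g) for g in rng.permutation(full_genes)]
        for g in chosen[:n_iso]:
            seq = sequences[g]
            m = max(1, int(0.004 * seq.size))
            iso = _mutate_exact(seq, m, rng)[: seq.size - 2]
            pid = f"{g}.iso1"
            proteins.append(ProteinRecord(pid, leaf_meta[g]["species"], _to_str(iso)))
            truth_rows.append(
                _artifact_row(pid, leaf_meta[g]["species"], family,
                              leaf_meta[g]["subfamily"], kind="isoform",
                              group99=g, group95=g)
            )
        for g in chosen[n_iso : n_iso + n_near]:
            seq = sequences[g]
            m = max(1, int(0.03 * seq.size))
            near = _mutate_exact(seq, m, rng)
            pid = f"{g}.near1"
            proteins.append(ProteinRecord(pid, leaf_meta[g]["species"], _to_str(near)))
            truth_rows.append(
                _artifact_row(pid, leaf_meta[g]["species"], family,
                              leaf_meta[g]["subfamily"], kind="near_duplicate",
                              group99="", group95=g)
            )
        iso_parents = set(chosen[:n_iso])
        near_parents = set(chosen[n_iso : n_iso + n_near])
        for row in truth_rows:
            pid = row["protein_id"]
            if pid in iso_parents:
                row["redundancy_group_99"] = pid
                row["redundancy_group_95"] = pid
            elif pid in near_parents:
                row["redundancy_group_95"] = pid

        # --- genomic clusters and scattered singleton loci
        cluster_members: set[str] = set()
        for cp in plan.cluster_plan:
            members = sorted(
                g for g, m in leaf_meta.items()
                if m["subfamily"] == cp.subfamily and m["species"] == cp.species
                and not emitted[g][2]
            )
            pos = 10_000
            cid = f"{cp.contig}#{cp.subfamily}"
            for g in members:
                gene_len = int(rng.integers(1_500, 3_000))
                loci.append(GeneLocus(g, cp.contig, pos, pos + gene_len,
                                      "+" if rng.random() < 0.5 else "-"))
                for row in truth_rows:
                    if row["protein_id"] == g:
                        row["cluster_id"] = cid
                        row["contig"] = cp.contig
                        row["start"] = pos
                        row["end"] = pos + gene_len
                gap = int(rng.integers(*cp.gap_range_bp))
                pos += gap
                cluster_members.add(g)
        # singletons of clustered species go far apart on a separate scaffold
        for cp in plan.cluster_plan:
            others = sorted(
                g for g, m in leaf_meta.items()
                if m["species"] == cp.species and g not in cluster_members
                and not emitted[g][2]
            )
            pos = 50_000
            for g in others:
                gene_len = int(rng.integers(1_500, 3_000))
                loci.append(
                    GeneLocus(g, f"{cp.contig}_scattered", pos, pos + gene_len, "+")
                )
                pos += 300_000  # >> 50 kb: never clusters
            cluster_members.update(others)

        # --- expression baselines and planted dominance (fragments get a
        # baseline too: partial transcripts are still quantified)
        for gene, meta in leaf_meta.items():
            base = 10.0 ** float(rng.normal(1.0, 0.6))
            tpm_gene_means[gene] = (meta["species"], min(base, 2_000.0))
        if plan.expression_plan is not None:
            ep = plan.expression_plan
            for sp in SANDFLY_SPECIES:
                hi = [g for g, m in leaf_meta.items()
                      if m["subfamily"] == ep.dominant_subfamily
                      and m["species"] == sp and not emitted[g][2]]
                lo = [g for g, m in leaf_meta.items()
                      if m["subfamily"] == ep.competitor_subfamily
                      and m["species"] == sp and not emitted[g][2]]
                if hi and lo:
                    tpm_gene_means[hi[0]] = (sp, 5_000.0)
                    tpm_gene_means[lo[0]] = (sp, 5_000.0 / ep.fold)

        hits[family] = fam_hits

    # --- decoys (plus a few non-qualifying hit rows to exercise the gate)
    decoys = make_decoys(spec.n_decoys, seed=rng)
    proteins.extend(decoys)
    for d in decoys:
        truth_rows.append(
            {
                "protein_id": d.protein_id, "species": d.species, "family": "",
                "subfamily": "", "kind": "decoy", "is_fragment": False,
                "is_decoy": True, "expected_status": "",
                "in_planted_repertoire": False,
                "expansion_scope": "", "expansion_species": "",
                "redundancy_group_99": "", "redundancy_group_95": "",
                "cluster_id": "", "contig": "", "start": 0, "end": 0,
            }
        )
    if decoys and spec.families:
        first_family = spec.families[0].family
        for d in decoys[:: max(1, len(decoys) // 5)]:
            hits[first_family].append(
                HitRecord(
                    query_id=d.protein_id, subject_id=f"REF_{first_family}",
                    evalue=0.01, aln_len_aa=min(80, d.length_aa),
                    q_start=1, q_end=min(80, d.length_aa),
                    s_start=1, s_end=min(80, d.length_aa),
                    bitscore=30.0, source="blast_tab"
                    if FAMILY_EVIDENCE[first_family] == "blast_reference"
                    else "hmmer_dom",
                )
            )

    # --- replicate-level TPM matrix (3 replicates per species)
    genes = sorted(tpm_gene_means)
    columns = [f"{sp}|rep{i}" for sp in SANDFLY_SPECIES for i in (1, 2, 3)]
    data = np.zeros((len(genes), len(columns)))
    for gi, gene in enumerate(genes):
        sp, mean = tpm_gene_means[gene]
        for ci, col in enumerate(columns):
            if col.split("|")[0] == sp:
                data[gi, ci] = mean * 10.0 ** float(rng.normal(0.0, 0.05))
    tpm = ExpressionMatrix(
        tpm=pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=columns),
        replicate_species={c: c.split("|")[0] for c in columns},
    )

    og_table, og_truth, og_totals = generate_orthogroups(
        rng, roster=tuple(sorted(roster)),
        n_per_category=spec.n_orthogroups_per_category,
    )

    truth = pd.DataFrame(truth_rows)
    return Dataset(
        species_tree=species_tree,
        proteins=proteins,
        hits=hits,
        gene_trees=gene_trees,
        loci=loci,
        orthogroups=og_table,
        orthogroup_totals=og_totals,
        tpm=tpm,
        truth=truth,
        og_truth=og_truth,
    )


class _RevStr(str):
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _artifact_row(pid, species, family, subfamily, kind, group99, group95):
    return {
        "protein_id": pid, "species": species, "family": family,
        "subfamily": subfamily, "kind": kind, "is_fragment": False,
        "is_decoy": False, "expected_status": "",
        "in_planted_repertoire": False,
        "expansion_scope": "", "expansion_species": "",
        "redundancy_group_99": group99, "redundancy_group_95": group95,
        "cluster_id": "", "contig": "", "start": 0, "end": 0,
    }


def generate_orthogroups(rng: np.random.Generator,
                         roster: tuple[str, ...],
                         n_per_category: int = 4,
                         named_clades: dict[str, frozenset[str]] | None = None
                         ) -> tuple[OrthogroupTable, pd.DataFrame, dict[str, int]]:
    """Generic orthogroups with planted profile categories, plus per-species
    totals that include a few unassigned singleton genes."""
    named_clades = named_clades or {
        k: v for k, v in NAMED_CLADES.items() if v <= set(roster)
    }
    roster_set = frozenset(roster)
    groups: dict[str, dict[str, list[str]]] = {}
    rows = []
    counter = 0

    def add(presence: frozenset[str], category: str) -> None:
        nonlocal counter
        counter += 1
        og_id = f"OG{counter:05d}"
        per_species = {}
        for sp in roster:
            if sp in presence:
                n = int(rng.integers(1, 4))
                per_species[sp] = [f"{og_id}_{sp}_g{j + 1}" for j in range(n)]
            else:
                per_species[sp] = []
        groups[og_id] = per_species
        rows.append({"og_id": og_id, "category": category})

    forbidden = {roster_set} | set(named_clades.values())
    for _ in range(n_per_category):
        add(roster_set, "universal_all_taxa")
    for name, clade in named_clades.items():
        for _ in range(n_per_category):
            add(clade, f"clade_restricted:{name}")
    need = max(2, int(np.ceil(0.5 * len(roster))))
    for _ in range(n_per_category):
        while True:
            size = int(rng.integers(need, len(roster)))
            subset = frozenset(rng.choice(roster, size=size, replace=False))
            if subset not in forbidden:
                break
        add(subset, "widespread")
    for _ in range(n_per_category):
        while True:
            size = int(rng.integers(2, max(3, need)))
            subset = frozenset(rng.choice(roster, size=size, replace=False))
            if subset not in forbidden and len(subset) / len(roster) < 0.5:
                break
        add(subset, "multi_species")
    for _ in range(n_per_category):
        sp = str(rng.choice(roster))
        add(frozenset({sp}), "species_specific")

    table = OrthogroupTable(species=list(roster), groups=groups)
    assigned = {sp: 0 for sp in roster}
    for per_species in groups.values():
        for sp, genes in per_species.items():
            assigned[sp] += len(genes)
    totals = {sp: assigned[sp] + int(rng.integers(0, 6)) for sp in roster}
    return table, pd.DataFrame(rows), totals


def make_site_alignment(seed: int = 0,
                        genotypes: dict[str, dict[str, str]] | None = None,
                        reference_id: str = "Agam|AGAP004707-RD",
                        length: int = 1650) -> dict[str, str]:
    """A synthetic channel-protein alignment with planted residues at the
    two kdr positions (L995, N1570) under reference numbering.

    ``genotypes`` maps species -> {site_label: residue}; unlisted species
    are wildtype.  The alignment is ungapped by construction (tests insert
    gap columns to probe mapping invariance).
    """
    rng = np.random.default_rng(seed)
    genotypes = genotypes or {}
    ref = _random_protein(rng, length)
    sites = {"L995": (995, "L"), "N1570": (1570, "N")}
    aa_index = {a: i for i, a in enumerate(AA)}
    for pos, wt in sites.values():
        ref[pos - 1] = aa_index[wt]
    rows = {reference_id: _to_str(ref)}
    for sp in SANDFLY_SPECIES:
        seq = _mutate(ref, 0.02, rng)
        for label, (pos, wt) in sites.items():
            residue = genotypes.get(sp, {}).get(label, wt)
            seq[pos - 1] = aa_index[residue]
        rows[f"{sp}|VGSC_{sp}"] = _to_str(seq)
    return rows
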