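"""Per-species gene-family repertoire curation.

The curation mirrors how transcriptome-derived detoxification repertoires
are built: candidates are gated on similarity evidence (BLAST hits at
e-value <= 1e-3, or required Pfam domains from HMMER), partitioned into
full-length versus incomplete proteins by a family-specific length threshold
(300 aa for CYP/UGT/CCE/ABC, 150 aa for GST; 100 aa floor), and fragments
are rescued per ortholog group only where a species lacks any full-length
member — keeping the single longest fragment and discarding the rest as
partial transcripts or assembly artifacts.

Special-case ids (e.g. an Ace1 ortholog recovered below the 100 aa floor)
bypass the floor but are flagged ``below_floor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import HitRecord, ProteinRecord, TreeDoc
from .expansion import rescue_groups

__all__ = [
    "FamilyRule",
    "RepertoireEntry",
    "DEFAULT_RULES",
    "identify_candidates",
    "partition_by_length",
    "rescue_fragments",
    "curate_family",
    "repertoire_summary",
]

STATUSES = (
    "kept_full",
    "rescued_fragment",
    "discarded_short",
    "discarded_fragment_redundant_with_full",
    "discarded_fragment_not_longest",
    "discarded_no_hit",
)


@dataclass(frozen=True)
class FamilyRule:
    family: str  # {CYP, GST, UGT, CCE, ABC}
    evidence: str  # {blast_reference, hmm_domains}
    evalue_max: float = 1e-3
    full_min_aa: int = 300
    frag_min_aa: int = 100
    required_domains: tuple[str, ...] = ()
    special_rescue_ids: tuple[str, ...] = ()
    # blast evidence gates on merged query coverage; hmm evidence gates on
    # polypeptide length (mirrors "query coverage" vs "polypeptide size")
    gate_on: str = "auto"  # {auto, coverage, length}

    def __post_init__(self) -> None:
        if self.frag_min_aa >= self.full_min_aa:
            raise ValueError("frag_min_aa must be < full_min_aa")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.evidence not in ("blast_reference", "hmm_domains"):
            raise ValueError(f"unknown evidence kind {self.evidence!r}")

    @property
    def effective_gate(self) -> str:
        if self.gate_on != "auto":
            return self.gate_on
        return "coverage" if self.evidence == "blast_reference" else "length"


DEFAULT_RULES: dict[str, FamilyRule] = {
    "CYP": FamilyRule("CYP", "blast_reference", full_min_aa=300),
    "GST": FamilyRule(
        "GST", "hmm_domains", full_min_aa=150,
        required_domains=("PF02798", "PF00043"),
    ),
    "UGT": FamilyRule(
        "UGT", "hmm_domains", full_min_aa=300, required_domains=("PF00201",)
    ),
    "CCE": FamilyRule(
        "CCE", "hmm_domains", full_min_aa=300, required_domains=("PF00135",)
    ),
    "ABC": FamilyRule("ABC", "blast_reference", full_min_aa=300),
}


@dataclass(frozen=True)
class RepertoireEntry:
    protein_id: str
    species: str
    family: str
    coverage_aa: int
    length_class: str = ""  # {full, fragment} once partitioned
    status: str = ""
    ortholog_group_id: str | None = None
    below_floor: bool = False


def _merged_span(intervals: list[tuple[int, int]]) -> int:
    """Total residues covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end + 1:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start + 1
    return covered


def identify_candidates(proteins: list[ProteinRecord], hits: list[HitRecord],
                        rule: FamilyRule) -> list[RepertoireEntry]:
    """Gate proteins on similarity evidence.

    A protein is a candidate iff it has at least one hit with
    evalue <= ``rule.evalue_max`` and, for domain evidence, carries every
    required domain at a qualifying e-value.  ``coverage_aa`` is the merged
    qualifying-hit query span (blast gating) or the polypeptide length
    (domain gating).
    """
    known = {p.protein_id: p for p in proteins}
    per_protein: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.query_id not in known:
            raise ValueError(f"hit references unknown protein {h.query_id!r}")
        if h.evalue <= rule.evalue_max:
            per_protein.setdefault(h.query_id, []).append(h)

    entries: list[RepertoireEntry] = []
    for p in proteins:
        qualifying = per_protein.get(p.protein_id, [])
        if rule.evidence == "hmm_domains" and rule.required_domains:
            present = {h.subject_id for h in qualifying}
            if not set(rule.required_domains) <= present:
                qualifying = []
        if not qualifying:
            entries.append(
                RepertoireEntry(p.protein_id, p.species, rule.family,
                                coverage_aa=0, status="discarded_no_hit")
            )
            continue
        if rule.effective_gate == "coverage":
            coverage = _merged_span([(h.q_start, h.q_end) for h in qualifying])
        else:
            coverage = p.length_aa
        entries.append(
            RepertoireEntry(p.protein_id, p.species, rule.family,
                            coverage_aa=coverage)
        )
    return entries


def partition_by_length(drafts: list[RepertoireEntry],
                        rule: FamilyRule) -> list[RepertoireEntry]:
    """Assign length classes: full (kept), fragment (pending rescue), or
    discarded_short; special-rescue ids below the floor stay pending."""
    out: list[RepertoireEntry] = []
    for d in drafts:
        if d.status == "discarded_no_hit":
            out.append(d)
        elif d.coverage_aa >= rule.full_min_aa:
            out.append(replace(d, length_class="full", status="kept_full"))
        elif d.coverage_aa >= rule.frag_min_aa:
            out.append(replace(d, length_class="fragment", status=""))
        elif d.protein_id in rule.special_rescue_ids:
            out.append(
                replace(d, length_class="fragment", status="", below_floor=True)
            )
        else:
            out.append(replace(d, length_class="fragment", status="discarded_short"))
    return out


def rescue_fragments(drafts: list[RepertoireEntry], gene_tree: TreeDoc,
                     rule: FamilyRule) -> list[RepertoireEntry]:
    """Resolve pending fragments per ortholog group and species.

    Ortholog groups are species-overlap clades of the gene tree over the
    full and pending-fragment leaves, with duplications inferred from the
    full-length leaves only (fragments are placed in the tree but never
    create duplications).  Within a (group x species): any full member
    discards every fragment of that species; otherwise the single longest
    fragment is rescued (ties broken lexicographically by id) and the rest
    are discarded.
    """
    pending = [d for d in drafts if d.length_class == "fragment" and d.status == ""]
    fulls = [d for d in drafts if d.status == "kept_full"]
    active_ids = {d.protein_id for d in pending} | {d.protein_id for d in fulls}

    tree_ids = set(gene_tree.gene_ids)
    missing = active_ids - tree_ids
    if missing:
        raise ValueError(
            f"drafts absent from gene tree: {sorted(missing)}"
        )

    groups = rescue_groups(
        gene_tree,
        full_ids={d.protein_id for d in fulls},
        fragment_ids={d.protein_id for d in pending},
    )
    og_of: dict[str, str] = {}
    for g in groups:
        for label in g.members:
            og_of[label.split("|", 1)[1]] = g.og_id

    full_sp_og = {
        (d.species, og_of[d.protein_id]) for d in fulls if d.protein_id in og_of
    }
    # choose winners among fragments sharing (species, og)
    by_slot: dict[tuple[str, str], list[RepertoireEntry]] = {}
    for d in pending:
        by_slot.setdefault((d.species, og_of[d.protein_id]), []).append(d)

    resolution: dict[str, str] = {}
    for slot, frags in by_slot.items():
        if slot in full_sp_og:
            for d in frags:
                resolution[d.protein_id] = "discarded_fragment_redundant_with_full"
            continue
        winner = max(frags, key=lambda d: (d.coverage_aa, _neg_id(d.protein_id)))
        for d in frags:
            resolution[d.protein_id] = (
                "rescued_fragment" if d is winner else "discarded_fragment_not_longest"
            )

    out: list[RepertoireEntry] = []
    for d in drafts:
        og = og_of.get(d.protein_id)
        if d.protein_id in resolution:
            out.append(replace(d, status=resolution[d.protein_id],
                               ortholog_group_id=og))
        elif d.status == "kept_full":
            out.append(replace(d, ortholog_group_id=og))
        else:
            out.append(d)
    return out


class _neg_id(str):
    """Reverses lexicographic comparison so max() picks the smallest id on
    coverage ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def curate_family(proteins: list[ProteinRecord], hits: list[HitRecord],
                  gene_tree: TreeDoc, rule: FamilyRule) -> list[RepertoireEntry]:
    """identify -> partition -> rescue, in one call."""
    drafts = partition_by_length(identify_candidates(proteins, hits, rule), rule)
    return rescue_fragments(drafts, gene_tree, rule)


def repertoire_summary(entries: list[RepertoireEntry],
                       display_decimals: int = 1) -> dict:
    """Counts of curated (kept) genes and full/fragment percentages.

    Percentages are computed at one decimal; ``display_decimals`` controls
    only the formatted strings (some families are conventionally printed
    with two decimals).
    """
    kept = [e for e in entries if e.status in ("kept_full", "rescued_fragment")]
    n_full = sum(1 for e in kept if e.status == "kept_full")
    n_fragment = sum(1 for e in kept if e.status == "rescued_fragment")
    n_total = len(kept)
    per_species: dict[str, int] = {}
    for e in kept:
        per_species[e.species] = per_species.get(e.species, 0) + 1
    status_counts = {s: sum(1 for e in entries if e.status == s) for s in STATUSES}
    if n_total == 0:
        return {
            "n_total": 0, "n_full": 0, "n_fragment": 0,
            "pct_full": None, "pct_fragment": None,
            "pct_full_str": "", "pct_fragment_str": "",
            "per_species": per_species, "status_counts": status_counts,
        }
    pct_full = round(100.0 * n_full / n_total, 1)
    pct_fragment = round(100.0 * n_fragment / n_total, 1)
    return {
        "n_total": n_total,
        "n_full": n_full,
        "n_fragment": n_fragment,
        "pct_full": pct_full,
        "pct_fragment": pct_fragment,
        "pct_full_str": f"{pct_full:.{display_decimals}f}",
        "pct_fragment_str": f"{pct_fragment:.{display_decimals}f}",
        "per_species": per_species,
        "status_counts": status_counts,
    }
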