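"""Orthology-profile classification of gene counts.

Each orthogroup's species-presence pattern places it on a ladder from
universally present to species-specific, and each species' annotated genes
are partitioned by the category of the orthogroup they belong to (genes in
no orthogroup are ``unassigned``).  Presence means >= 1 gene; copy number is
reported separately and never affects the category.

Default ladder (first match wins, top-down):

1. ``universal_all_taxa`` — present in every roster species;
2. ``clade_restricted:<name>`` — presence set equals a named, monophyletic
   species-tree clade;
3. ``widespread`` — present in >= a threshold fraction of the roster
   (default 0.5);
4. ``multi_species`` — present in >= 2 species;
5. ``species_specific`` — present in exactly one species.

Named clades are checked before the widespread threshold so that, e.g., an
orthogroup spanning exactly one family's clade is reported as restricted to
it rather than merely widespread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import OrthogroupTable, TreeDoc

__all__ = ["ProfileLadder", "classify_orthogroups"]


@dataclass
class ProfileLadder:
    named_clades: dict[str, frozenset[str]] = field(default_factory=dict)
    widespread_fraction: float = 0.5

    def categories(self) -> list[str]:
        return (
            ["universal_all_taxa"]
            + [f"clade_restricted:{name}" for name in self.named_clades]
            + ["widespread", "multi_species", "species_specific", "unassigned"]
        )

    def classify(self, presence: frozenset[str], roster: frozenset[str]) -> str:
        if not presence:
            return "unassigned"
        if presence == roster:
            return "universal_all_taxa"
        for name, clade in self.named_clades.items():
            if presence == clade:
                return f"clade_restricted:{name}"
        if len(presence) / len(roster) >= self.widespread_fraction and len(presence) >= 2:
            return "widespread"
        if len(presence) >= 2:
            return "multi_species"
        return "species_specific"


def _validate_clades(ladder: ProfileLadder, species_tree: TreeDoc) -> None:
    tree_clades = {
        frozenset(l.name for l in clade.get_terminals())
        for clade in species_tree.tree.find_clades()
    }
    for name, members in ladder.named_clades.items():
        if members not in tree_clades:
            raise ValueError(f"named clade {name!r} is not monophyletic in the species tree")


def classify_orthogroups(table: OrthogroupTable, species_tree: TreeDoc,
                         ladder: ProfileLadder | None = None,
                         totals: dict[str, int] | None = None) -> dict:
    """Classify every orthogroup and partition per-species gene counts.

    ``totals`` gives each species' total annotated gene count; genes not in
    any orthogroup are counted as ``unassigned`` (defaults to the genes seen
    in the table, i.e. zero unassigned).

    Returns ``{"og_category": {og: cat}, "counts": {species: {cat: n}}}``
    with, for every species, the category counts summing to its total.
    """
    ladder = ladder or ProfileLadder()
    roster = frozenset(l.name for l in species_tree.tree.get_terminals())
    unknown = set(table.species) - roster
    if unknown:
        raise ValueError(f"table species absent from species tree: {sorted(unknown)}")
    _validate_clades(ladder, species_tree)

    og_category: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {
        sp: {cat: 0 for cat in ladder.categories()} for sp in table.species
    }
    assigned: dict[str, int] = {sp: 0 for sp in table.species}
    for og_id, per_species in table.groups.items():
        presence = frozenset(table.presence(og_id))
        cat = ladder.classify(presence, roster)
        og_category[og_id] = cat
        for sp, genes in per_species.items():
            counts[sp][cat] += len(genes)
            assigned[sp] += len(genes)

    for sp in table.species:
        total = assigned[sp] if totals is None else totals[sp]
        if total < assigned[sp]:
            raise ValueError(
                f"species {sp}: total {total} below assigned gene count {assigned[sp]}"
            )
        counts[sp]["unassigned"] = total - assigned[sp]

    return {"og_category": og_category, "counts": counts}
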