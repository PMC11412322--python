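"""Ortholog groups, duplication inference, and gene-family expansion calls.

Duplications are inferred on midpoint-rooted gene trees with the
species-overlap criterion: an internal node is a duplication iff the species
sets of its children intersect.  Ortholog groups are the maximal clades free
of duplication nodes; only full-length proteins are counted, so fragments in
the tree never affect a call.

Expansion scope of an ortholog-group complex (a clade whose duplications are
all "shallow", i.e. do not span the entire species roster):

* ``species_specific`` — exactly one species has copy number > 1;
* ``lineage_specific`` — the multi-copy species form a monophyletic clade
  (>= 2 species) in the species tree;
* ``none`` — no duplication, or multi-copy species not forming a clade.

Family-size distribution helpers quantify the "Many and the Few" pattern
(many small subfamilies, a few very large ones) via top-k shares and the
Gini coefficient, plus clan fractions (e.g. the CYP3 clan share of a CYPome).
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import TreeDoc

__all__ = [
    "OrthologGroup",
    "ExpansionCall",
    "midpoint_root",
    "prune_to",
    "duplication_nodes",
    "infer_ortholog_groups",
    "rescue_groups",
    "ortholog_relations",
    "call_expansions",
    "family_size_distribution",
    "gini",
]


@dataclass
class OrthologGroup:
    og_id: str
    members: list[str]  # leaf labels "species|gene"
    species: dict[str, int]  # species -> copy number within the group


@dataclass
class ExpansionCall:
    og_id: str
    scope: str  # {none, species_specific, lineage_specific}
    species: tuple[str, ...]  # multi-copy species (expansion carriers)
    copy_numbers: dict[str, int]


def _leaf_species(label: str) -> str:
    return label.split("|", 1)[0]


def midpoint_root(doc: TreeDoc) -> TreeDoc:
    """Root a gene tree at the midpoint of its longest leaf-to-leaf path."""
    tree = copy.deepcopy(doc.tree)
    for clade in tree.find_clades():
        if clade is not tree.root and clade.branch_length is None:
            raise ValueError("midpoint rooting requires branch lengths on every edge")
    total = tree.total_branch_length()
    if total == 0:
        raise ValueError("midpoint rooting undefined on a zero-length tree")
    tree.root_at_midpoint()
    out = TreeDoc.__new__(TreeDoc)
    out.tree = tree
    return out


def prune_to(doc: TreeDoc, keep_labels: set[str]) -> TreeDoc:
    """Restrict a tree to the given leaf labels, suppressing unary nodes and
    summing their branch lengths."""
    tree = copy.deepcopy(doc.tree)

    def rebuild(clade):
        if clade.is_terminal():
            return clade if clade.name in keep_labels else None
        kept = [c for c in (rebuild(ch) for ch in clade.clades) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if clade.branch_length is not None and child.branch_length is not None:
                child.branch_length += clade.branch_length
            return child
        clade.clades = kept
        return clade

    root = rebuild(tree.root)
    if root is None:
        raise ValueError("pruning removed every leaf")
    tree.root = root
    out = TreeDoc.__new__(TreeDoc)
    out.tree = tree
    return out


def _species_sets(root, count_gene_ids: set[str] | None = None) -> dict[int, set[str]]:
    """Species set under every clade, bottom-up in one traversal.

    With ``count_gene_ids``, only leaves whose gene id is in the set
    contribute (used to infer duplications from full-length proteins only).
    """
    sets: dict[int, set[str]] = {}

    def walk(clade) -> set[str]:
        if clade.is_terminal():
            if (count_gene_ids is not None
                    and clade.name.split("|", 1)[1] not in count_gene_ids):
                s: set[str] = set()
            else:
                s = {_leaf_species(clade.name)}
        else:
            s = set()
            for ch in clade.clades:
                s |= walk(ch)
        sets[id(clade)] = s
        return s

    walk(root)
    return sets


def duplication_nodes(doc: TreeDoc, count_gene_ids: set[str] | None = None
                      ) -> dict[int, bool]:
    """Species-overlap duplication labels: id(clade) -> is_duplication.

    ``count_gene_ids`` restricts the species sets to those leaves (e.g.
    full-length proteins), so other leaves never create duplications.
    """
    sets = _species_sets(doc.tree.root, count_gene_ids)
    labels: dict[int, bool] = {}
    for clade in doc.tree.find_clades():
        if clade.is_terminal():
            labels[id(clade)] = False
            continue
        dup = any(
            sets[id(a)] & sets[id(b)]
            for a, b in itertools.combinations(clade.clades, 2)
        )
        labels[id(clade)] = dup
    return labels


def infer_ortholog_groups(doc: TreeDoc, full_length_ids: set[str] | None = None
                          ) -> list[OrthologGroup]:
    """Maximal duplication-free clades of the (full-length-pruned) gene tree.

    ``full_length_ids`` are gene ids (the part after ``|``); when given, the
    tree is pruned to those leaves first so fragments never contribute.
    """
    pruned = _restrict(doc, full_length_ids)
    if pruned is None:
        return []
    labels = duplication_nodes(pruned)

    groups: list[OrthologGroup] = []

    def has_dup(clade) -> bool:
        if labels[id(clade)]:
            return True
        return any(has_dup(ch) for ch in clade.clades)

    def emit(clade) -> None:
        leaves = [l.name for l in clade.get_terminals()]
        species: dict[str, int] = {}
        for label in leaves:
            sp = _leaf_species(label)
            species[sp] = species.get(sp, 0) + 1
        groups.append(OrthologGroup(f"OG{len(groups) + 1:04d}", leaves, species))

    def walk(clade) -> None:
        if not has_dup(clade):
            emit(clade)
        else:
            for ch in clade.clades:
                walk(ch)

    walk(pruned.tree.root)
    return groups


def rescue_groups(doc: TreeDoc, full_ids: set[str], fragment_ids: set[str]
                  ) -> list[OrthologGroup]:
    """Ortholog groups for fragment rescue.

    The tree is pruned to full + fragment leaves, but duplication labels are
    inferred from the full-length leaves only — fragments are placed in the
    tree without ever creating duplications, so a fragment sits in the same
    group as a full-length protein of its species (the situation where it is
    discarded as a partial transcript of that gene).
    """
    keep = {
        label for label in doc.leaf_labels
        if label.split("|", 1)[1] in (full_ids | fragment_ids)
    }
    if not keep:
        return []
    pruned = prune_to(doc, keep)
    labels = duplication_nodes(pruned, count_gene_ids=full_ids)

    groups: list[OrthologGroup] = []

    def has_dup(clade) -> bool:
        if labels[id(clade)]:
            return True
        return any(has_dup(ch) for ch in clade.clades)

    def walk(clade) -> None:
        if not has_dup(clade):
            leaves = [l.name for l in clade.get_terminals()]
            species: dict[str, int] = {}
            for label in leaves:
                sp = _leaf_species(label)
                species[sp] = species.get(sp, 0) + 1
            groups.append(OrthologGroup(f"OG{len(groups) + 1:04d}", leaves, species))
        else:
            for ch in clade.clades:
                walk(ch)

    walk(pruned.tree.root)
    return groups


def ortholog_relations(doc: TreeDoc, full_length_ids: set[str] | None = None
                       ) -> list[tuple[str, str]]:
    """Cross-group ortholog pairs: leaves whose LCA is not a duplication node.

    Captures many-to-one orthology that the group partition cannot express
    (e.g. one gene orthologous to each member of a duplicated pair).
    """
    pruned = _restrict(doc, full_length_ids)
    if pruned is None:
        return []
    labels = duplication_nodes(pruned)
    tree = pruned.tree
    leaves = tree.get_terminals()
    pairs: list[tuple[str, str]] = []
    for a, b in itertools.combinations(leaves, 2):
        lca = tree.common_ancestor([a, b])
        if not labels[id(lca)]:
            pairs.append(tuple(sorted((a.name, b.name))))
    return sorted(pairs)


def _restrict(doc: TreeDoc, full_length_ids: set[str] | None) -> TreeDoc | None:
    if full_length_ids is None:
        return doc
    keep = {
        label for label in doc.leaf_labels
        if label.split("|", 1)[1] in full_length_ids
    }
    if not keep:
        return None
    return prune_to(doc, keep)


def _species_clades(species_tree: TreeDoc) -> list[frozenset[str]]:
    out = []
    for clade in species_tree.tree.find_clades():
        out.append(frozenset(l.name for l in clade.get_terminals()))
    return out


def call_expansions(gene_tree: TreeDoc, species_tree: TreeDoc,
                    full_length_ids: set[str] | None = None,
                    deep_overlap_fraction: float = 0.5) -> list[ExpansionCall]:
    """Partition the gene tree into ortholog-group complexes and call the
    expansion scope of each.

    A duplication node whose children's species overlap covers strictly
    more than ``deep_overlap_fraction`` of the species observed in the gene
    tree is treated as deep — an ancient, family-level duplication
    separating ortholog-group complexes (e.g. the join between two
    subfamilies each represented in most species).  The walk descends
    through deep duplications and emits each remaining subtree as one
    complex; shallow duplications inside a complex are the lineage- or
    species-restricted expansions being called.
    """
    pruned = _restrict(gene_tree, full_length_ids)
    if pruned is None:
        return []
    species_roster = frozenset(l.name for l in species_tree.tree.get_terminals())
    observed = frozenset(pruned.species)
    unknown = observed - species_roster
    if unknown:
        raise ValueError(f"gene-tree species absent from species tree: {sorted(unknown)}")

    labels = duplication_nodes(pruned)
    sets = _species_sets(pruned.tree.root)
    clades_of_species_tree = _species_clades(species_tree)

    def overlap(clade) -> frozenset[str]:
        ov: set[str] = set()
        for a, b in itertools.combinations(clade.clades, 2):
            ov |= sets[id(a)] & sets[id(b)]
        return frozenset(ov)

    def is_deep(clade) -> bool:
        return (
            not clade.is_terminal()
            and labels[id(clade)]
            and len(overlap(clade)) > deep_overlap_fraction * len(observed)
        )

    def contains_deep(clade) -> bool:
        if is_deep(clade):
            return True
        return any(contains_deep(ch) for ch in clade.clades)

    calls: list[ExpansionCall] = []

    def emit(clade) -> None:
        copy_numbers: dict[str, int] = {}
        for leaf in clade.get_terminals():
            sp = _leaf_species(leaf.name)
            copy_numbers[sp] = copy_numbers.get(sp, 0) + 1
        multi = frozenset(sp for sp, n in copy_numbers.items() if n > 1)
        if len(multi) == 0:
            scope = "none"
        elif len(multi) == 1:
            scope = "species_specific"
        elif multi in clades_of_species_tree:
            scope = "lineage_specific"
        else:
            scope = "none"
        calls.append(
            ExpansionCall(
                og_id=f"OGC{len(calls) + 1:04d}",
                scope=scope,
                species=tuple(sorted(multi)),
                copy_numbers=copy_numbers,
            )
        )

    def walk(clade) -> None:
        if contains_deep(clade):
            for ch in clade.clades:
                walk(ch)
        else:
            emit(clade)

    walk(pruned.tree.root)
    return calls


def gini(counts) -> float:
    """Gini coefficient of a non-negative count vector (0 = perfect equality)."""
    x = np.sort(np.asarray(counts, dtype=float))
    if x.size == 0 or x.sum() == 0:
        raise ValueError("gini requires at least one positive count")
    n = x.size
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def family_size_distribution(per_subfamily_counts: dict[str, int],
                             clans: dict[str, list[str]] | None = None,
                             top_k: tuple[int, ...] = (1, 3, 8)) -> dict:
    """Summarize a family-size distribution: top-k gene shares, Gini, and
    optional clan fractions (clan -> member subfamilies)."""
    counts = {k: int(v) for k, v in per_subfamily_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative subfamily counts")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all-zero subfamily counts")
    ordered = sorted(counts.values(), reverse=True)
    out = {
        "total": total,
        "gini": gini(list(counts.values())),
        "top_k_share": {
            k: sum(ordered[:k]) / total for k in top_k
        },
    }
    if clans is not None:
        out["clan_fractions"] = {
            clan: sum(counts.get(sf, 0) for sf in members) / total
            for clan, members in clans.items()
        }
    return out
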