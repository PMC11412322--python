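"""One-command orchestration of all stages on a config.

Stages run in dependency order: collapse -> curate -> expansions -> clusters
-> profiles -> expr -> sites.  Every stage writes a TSV under the output
directory and the run ends with one summary aggregating the per-family
repertoire bookkeeping and the grand detoxification-gene total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .clusters import detect_clusters
from .expansion import call_expansions
from .expression import summarize_expression
from .profiles import ProfileLadder, classify_orthogroups
from .redundancy import collapse_redundant, reduction_stats
from .repertoire import DEFAULT_RULES, FamilyRule, curate_family, repertoire_summary
from .sites import DEFAULT_VGSC_SITES, call_sites

__all__ = ["RunConfig", "run_all", "aggregate_detox_total"]


@dataclass
class RunConfig:
    """Paths and parameters for a full run.

    ``families`` maps family name -> {"hits": path, "tree": path,
    "source": blast_tab|hmmer_dom}; rules default to the per-family
    curation defaults and can be overridden per family.
    """

    proteins: str
    species_tree: str
    families: dict[str, dict]
    gff: str | None = None
    orthogroups: str | None = None
    tpm: str | None = None
    msa: dict[str, str] | None = None  # optional in-memory alignment
    identity_threshold: float = 0.99
    window_bp: int = 50_000
    named_clades: dict[str, list[str]] = field(default_factory=dict)
    out_dir: str = "detoxrep_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.proteins, self.species_tree]
        for fam, cfg in self.families.items():
            paths += [cfg["hits"], cfg["tree"]]
        for p in (self.gff, self.orthogroups, self.tpm):
            if p is not None:
                paths.append(p)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")


def _family_rule(family: str, overrides: dict | None) -> FamilyRule:
    rule = DEFAULT_RULES[family]
    if overrides:
        from dataclasses import replace

        rule = replace(rule, **overrides)
    return rule


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": {
        "identity_threshold": config.identity_threshold,
        "window_bp": config.window_bp,
        "seed": config.seed,
    }}

    try:
        proteins = dio.read_fasta(config.proteins)
        species_tree = dio.read_tree(config.species_tree, require_labels=False)

        # 1. collapse
        clusters99 = collapse_redundant(proteins, config.identity_threshold)
        reps = {c.representative for c in clusters99}
        pd.DataFrame(
            [
                {"representative": c.representative, "member": m}
                for c in clusters99 for m in c.members
            ]
        ).to_csv(out / "collapse.tsv", sep="\t", index=False)
        log["collapse"] = {
            "n_before": len(proteins),
            "n_after": len(clusters99),
            "pct_reduction": reduction_stats(len(proteins), len(clusters99)),
        }
        kept_proteins = [p for p in proteins if p.protein_id in reps]

        # 2. curate per family, 3. expansions
        summaries: dict[str, dict] = {}
        all_entries = []
        expansion_rows = []
        for family, cfg in sorted(config.families.items()):
            rule = _family_rule(family, cfg.get("rule_overrides"))
            hits = dio.read_hits(cfg["hits"], cfg.get("source", "blast_tab"))
            tree = dio.read_tree(cfg["tree"])
            hits = [h for h in hits if h.query_id in reps]
            entries = curate_family(kept_proteins, hits, tree, rule)
            summaries[family] = repertoire_summary(entries)
            for e in entries:
                if e.status != "discarded_no_hit":
                    all_entries.append(e)
            full_ids = {e.protein_id for e in entries if e.status == "kept_full"}
            for call in call_expansions(tree, species_tree, full_ids):
                expansion_rows.append(
                    {
                        "family": family, "og_id": call.og_id,
                        "scope": call.scope,
                        "species": ",".join(call.species),
                        "copy_numbers": json.dumps(call.copy_numbers, sort_keys=True),
                    }
                )
        pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id, "species": e.species,
                    "family": e.family, "length_class": e.length_class,
                    "coverage_aa": e.coverage_aa, "status": e.status,
                    "ortholog_group_id": e.ortholog_group_id or "",
                }
                for e in all_entries
            ]
        ).to_csv(out / "repertoire.tsv", sep="\t", index=False)
        pd.DataFrame(expansion_rows).to_csv(out / "expansions.tsv", sep="\t", index=False)

        # 4. clusters
        if config.gff:
            loci = dio.read_gff(config.gff)
            fam_ids = {e.protein_id for e in all_entries}
            fam_loci = [l for l in loci if l.gene_id in fam_ids]
            gene_clusters, singletons = detect_clusters(fam_loci, config.window_bp)
            pd.DataFrame(
                [
                    {"cluster_id": c.cluster_id, "contig": c.contig,
                     "gene_id": g, "n_members": c.n_members, "span_bp": c.span_bp}
                    for c in gene_clusters for g in c.members
                ]
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            log["clusters"] = {
                "n_clusters": len(gene_clusters), "n_singletons": len(singletons),
            }

        # 5. profiles
        if config.orthogroups:
            table = dio.read_orthogroups(config.orthogroups)
            ladder = ProfileLadder(
                named_clades={
                    k: frozenset(v) for k, v in config.named_clades.items()
                }
            )
            prof = classify_orthogroups(table, species_tree, ladder)
            pd.DataFrame(
                [
                    {"species": sp, "category": cat, "n_genes": n}
                    for sp, cats in prof["counts"].items()
                    for cat, n in cats.items()
                ]
            ).to_csv(out / "profiles.tsv", sep="\t", index=False)

        # 6. expression
        if config.tpm:
            tpm = dio.read_tpm(config.tpm)
            rep_df = pd.DataFrame(
                [
                    {"gene_id": e.protein_id, "species": e.species, "family": e.family}
                    for e in all_entries
                    if e.status in ("kept_full", "rescued_fragment")
                ]
            )
            expr = summarize_expression(tpm, rep_df)
            expr.table.to_csv(out / "expression.tsv", sep="\t", index=False)

        # 7. target sites
        if config.msa:
            calls = call_sites(config.msa, DEFAULT_VGSC_SITES)
            pd.DataFrame(
                [
                    {"row_id": c.row_id, "species": c.species, "site": c.site_label,
                     "observed": c.observed, "call": c.call}
                    for c in calls
                ]
            ).to_csv(out / "site_calls.tsv", sep="\t", index=False)

    except Exception as exc:  # annotate with stage context and re-raise
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    log["families"] = summaries
    log["detox_total"] = aggregate_detox_total(
        [s for s in summaries.values()]
    ) if summaries else 0
    with open(out / "summary.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log


def aggregate_detox_total(per_family_summaries: list[dict | int]) -> int:
    """Grand total of curated detoxification genes across families."""
    if not per_family_summaries:
        raise ValueError("no family summaries to aggregate")
    total = 0
    for s in per_family_summaries:
        total += s if isinstance(s, int) else s["n_total"]
    return total
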