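# detoxrep

Curation and comparative evolution of insect **detoxification gene-family
repertoires** — cytochrome P450s (CYPs), glutathione-S-transferases (GSTs),
UDP-glycosyltransferases (UGTs), carboxyl/cholinesterases (CCEs) and
ATP-binding cassette (ABC) transporters — from transcriptome-derived protein
sets, as used in comparative studies of disease-vector insects such as
phlebotomine sand flies.

Transcriptome-based gene sets are noisy: they carry near-identical isoform
redundancy, truncated partial transcripts, and assembly artifacts. Building a
credible per-species family repertoire therefore needs more than a BLAST
search. This package implements the full curation and analysis chain as a
tested library with a thin CLI:

1. **Redundancy collapse** — greedy incremental clustering at a local
   sequence-identity threshold (default 99%, CD-HIT semantics): sequences
   processed longest-first, each joining the first cluster whose
   representative it matches at ≥ *c* under optimal Smith–Waterman local
   alignment (BLOSUM62, gap open 11 / extend 1), identity = identical
   columns / aligned columns.
2. **Repertoire curation** — candidates gated on evidence (BLAST hits at
   e-value ≤ 10⁻³ against a curated reference, or required Pfam domains:
   GST needs PF02798 **and** PF00043, UGT PF00201, CCE PF00135), then
   partitioned by a family-specific full-length threshold (≥300 aa for
   CYP/UGT/CCE/ABC, ≥150 aa for GST; 100 aa floor). Incomplete proteins are
   **rescued** only when their ortholog group lacks a full-length member for
   that species — the longest fragment wins; fragments alongside a
   full-length ortholog are discarded as partial transcripts.
3. **Expansion inference** — gene trees are midpoint-rooted; internal nodes
   are duplications iff their children's species sets intersect
   (species-overlap). Ortholog groups are maximal duplication-free clades.
   Per ortholog-group complex, copy numbers over full-length proteins yield
   expansion calls: *species-specific* (one species multi-copy) or
   *lineage-specific* (the multi-copy species form a species-tree clade).
4. **Genomic clusters** — tandem arrays detected per contig by chaining
   genes whose start-to-start distance is ≤ 50 kb.
5. **Orthology profiles** — orthogroups classified from
   `universal_all_taxa` through `clade_restricted` and `widespread` down to
   `species_specific`; per-species gene counts partitioned by category.
6. **Expression** — per-gene mean TPM across replicates, log₁₀(mean + 1),
   within-family ranks, and dominant-paralog calls (fold ≥ 100 over a named
   duplicate, e.g. the functional CYP4G ortholog pair).
7. **Target sites** — reference-anchored residue calling at insecticide
   target positions (VGSC kdr sites L995 and N1570 under AGAP004707-RD
   numbering; legacy names L1014F / N1575Y).

A first-class **synthetic-data generator** plants all of this structure
(expansions, fragments, isoforms, clusters, dominance, orthogroup profiles)
with a machine-readable truth table, so every stage is tested end-to-end
against known answers — no downloads required.

## Worked example

Generate a synthetic world (11 ingroup species + outgroup) and curate its
CYP family:

```bash
detoxrep generate --seed 5 --out-dir demo
# wrote 17 files to demo

detoxrep collapse --fasta demo/proteins.faa --identity 0.99 --out collapse.tsv
# 375 proteins -> 360 clusters

detoxrep curate --family CYP --fasta demo/proteins.faa \
    --hits demo/CYP.blast.tsv --tree demo/CYP.nwk --out cyp_repertoire.tsv
# 99 curated genes written to cyp_repertoire.tsv
```

The 375 proteins collapse to 360 clusters (4.0% reduction) because 15
planted isoforms sit above the 99% identity threshold. The 99 curated CYP
genes are the planted repertoire exactly: full-length candidates plus
fragments rescued where a species had no full-length ortholog.

Expansion calling on full-length proteins only:

```bash
awk -F'\t' '$6=="kept_full"{print $1}' cyp_repertoire.tsv > cyp_full_ids.txt
detoxrep expansions --gene-tree demo/CYP.nwk --species-tree demo/species_tree.nwk \
    --full-ids cyp_full_ids.txt --out cyp_expansions.tsv
```

yields 8 ortholog-group complexes, two of them expanded — exactly the two
planted ones:

```
  og_id            scope   species  copy_numbers
OGC0001 species_specific      Ppap  {"Ppap": 6, ... all others 1}
OGC0002 lineage_specific Llon,Lmig  {"Llon": 4, "Lmig": 4, ... all others 1}
```

and `detoxrep clusters --gff demo/genes.gff3 --out cyp_clusters.tsv` reports
the two planted tandem arrays (6 and 4 genes) with 11 scattered singletons.
Passing `--full-ids` matters: with fragments left in the tree, a fragment
sitting next to its species' full-length gene would masquerade as an extra
copy.

The same stages run end-to-end from one YAML config via
`detoxrep run-all --config config.yaml`.

## Bookkeeping helpers

`repertoire_summary` reproduces standard full/incomplete breakdowns — e.g. a
family with 1,158 full-length and 117 incomplete members reports 90.8% /
9.2% — and `aggregate_detox_total` sums curated totals across the five
families.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world under the given seed, runs the complete
pipeline (collapse → curate → expansions → clusters → profiles → expression
→ target sites), prints the curated totals against the planted truth, and
writes the result file.
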