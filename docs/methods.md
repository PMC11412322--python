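# Methods

This note documents the models, rules and numerical choices behind
`detoxrep`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish.

## Redundancy collapse

**Model.** Transcriptome gene sets inflate gene counts through isoforms,
allelic variants and technical duplicates. We collapse them by greedy
incremental clustering, the semantics of CD-HIT in local mode: sequences are
sorted by decreasing length (ties broken lexicographically by id for
determinism); each sequence joins the first existing cluster whose
*representative* it matches at ≥ the identity threshold, otherwise it founds
a new cluster. Representatives are therefore always a longest member, and
representatives are pairwise below the threshold.

**Identity.** Identity is computed on the optimal local (Smith–Waterman)
alignment: identical columns divided by aligned columns (internal gap
columns included). Defaults: BLOSUM62, gap open 11, gap extend 1 —
ordinary protein-search parameters; both the matrix and the denominator
(`aligned_columns` vs `shorter` sequence length) are configurable. A pair
with no positive-scoring local alignment has identity 0. Note a consequence
of *local* identity: an exact fragment of a longer protein scores 1.0
against it, which is the desired behaviour for collapsing partial isoforms.

**Performance.** Before aligning, a conservative shared-5-mer prescreen
discards pairs that cannot plausibly reach 95% identity (pairs with a
sequence under 40 aa skip the screen). Two proteins at ≥95% identity over a
usable alignment share well over half of the shorter one's 5-mers; the
screen threshold is 0.3, leaving a wide margin. The brute-force all-pairs
oracle test runs without the prescreen and agrees with the screened
clustering. No attempt is made to reproduce CD-HIT's exact word-filter
cluster boundaries.

`reduction_stats` reports 100·(n_before − n_after)/n_before to one decimal,
the statistic usually quoted for isoform-collapse severity.

## Repertoire curation

**Evidence gate.** A protein is a family candidate iff it has at least one
hit at e-value ≤ 10⁻³ (configurable); for domain-based families every
required Pfam domain must be present at a qualifying e-value (GST: PF02798
*and* PF00043; UGT: PF00201; CCE: PF00135). HMMER per-domain rows use
alignment (`ali`) coordinates and the independent per-domain e-value
(i-Evalue).

**Coverage vs length.** BLAST-evidence families (CYP, ABC) gate on *query
coverage*: the merged union of qualifying-hit query intervals, robust to
split HSPs. Domain-evidence families gate on polypeptide length. Both are
overridable per family (`gate_on`).

**Length classes.** Full-length requires ≥300 aa (CYP/UGT/CCE/ABC) or
≥150 aa (GST); candidates of 100 aa up to the threshold are fragments; below
100 aa they are discarded, except ids on a per-family special-rescue list
(the acetylcholinesterase Ace1 case, where a biologically essential ortholog
is recoverable only as a very short transcript). Those bypass the floor and
are flagged `below_floor`.

**Fragment rescue.** Fragments are placed in the family gene tree (trees
are taken as given; the package never re-estimates them). Ortholog groups
for rescue are maximal clades free of duplication nodes, where duplications
are inferred **from full-length leaves only** — a fragment never creates a
duplication, so a fragment landing next to its species' full-length gene
shares that gene's group. Within each (group × species): any full-length
member discards all fragments of that species (partial transcripts /
assembly artifacts); otherwise the single longest fragment is rescued, ties
broken lexicographically by id. This yields two invariants the tests
enforce: at most one rescued fragment per species × group, and never
alongside a full-length member.

**Bookkeeping.** Percentages of full vs incomplete members are computed at
one decimal; a `display_decimals` option renders the two-decimal style some
families are conventionally reported with (e.g. 98.2 → "98.20").

## Expansion inference

**Duplications.** Gene trees are midpoint-rooted (error if branch lengths
are missing or all zero). An internal node is a duplication iff any two
children's species sets intersect (species-overlap). This deliberately
avoids full gene-tree/species-tree reconciliation: species-overlap is
deterministic, parameter-free, and adequate for expansion calling; it will
over-call duplications under heavy incomplete lineage sorting or gene-tree
error, which is a known limitation.

**Ortholog groups** are maximal duplication-free clades; they partition the
full-length leaves. Cross-group many-to-one orthology (a single gene
orthologous to both members of a duplicated pair) is emitted as a separate
relation table — pairs whose LCA is not a duplication — rather than forcing
single-group membership.

**Complexes and scope.** Only full-length proteins are counted (fragments
are pruned first, so adding fragment leaves never changes a call). A
duplication whose children's species overlap spans **strictly more than
half** of the species observed in the gene tree is classified *deep* — an
ancient duplication separating ortholog-group complexes, such as the join
between two subfamilies each represented in essentially every species. The
tree is walked from the root, descending through deep duplications; every
remaining subtree is one complex. Per complex, per-species copy numbers
give the call: `species_specific` if exactly one species is multi-copy,
`lineage_specific` if the multi-copy species form a monophyletic clade
(≥2 species) of the species tree, otherwise `none`. The ½ cutoff
(configurable, `deep_overlap_fraction`) separates the two regimes by a wide
margin in the intended setting — ancient joins overlap on ~9–11 of 11
species even when fragments remove some species from a subfamily, while
reported lineage expansions span 2–3 species. With very small rosters
(≤4 species) a genuine lineage expansion can cross the cutoff; pass an
explicit fraction there.

**Family-size statistics.** `family_size_distribution` quantifies the "many
small subfamilies, few large ones" shape via top-*k* gene shares and the
Gini coefficient, plus clan fractions (clan total / family total) when a
clan → subfamily map is supplied.

## Genomic clusters

Per contig, genes sorted by start are chained while the start-to-start
distance is ≤ the window (50 kb default, matching the sliding-window scale
used for CYP clusters); chains of ≥ `min_size` (default 2) are clusters.
Start-to-start is the declumped equivalent of counting genes per window; an
end-to-start (`gap`) mode is available. Strand is ignored for membership
(tandem arrays mix orientations) but reported. Enlarging the window can only
merge clusters, never shrink them.

`compare_clusters` matches each cluster to its best counterpart in another
assembly by shared-ortholog count and reports composition diffs and the
copy-number delta — counts only, no collinearity scoring.

`permutation_null` is a sanity check, not an inference procedure: it
re-draws gene starts uniformly per contig and reports how often shuffles
look at least as clustered as the data. The statistic is the number of genes
inside clusters (a raw cluster count is non-monotone: one planted array can
fragment into several chance pairs under shuffling). The null is only
meaningful with realistic contig lengths — by default the occupied extent is
used; pass `contig_length` where real sizes are known.

## Orthology profiles

An orthogroup's category comes from its species-presence set (presence =
≥1 gene; copy number never affects the category): `universal_all_taxa` →
`clade_restricted:<name>` (presence equals a named, monophyletic
species-tree clade) → `widespread` (≥ a configurable fraction of the
roster, default 0.5) → `multi_species` → `species_specific`; genes in no
orthogroup are `unassigned`. Named clades are evaluated **before** the
widespread threshold: a set spanning exactly a named clade is reported as
restricted to it even when it also clears the fraction (an 11-of-19 clade
would otherwise be swallowed by `widespread`). Per species, category counts
plus unassigned sum exactly to the species' total gene count.

## Expression summaries

Replicates are averaged as the arithmetic mean of TPM (not mean of logs),
then transformed as log₁₀(mean + pseudocount); pseudocount 1 by default,
affecting only the log scale, never ranks. Ranks are dense within
family × species, ties broken by gene id and flagged. Dominant-paralog
calls: fold = mean(a)/max(mean(b), ε) with ε = 10⁻⁶ TPM to keep ">100×"
semantics meaningful when the competitor is unexpressed (the floored case is
flagged); dominance additionally requires rank 1 in the family × species.
All ranks and folds are invariant to global TPM rescaling.

## Target-site calls

A site is defined by an ungapped residue index on a reference alignment row
(kdr defaults: L995 wildtype L, resistant F/S; N1570 wildtype N, resistant
Y; numbering per the Anopheles gambiae VGSC transcript AGAP004707-RD, with
the Musca-legacy names L1014F/N1575Y carried as aliases only). The index is
mapped to its alignment column through the reference row's gaps; every row
is then called sensitive (wildtype), resistant (listed allele) or unknown.
Gaps and *novel* residues are unknown — never resistant — to avoid
over-calling uncharacterized variants. Column mapping is invariant to
inserting all-gap columns.

## Synthetic worlds

The generator emits a complete input bundle (FASTA, BLAST/HMMER hit tables,
gene trees, GFF3, orthogroup TSV, TPM matrix) plus a truth table, all
driven by one integer seed (same seed ⇒ byte-identical files).

* **Species roster**: 11 ingroup species in three genus-like groups plus one
  outgroup, on a fixed species tree with branch lengths.
* **Sequences** evolve from a random ancestor along each family's gene
  genealogy by per-site substitution (probability = branch length ×
  `mutation_scale`, default 0.6). No indels except planted truncations, so
  pairwise identities are analytically controllable.
* **Family sizes** follow the many-small/few-large pattern: one copy per
  species per subfamily, except planted expansions (4–12 copies realized as
  duplication caterpillars at the species leaf or lineage subtree).
* **Fragments** are contiguous truncations drawn uniformly in
  [100 aa, full-length threshold) — kept below the threshold so planted
  labels match the curation rule — in three scenarios: sole representative
  (expect rescue), alongside a full-length member (expect discard), and
  competing pairs (longest wins). Per-family fragment rates default to the
  full/incomplete proportions typical of such repertoires (CYP 9%, GST 2%,
  UGT 17%, CCE 18%, ABC 7%).
* **Redundancy**: isoforms at ≥99.3% identity (exactly placed substitutions
  away from the termini, minus a 2-aa truncation) collapse at 0.99;
  near-duplicates at ~97% collapse only at 0.95. Recent paralogs are
  separated by branch lengths of 0.08 (~9% expected divergence) so they sit
  firmly between the two thresholds.
* **Clusters**: planted subfamily arrays with intra-cluster gaps of
  2–30 kb and singletons spaced 300 kb apart.
* **Expression**: log-normal baseline (log₁₀ TPM ~ N(1, 0.6), capped at
  2,000 TPM), three replicates per species with small multiplicative noise;
  the planted dominant gene is set to 5,000 TPM and its competitor to
  5,000/fold (fold 150 by default), guaranteeing rank 1 and fold ≥ 100.
* **Decoys**: random-composition proteins with no qualifying hits (a few
  carry deliberately non-qualifying hits at e-value 0.01 to exercise the
  gate).

**What a green test establishes — and what it does not.** The synthetic
world validates the *rules*: gating, rescue logic, overlap labelling,
chaining, ladder evaluation, rank arithmetic, and their interactions, under
a genealogy whose truth is known. It does not emulate real transcriptome
pathologies — chimeric transcripts, alignment error in the gene trees,
incomplete lineage sorting, expression-dependent assembly dropout, codon
bias — so exact recovery here does not promise exact recovery on real data,
where tree error in particular feeds directly into rescue and expansion
calls.

## Degenerate inputs and tie-breaks

Empty families report zero counts with no division; zero-length trees are a
midpoint-rooting error; equal-length competing fragments resolve
lexicographically; equal-TPM genes rank by id and are flagged; cluster ids
are deterministic (`contig:first_start`); greedy collapse order is total
(length, then id). All randomness flows from explicit seeds.
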