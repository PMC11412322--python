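"""Readers and writers for every external format the pipeline touches.

All coordinates are 1-based inclusive after parsing, matching GFF3 and the
BLAST/HMMER tabular dialects.  Every reader validates its type invariants and
every format has a lossless writer, so ``write(read(path))`` round-trips.

Formats covered: protein FASTA (``>species|gene_id`` headers by default),
12-column BLAST tabular (``-outfmt 6``), HMMER per-domain tables
(``--domtblout``), GFF3 gene features, newick trees with ``species|gene``
leaf labels, OrthoFinder-style orthogroup TSVs, and TPM expression TSVs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Phylo

__all__ = [
    "ProteinRecord",
    "HitRecord",
    "GeneLocus",
    "TreeDoc",
    "OrthogroupTable",
    "ExpressionMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_hits",
    "write_hits",
    "read_gff",
    "write_gff",
    "read_tree",
    "write_tree",
    "read_orthogroups",
    "write_orthogroups",
    "read_tpm",
    "write_tpm",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_HEADER_PATTERN = re.compile(r"^(?P<species>[^|\s]+)\|(?P<protein_id>\S+)")


class FormatError(ValueError):
    """A file violated the format contract or a type invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A species-tagged polypeptide."""

    protein_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.species:
            raise FormatError(f"protein {self.protein_id!r}: empty species token")
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One similarity or domain hit with e-value and aligned span.

    For BLAST tabular rows the query is the searched protein.  For HMMER
    per-domain rows the searched protein is the *target*; it is mapped onto
    ``query_id`` here so downstream gating addresses proteins uniformly, with
    the domain (HMM) accession as ``subject_id`` and alignment (``ali``)
    coordinates as the query span.
    """

    query_id: str
    subject_id: str
    evalue: float
    aln_len_aa: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    bitscore: float
    source: str  # {"blast_tab", "hmmer_dom"}

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if self.aln_len_aa < 1:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: aln_len_aa < 1")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: reversed coordinates"
            )
        if self.source not in ("blast_tab", "hmmer_dom"):
            raise FormatError(f"unknown hit source {self.source!r}")


@dataclass(frozen=True)
class GeneLocus:
    """Genomic coordinates of one gene (1-based inclusive)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "?"):
            raise FormatError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class TreeDoc:
    """A parsed newick tree whose leaves are labelled ``species|gene_id``."""

    tree: object  # Bio.Phylo tree

    def __post_init__(self) -> None:
        for leaf in self.tree.get_terminals():
            if leaf.name is None or "|" not in leaf.name:
                raise FormatError(
                    f"leaf label {leaf.name!r} does not split on '|' into species|gene"
                )

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.name for leaf in self.tree.get_terminals()]

    @property
    def species(self) -> set[str]:
        return {label.split("|", 1)[0] for label in self.leaf_labels}

    @property
    def gene_ids(self) -> list[str]:
        return [label.split("|", 1)[1] for label in self.leaf_labels]


@dataclass
class OrthogroupTable:
    """og_id -> per-species gene-id lists over a declared species roster."""

    species: list[str]
    groups: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og_id, per_species in self.groups.items():
            for sp, genes in per_species.items():
                if sp not in self.species:
                    raise FormatError(f"orthogroup {og_id}: unknown species {sp!r}")
                for g in genes:
                    if g in seen:
                        raise FormatError(
                            f"gene {g!r} appears in orthogroups {seen[g]} and {og_id}"
                        )
                    seen[g] = og_id

    def presence(self, og_id: str) -> set[str]:
        """Species with at least one gene in the orthogroup."""
        return {sp for sp, genes in self.groups[og_id].items() if genes}

    def gene_to_og(self) -> dict[str, str]:
        return {
            g: og_id
            for og_id, per_species in self.groups.items()
            for genes in per_species.values()
            for g in genes
        }


@dataclass
class ExpressionMatrix:
    """TPM values, genes x replicates, with a replicate -> species map."""

    tpm: pd.DataFrame  # index gene_id, columns replicate ids
    replicate_species: dict[str, str]

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            dups = self.tpm.index[self.tpm.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids in TPM matrix: {dups}")
        if (self.tpm.values < 0).any():
            raise FormatError("negative TPM values present")
        missing = set(self.tpm.columns) - set(self.replicate_species)
        if missing:
            raise FormatError(f"replicates without species mapping: {sorted(missing)}")

    def replicates_of(self, species: str) -> list[str]:
        return [r for r in self.tpm.columns if self.replicate_species[r] == species]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, header_pattern: re.Pattern | str | None = None
               ) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Headers must match ``header_pattern`` (default ``species|protein_id``,
    free text after the id ignored).  Sequences are upper-cased; a trailing
    stop ``*`` is stripped with a warning, an internal ``*`` is an error.
    """
    pattern = (
        DEFAULT_HEADER_PATTERN
        if header_pattern is None
        else re.compile(header_pattern)
    )
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: tuple[str, str] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        species, pid = header
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            warnings.warn(f"protein {pid!r}: trailing stop codon '*' stripped")
            seq = seq[:-1]
        if "*" in seq:
            raise FormatError(f"protein {pid!r}: internal stop codon '*'")
        if not seq:
            raise FormatError(f"protein {pid!r}: empty sequence")
        records.append(ProteinRecord(pid, species, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                m = pattern.match(line[1:])
                if not m:
                    raise FormatError(f"{path}:{lineno}: unparsable FASTA header {line!r}")
                header = (m.group("species"), m.group("protein_id"))
                if header[1] in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate protein_id {header[1]!r}")
                seen.add(header[1])
                chunks = []
                header_line = lineno
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line.strip())
        flush()
    if header is None and not records:
        return []
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species}|{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hit tables

_BLAST_COLS = 12


def _parse_blast_row(fields: Sequence[str], ctx: str) -> HitRecord:
    if len(fields) != _BLAST_COLS:
        raise FormatError(f"{ctx}: expected {_BLAST_COLS} columns, got {len(fields)}")
    return HitRecord(
        query_id=fields[0],
        subject_id=fields[1],
        evalue=float(fields[10]),
        aln_len_aa=int(fields[3]),
        q_start=int(fields[6]),
        q_end=int(fields[7]),
        s_start=int(fields[8]),
        s_end=int(fields[9]),
        bitscore=float(fields[11]),
        source="blast_tab",
    )


def _parse_domtbl_row(fields: Sequence[str], ctx: str) -> HitRecord:
    # target name, t-acc, tlen, query name, q-acc, qlen, full E-value, full
    # score, full bias, #, of, c-Evalue, i-Evalue, dom score, dom bias,
    # hmm from, hmm to, ali from, ali to, env from, env to, acc, description
    if len(fields) < 22:
        raise FormatError(f"{ctx}: expected >=22 columns, got {len(fields)}")
    target, t_acc = fields[0], fields[1]
    query, q_acc = fields[3], fields[4]
    domain = q_acc if q_acc != "-" else query
    domain = domain.split(".", 1)[0]  # strip Pfam accession version
    ali_from, ali_to = int(fields[17]), int(fields[18])
    return HitRecord(
        query_id=target,
        subject_id=domain,
        evalue=float(fields[12]),  # i-Evalue, per-domain
        aln_len_aa=ali_to - ali_from + 1,
        q_start=ali_from,
        q_end=ali_to,
        s_start=int(fields[15]),
        s_end=int(fields[16]),
        bitscore=float(fields[13]),
        source="hmmer_dom",
    )


def read_hits(path: str | Path, source: str) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular or HMMER per-domain hit table."""
    if source not in ("blast_tab", "hmmer_dom"):
        raise ValueError(f"unknown hit source {source!r}")
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if source == "blast_tab" else line.split()
            ctx = f"{path}:{lineno}"
            try:
                if source == "blast_tab":
                    hits.append(_parse_blast_row(fields, ctx))
                else:
                    hits.append(_parse_domtbl_row(fields, ctx))
            except (ValueError, IndexError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{ctx}: malformed row ({exc})") from exc
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits back out in their native tabular dialect (one per source)."""
    hits = list(hits)
    sources = {h.source for h in hits}
    if len(sources) > 1:
        raise ValueError("cannot mix hit sources in one table")
    source = sources.pop() if sources else "blast_tab"
    with open(path, "w") as fh:
        for h in hits:
            if source == "blast_tab":
                span = h.q_end - h.q_start + 1
                fh.write(
                    "\t".join(
                        [
                            h.query_id, h.subject_id, "0.0", str(h.aln_len_aa),
                            "0", "0", str(h.q_start), str(h.q_end),
                            str(h.s_start), str(h.s_end),
                            f"{h.evalue:g}", f"{h.bitscore:g}",
                        ]
                    )
                    + "\n"
                )
            else:
                tlen = h.q_end  # lower bound; real tlen unknown after parsing
                fh.write(
                    " ".join(
                        [
                            h.query_id, "-", str(tlen), h.subject_id, h.subject_id,
                            str(h.s_end), f"{h.evalue:g}", f"{h.bitscore:g}", "0.0",
                            "1", "1", f"{h.evalue:g}", f"{h.evalue:g}",
                            f"{h.bitscore:g}", "0.0",
                            str(h.s_start), str(h.s_end),
                            str(h.q_start), str(h.q_end),
                            str(h.q_start), str(h.q_end), "0.99", "-",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# GFF3 gene features


def _gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in raw.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff(path: str | Path) -> list[GeneLocus]:
    """Read ``gene`` features from a GFF3 file as :class:`GeneLocus` records.

    Only rows with type ``gene`` are returned; each must carry an ``ID``
    attribute.  Coordinates stay 1-based inclusive as written.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            attrs = _gff_attributes(fields[8])
            if "ID" not in attrs:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            start, end = int(fields[3]), int(fields[4])
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            strand = fields[6] if fields[6] in ("+", "-") else "?"
            loci.append(GeneLocus(gene_id, fields[0], start, end, strand))
    return loci


def write_gff(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            strand = loc.strand if loc.strand != "?" else "."
            fh.write(
                "\t".join(
                    [
                        loc.contig, "detoxrep", "gene", str(loc.start), str(loc.end),
                        ".", strand, ".", f"ID={loc.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Trees


def read_tree(path: str | Path, require_labels: bool = True) -> TreeDoc:
    """Read a single newick tree; leaf labels must be ``species|gene_id``.

    With ``require_labels=False`` plain leaf names are accepted (species
    trees use bare species tokens).
    """
    handle = path if hasattr(path, "read") else str(path)
    tree = Phylo.read(handle, "newick")
    if require_labels:
        return TreeDoc(tree)
    doc = TreeDoc.__new__(TreeDoc)
    doc.tree = tree
    return doc


def write_tree(doc: TreeDoc, path: str | Path) -> None:
    Phylo.write(doc.tree, str(path), "newick")


# ---------------------------------------------------------------------------
# Orthogroup tables (OrthoFinder-style TSV)


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read an OrthoFinder-style TSV: first column og id, one column per
    species, cells comma-separated gene lists."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("orthogroup table needs an og column plus species columns")
    species = list(df.columns[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og_id = row.iloc[0]
        if og_id in groups:
            raise FormatError(f"duplicate orthogroup id {og_id!r}")
        groups[og_id] = {
            sp: [g.strip() for g in row[sp].split(",") if g.strip()]
            for sp in species
        }
    return OrthogroupTable(species=species, groups=groups)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    rows = []
    for og_id, per_species in table.groups.items():
        rows.append(
            {"Orthogroup": og_id,
             **{sp: ", ".join(per_species.get(sp, [])) for sp in table.species}}
        )
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# TPM matrices


def read_tpm(path: str | Path) -> ExpressionMatrix:
    """Read a gene x replicate TPM TSV.

    Replicate column headers follow ``species|replicate`` so the matrix
    carries its own replicate -> species map.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        bad = df.columns[(df < 0).any()].tolist()
        raise FormatError(f"negative TPM values in columns {bad}")
    rep_species = {}
    for col in df.columns:
        if "|" not in col:
            raise FormatError(f"TPM column {col!r} not of the form species|replicate")
        rep_species[col] = col.split("|", 1)[0]
    return ExpressionMatrix(tpm=df.astype(float), replicate_species=rep_species)


def write_tpm(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.tpm.to_csv(path, sep="\t", index_label="gene_id")
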