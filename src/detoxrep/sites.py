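"""Reference-anchored residue calling at insecticide target sites.

Residues at known resistance positions are read off a protein multiple
sequence alignment by mapping an ungapped residue index on a reference row
(e.g. position 995 of the Anopheles gambiae voltage-gated sodium channel
transcript AGAP004707-RD) to its alignment column, then calling each row
sensitive (wildtype), resistant (a listed resistance allele), or unknown
(gap or any other residue — novel variants are never over-called resistant).

The bundled default site table covers the two canonical kdr positions of
the VGSC, L995 (resistant F/S; legacy house-fly numbering L1014F) and N1570
(resistant Y; legacy N1575Y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

__all__ = [
    "SiteDefinition",
    "SiteCall",
    "DEFAULT_VGSC_SITES",
    "read_msa",
    "map_reference_position",
    "call_sites",
]


@dataclass(frozen=True)
class SiteDefinition:
    site_label: str
    reference_id: str
    reference_position: int  # 1-based ungapped index on the reference row
    wildtype: str
    resistant: tuple[str, ...]
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.reference_position < 1:
            raise ValueError("reference_position must be >= 1")
        if self.wildtype in self.resistant:
            raise ValueError(f"site {self.site_label}: wildtype listed as resistant")


@dataclass(frozen=True)
class SiteCall:
    row_id: str
    species: str
    site_label: str
    observed: str  # residue or "-"
    call: str  # {sensitive, resistant, unknown}


def default_vgsc_sites(reference_id: str = "Agam|AGAP004707-RD"
                       ) -> tuple[SiteDefinition, ...]:
    return (
        SiteDefinition("L995", reference_id, 995, "L", ("F", "S"),
                       aliases=("L1014F",)),
        SiteDefinition("N1570", reference_id, 1570, "N", ("Y",),
                       aliases=("N1575Y",)),
    )


DEFAULT_VGSC_SITES = default_vgsc_sites()


def read_msa(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered {row_id: aligned sequence} map."""
    aln = AlignIO.read(str(path), "fasta")
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(rows) != len(aln):
        raise ValueError("duplicate row ids in alignment")
    return rows


def map_reference_position(msa: dict[str, str], site: SiteDefinition) -> int:
    """Alignment column (1-based) of the reference row's n-th non-gap residue."""
    if site.reference_id not in msa:
        raise KeyError(f"reference row {site.reference_id!r} absent from alignment")
    ref = msa[site.reference_id]
    seen = 0
    for col, ch in enumerate(ref, start=1):
        if ch != "-":
            seen += 1
            if seen == site.reference_position:
                return col
    raise ValueError(
        f"reference has only {seen} residues; cannot map position "
        f"{site.reference_position} for site {site.site_label}"
    )


def call_sites(msa: dict[str, str], sites: list[SiteDefinition] | tuple = DEFAULT_VGSC_SITES
               ) -> list[SiteCall]:
    """One call per (alignment row, site); the reference row is included."""
    lengths = {len(s) for s in msa.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    calls: list[SiteCall] = []
    for site in sites:
        col = map_reference_position(msa, site)
        for row_id, seq in msa.items():
            observed = seq[col - 1]
            if observed == "-":
                call = "unknown"
            elif observed == site.wildtype:
                call = "sensitive"
            elif observed in site.resistant:
                call = "resistant"
            else:
                call = "unknown"
            species = row_id.split("|", 1)[0]
            calls.append(SiteCall(row_id, species, site.site_label, observed, call))
    return calls
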