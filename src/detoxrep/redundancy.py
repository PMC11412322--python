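"""Collapse identical and nearly identical proteins, CD-HIT style.

Transcriptome-derived gene sets carry isoform redundancy: several predicted
proteins that are the same locus.  The pipeline removes them by greedy
incremental clustering at a local-sequence-identity threshold (default 99%),
processing sequences longest-first so each cluster is represented by one
longest member — the same semantics as CD-HIT run at ``-c 0.99`` in local
mode, without its word-filter heuristics.

Local identity is identical columns over the columns of the optimal local
(Smith–Waterman) alignment under BLOSUM62 with gap open 11 / extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io import ProteinRecord

__all__ = [
    "RedundancyCluster",
    "local_identity",
    "collapse_redundant",
    "reduction_stats",
]


@dataclass
class RedundancyCluster:
    representative: str
    members: list[str]  # includes representative
    threshold: float


def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0,
                  matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def local_identity(a: ProteinRecord | str, b: ProteinRecord | str,
                   aligner: Align.PairwiseAligner | None = None,
                   denominator: str = "aligned_columns") -> float:
    """Fraction of identical columns in the optimal local alignment of two
    proteins.

    Returns 0.0 when no positive-scoring local alignment exists.  With
    ``denominator="shorter"`` identities are divided by the shorter sequence
    length instead of the aligned column count.
    """
    seq_a = a.sequence if isinstance(a, ProteinRecord) else a
    seq_b = b.sequence if isinstance(b, ProteinRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("local_identity requires non-empty sequences")
    if denominator not in ("aligned_columns", "shorter"):
        raise ValueError(f"unknown denominator {denominator!r}")
    aligner = aligner or _DEFAULT_ALIGNER
    alignments = aligner.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0
    if best.score <= 0:
        return 0.0
    counts = best.counts()
    if denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        denom = best.length  # aligned columns incl. internal gap columns
    if denom == 0:
        return 0.0
    return counts.identities / denom


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


class _Prescreen:
    """Conservative shared-k-mer filter so collapse only aligns plausible
    near-duplicate pairs.

    Two sequences matching at >=95% identity over a usable local alignment
    share the large majority of the shorter one's k-mers; unrelated random
    proteins share almost none.  Pairs with short sequences skip the screen
    entirely, so correctness on small inputs never depends on it.
    """

    def __init__(self, k: int = 5, min_len: int = 40, min_share: float = 0.3):
        self.k = k
        self.min_len = min_len
        self.min_share = min_share
        self._cache: dict[str, frozenset[str]] = {}

    def kmers(self, rec: ProteinRecord) -> frozenset[str]:
        cached = self._cache.get(rec.protein_id)
        if cached is None:
            cached = _kmer_set(rec.sequence, self.k)
            self._cache[rec.protein_id] = cached
        return cached

    def may_match(self, a: ProteinRecord, b: ProteinRecord) -> bool:
        if min(a.length_aa, b.length_aa) < self.min_len:
            return True
        ka, kb = self.kmers(a), self.kmers(b)
        smaller = ka if len(ka) <= len(kb) else kb
        other = kb if smaller is ka else ka
        if not smaller:
            return True
        return len(smaller & other) / len(smaller) >= self.min_share


def collapse_redundant(proteins: list[ProteinRecord], threshold: float = 0.99,
                       aligner: Align.PairwiseAligner | None = None,
                       denominator: str = "aligned_columns",
                       prescreen: bool = True) -> list[RedundancyCluster]:
    """Greedy incremental clustering at a local-identity threshold.

    Sequences are processed in decreasing length (ties broken by id); each
    joins the first existing cluster whose representative it matches at
    >= ``threshold``, else founds a new cluster.  The output partitions the
    input, one longest member per cluster as representative.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    aligner = aligner or _DEFAULT_ALIGNER
    screen = _Prescreen() if prescreen else None
    ordered = sorted(proteins, key=lambda r: (-r.length_aa, r.protein_id))
    clusters: list[RedundancyCluster] = []
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if screen is not None and not screen.may_match(rec, rep):
                continue
            if local_identity(rec, rep, aligner=aligner,
                              denominator=denominator) >= threshold:
                cluster.members.append(rec.protein_id)
                placed = True
                break
        if not placed:
            clusters.append(
                RedundancyCluster(rec.protein_id, [rec.protein_id], threshold)
            )
            reps.append(rec)
    return clusters


def reduction_stats(n_before: int, n_after: int) -> float:
    """Percent reduction in gene count, to one decimal."""
    if n_after > n_before:
        raise ValueError(f"n_after {n_after} > n_before {n_before}")
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    return round(100.0 * (n_before - n_after) / n_before, 1)
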