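"""Fragment-recruitment biogeography profiling.

A sample's reads are sub-sampled (10,000 sequences of 350 bp), aligned against
a database built from the nucleotide sequences of predicted open reading
frames only (intergenic sequence excluded), and the best hit per read is kept
if it passes the stated filters: e-value < 1e-5 and alignment length > 200 bp.
Counting accepted hits above a ladder of identity cutoffs gives the
identity-profile of a sample against a genome collection; counts are
normalized to *recruited reads per kb of genome per 10,000 queried reads* and
averaged over the member MAGs of each genome cluster.

E-values follow ungapped Karlin-Altschul statistics for the +1/-2 scoring of
the shared aligner (lambda ~= 1.33, K ~= 0.621) against the total database
length — BLAST-comparable without invoking BLAST.  In practice the length
filter dominates at these read lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Read, revcomp
from .dereplicate import align_local

__all__ = [
    "OrfDatabase",
    "RecruitmentHit",
    "RecruitmentProfile",
    "subsample_reads",
    "build_orf_db",
    "recruit_reads",
    "profile_by_identity",
    "normalize_recruitment",
    "cluster_recruitment",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (70, 75, 80, 85, 90, 95, 96, 97, 98, 99, 100)

KA_LAMBDA = 1.33
KA_K = 0.621

_SEP = "N" * 400  # longer than any subsampled read: alignments cannot span ORFs


@dataclass(frozen=True)
class RecruitmentHit:
    read_id: str
    gene_id: str
    bin_id: str
    identity: float  # fraction
    length: int
    evalue: float
    score: float


@dataclass(frozen=True)
class RecruitmentProfile:
    """Per-cutoff normalized recruitment for one cluster in one sample."""

    cluster_id: str
    sample_id: str
    cutoffs: tuple[float, ...]
    normalized_counts: tuple[float, ...]
    salinity: float | None = None


class OrfDatabase:
    """Strand-resolved nucleotide ORF records with provenance to their bins."""

    def __init__(self, records: Sequence[tuple[str, str, str]]):
        if not records:
            raise ValueError("empty ORF database")
        self.records = list(records)  # (gene_id, bin_id, sequence)
        self.total_length = sum(len(s) for _, _, s in self.records)
        seqs = [s for _, _, s in self.records]
        self.concatenated = _SEP.join(seqs)
        starts = []
        pos = 0
        for s in seqs:
            starts.append(pos)
            pos += len(s) + len(_SEP)
        self._starts = np.array(starts, dtype=np.int64)

    def locate(self, t_pos: int) -> tuple[str, str]:
        """Map a position in the concatenated database to (gene_id, bin_id)."""
        idx = int(np.searchsorted(self._starts, t_pos, side="right") - 1)
        gene_id, bin_id, _ = self.records[idx]
        return gene_id, bin_id

    def bin_sizes(self, bin_lengths: Mapping[str, int] | None = None) -> dict[str, int]:
        """Total ORF bases per bin (or user-provided genome sizes)."""
        if bin_lengths is not None:
            return dict(bin_lengths)
        sizes: dict[str, int] = {}
        for _, bin_id, seq in self.records:
            sizes[bin_id] = sizes.get(bin_id, 0) + len(seq)
        return sizes


def subsample_reads(
    reads: Sequence, n: int = 10_000, length: int = 350, seed: int = 0
) -> list[Read]:
    """Uniform sample without replacement, trimmed to ``length``.

    If fewer than ``n`` reads are supplied, all are returned (with a warning);
    reads shorter than ``length`` are kept whole.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not reads:
        raise ValueError("no reads to subsample")
    rng = np.random.default_rng(seed)
    if len(reads) <= n:
        if len(reads) < n:
            warnings.warn(f"only {len(reads)} reads available for a subsample of {n}; returning all")
        chosen = list(range(len(reads)))
    else:
        chosen = sorted(rng.choice(len(reads), size=n, replace=False).tolist())
    out = []
    for i in chosen:
        r = reads[i]
        if isinstance(r, tuple):
            r = Read(id=r[0], sequence=r[1])
        elif isinstance(r, str):
            r = Read(id=f"read{i:06d}", sequence=r)
        out.append(
            Read(
                id=r.id,
                sequence=r.sequence[:length],
                source_genome=r.source_genome,
                source_start=r.source_start,
                n_substitutions=r.n_substitutions,
            )
        )
    return out


def build_orf_db(contigs: Mapping[str, str], gene_table: pd.DataFrame) -> OrfDatabase:
    """Extract strand-resolved ORF nucleotide sequences from contigs.

    ``gene_table`` columns: contig_id, gene_id, start, end (0-based half-open),
    strand (+/-); optional bin_id (defaults to the contig id).  Minus-strand
    genes are reverse-complemented.
    """
    required = {"contig_id", "gene_id", "start", "end", "strand"}
    missing = required - set(gene_table.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    records = []
    for row in gene_table.itertuples(index=False):
        seq = contigs.get(row.contig_id)
        if seq is None:
            raise KeyError(f"gene table references unknown contig {row.contig_id!r}")
        start, end = int(row.start), int(row.end)
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"gene {row.gene_id!r} out of contig bounds")
        orf = seq[start:end]
        if row.strand == "-":
            orf = revcomp(orf)
        bin_id = str(getattr(row, "bin_id", row.contig_id))
        records.append((str(row.gene_id), bin_id, orf))
    return OrfDatabase(records)


def _evalue(score: float, read_len: int, db_len: int) -> float:
    return KA_K * read_len * db_len * math.exp(-KA_LAMBDA * score)


def recruit_reads(
    reads: Sequence[Read],
    db: OrfDatabase,
    min_len: int = 200,
    max_evalue: float = 1e-5,
    min_identity: float = 0.70,
    best_hit_only: bool = True,
) -> list[RecruitmentHit]:
    """Align reads to the ORF database and keep filtered hits.

    The best (highest-scoring) alignment per read is retained when it passes
    both filters: alignment length strictly greater than ``min_len`` and
    e-value strictly below ``max_evalue``.  With ``best_hit_only=False`` every
    passing alignment is kept instead.
    """
    hits: list[RecruitmentHit] = []
    for read in reads:
        if isinstance(read, tuple):
            read = Read(id=read[0], sequence=read[1])
        if len(read.sequence) < 30:
            continue
        alns = align_local(
            read.sequence,
            db.concatenated,
            min_len=min(50, len(read.sequence)),
            min_identity=min_identity,
            query_id=read.id,
            target_id="orf_db",
        )
        if not alns:
            continue
        candidates = alns if not best_hit_only else [alns[0]]
        for al in candidates:
            if al.length <= min_len:
                continue
            ev = _evalue(al.score, len(read.sequence), db.total_length)
            if ev >= max_evalue:
                continue
            gene_id, bin_id = db.locate(al.t_start)
            hits.append(
                RecruitmentHit(
                    read_id=read.id,
                    gene_id=gene_id,
                    bin_id=bin_id,
                    identity=al.identity,
                    length=al.length,
                    evalue=ev,
                    score=al.score,
                )
            )
            if best_hit_only:
                break
    return hits


def profile_by_identity(
    hits: Sequence[RecruitmentHit], cutoffs: Sequence[float] = DEFAULT_CUTOFFS
) -> dict[float, int]:
    """Hits with identity >= cutoff, for each cutoff percent (ascending)."""
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    identities = np.array([h.identity * 100.0 for h in hits])
    return {float(c): int((identities >= c - 1e-9).sum()) for c in cutoffs}


def normalize_recruitment(count: float, genome_size: int, n_queried: int) -> float:
    """Recruited reads per kb of genome per 10,000 queried reads."""
    if genome_size <= 0 or n_queried <= 0:
        raise ValueError("genome_size and n_queried must be positive")
    return (count / (genome_size / 1000.0)) * (10_000.0 / n_queried)


def cluster_recruitment(
    hits: Sequence[RecruitmentHit],
    cluster_members: Mapping[str, Sequence[str]],
    bin_sizes: Mapping[str, int],
    n_queried: int,
    sample_id: str = "sample",
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    salinity: float | None = None,
) -> list[RecruitmentProfile]:
    """Per-cluster identity profiles: normalized per MAG, averaged over members."""
    by_bin: dict[str, list[RecruitmentHit]] = {}
    for h in hits:
        by_bin.setdefault(h.bin_id, []).append(h)
    profiles = []
    for cluster_id, members in sorted(cluster_members.items()):
        per_cutoff = []
        for c in cutoffs:
            vals = []
            for m in members:
                counts = profile_by_identity(by_bin.get(m, []), cutoffs=[c])
                vals.append(normalize_recruitment(counts[float(c)], bin_sizes[m], n_queried))
            per_cutoff.append(float(np.mean(vals)) if vals else 0.0)
        profiles.append(
            RecruitmentProfile(
                cluster_id=cluster_id,
                sample_id=sample_id,
                cutoffs=tuple(float(c) for c in cutoffs),
                normalized_counts=tuple(per_cutoff),
                salinity=salinity,
            )
        )
    return profiles
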