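"""Seeded synthetic-community generator.

Every downstream stage of the pipeline is exercised against communities with
known ground truth: genomes of controlled length and GC, single-copy marker
tokens embedded at recorded coordinates, assembly-like fragmentation into
contigs, a per-contig coverage matrix over a seasonal time series, and read
sets at controlled per-base divergence from their source genomes.

The generator states a simplified world on purpose:

* markers are unique random tokens recovered by exact search (standing in for
  profile-based COG hits while preserving the downstream counting semantics);
* coverage noise is additive Gaussian truncated at zero;
* read errors are substitutions only (an optional indel rate exists but
  defaults to zero) — identity-cutoff behaviour is substitution-driven.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BASES, Contig, Read, decode, encode

__all__ = [
    "SyntheticGenome",
    "PeakModel",
    "CommunityConfig",
    "CommunityFixture",
    "make_genome",
    "embed_markers",
    "fragment_genome",
    "simulate_coverage",
    "simulate_reads",
    "make_community_fixture",
]


@dataclass(frozen=True)
class SyntheticGenome:
    """A synthetic genome with recorded marker intervals and a truth lineage.

    ``marker_map`` holds (marker_id, start, end, copy_index) with 0-based
    half-open coordinates; intervals never overlap.
    """

    id: str
    sequence: str
    gc_target: float
    marker_map: tuple[tuple[str, int, int, int], ...] = ()
    truth_lineage: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeakModel:
    """Gaussian seasonal abundance bump: coverage height at the peak sample,
    decaying with a width measured in samples."""

    peak_sample: int
    width: float
    height: float


def _rng(seed: int, *context: object) -> np.random.Generator:
    """Independent, reproducible stream per (seed, context) pair."""
    digest = hashlib.sha256(("|".join(map(str, context)) + f"|{seed}").encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big") % (2**63))


def make_genome(length: int, gc_target: float, seed: int, genome_id: str = "genome") -> SyntheticGenome:
    """Random genome of exactly ``length`` bases with i.i.d. base draws at the
    requested GC fraction.  Deterministic for a fixed seed."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000 bases")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly inside (0, 1)")
    rng = _rng(seed, "genome", genome_id, length)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return SyntheticGenome(id=genome_id, sequence=decode(codes), gc_target=gc_target)


def embed_markers(
    genome: SyntheticGenome,
    marker_ids: Sequence[str],
    copies: Mapping[str, int] | None = None,
    marker_length: int = 500,
    seed: int = 0,
) -> SyntheticGenome:
    """Overwrite non-overlapping slices of the genome with unique marker tokens.

    Each marker is placed ``copies[marker]`` times (default 1) at coordinates
    recorded in ``marker_map``; tokens are random sequences re-drawn until they
    occur in the final genome exactly as many times as placed, so exact
    substring search recovers every copy.
    """
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError("duplicate marker_id in marker list")
    copies = dict(copies or {})
    n_copies = {m: int(copies.get(m, 1)) for m in marker_ids}
    total = sum(n_copies.values())
    if total * marker_length > genome.length // 2:
        raise ValueError("markers do not fit: total marker bases exceed 50% of genome length")
    rng = _rng(seed, "markers", genome.id)
    # non-overlap by construction: slots on a marker_length-spaced grid
    grid = np.arange(0, genome.length - marker_length + 1, marker_length)
    taken = {s for (_, s, _, _) in genome.marker_map}
    grid = np.array([g for g in grid if g not in taken])
    slots = rng.choice(grid, size=total, replace=False)
    seq = np.array(list(genome.sequence))
    marker_map = list(genome.marker_map)
    i = 0
    placements: list[tuple[str, int, int]] = []
    for marker in marker_ids:
        for copy_index in range(n_copies[marker]):
            start = int(slots[i])
            i += 1
            token = decode(rng.choice(4, size=marker_length).astype(np.uint8))
            seq[start : start + marker_length] = list(token)
            placements.append((marker, start, copy_index))
            marker_map.append((marker, start, start + marker_length, copy_index))
    out = "".join(seq)
    # uniqueness audit: every token occurs exactly where placed
    for marker, start, _ in placements:
        token = out[start : start + marker_length]
        if out.count(token) != sum(1 for m, s, e, c in marker_map if out[s:e] == token):
            raise RuntimeError(f"marker token for {marker} collides elsewhere in the genome")
    marker_map.sort(key=lambda t: t[1])
    return SyntheticGenome(
        id=genome.id,
        sequence=out,
        gc_target=genome.gc_target,
        marker_map=tuple(marker_map),
        truth_lineage=genome.truth_lineage,
    )


def fragment_genome(
    genome: SyntheticGenome, n_contigs: int, min_len: int = 1000, seed: int = 0
) -> list[Contig]:
    """Cut the genome into ``n_contigs`` disjoint contigs covering >= 90 % of it.

    Each block of size L/n loses a small random prefix gap (at most 10 % of
    the block), emulating assembly gaps while retaining provenance coordinates.
    """
    if n_contigs < 1 or n_contigs * min_len > genome.length:
        raise ValueError("infeasible fragmentation parameters")
    rng = _rng(seed, "fragment", genome.id, n_contigs)
    base = genome.length // n_contigs
    gap_cap = max(0, min(base - min_len, base // 10))
    contigs = []
    for i in range(n_contigs):
        block_start = i * base
        block_end = (i + 1) * base if i < n_contigs - 1 else genome.length
        gap = int(rng.integers(0, gap_cap + 1)) if gap_cap > 0 else 0
        start = block_start + gap
        contigs.append(
            Contig(
                id=f"{genome.id}_c{i:04d}",
                sequence=genome.sequence[start:block_end],
                source_genome=genome.id,
                source_start=start,
            )
        )
    return contigs


def simulate_coverage(
    contigs: Sequence[Contig],
    peaks: Mapping[str, PeakModel],
    n_samples: int = 37,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-contig x per-sample mean coverage with a per-genome Gaussian seasonal bump.

    All contigs of a genome share the genome's abundance curve up to additive
    Gaussian noise truncated at zero.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for g, pk in peaks.items():
        if pk.height < 0:
            raise ValueError(f"negative peak height for genome {g}")
    samples = [f"s{i:02d}" for i in range(n_samples)]
    rng = _rng(seed, "coverage", n_samples)
    x = np.arange(n_samples, dtype=float)
    rows = {}
    for contig in contigs:
        pk = peaks[contig.source_genome]
        mean = pk.height * np.exp(-0.5 * ((x - pk.peak_sample) / max(pk.width, 1e-9)) ** 2)
        noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        rows[contig.id] = np.maximum(mean + noise, 0.0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def simulate_reads(
    genome: SyntheticGenome,
    n_reads: int,
    read_len: int = 100,
    divergence: float = 0.0,
    seed: int = 0,
    indel_rate: float = 0.0,
    read_prefix: str | None = None,
) -> list[Read]:
    """Reads drawn uniformly from the genome with i.i.d. substitutions.

    ``divergence`` is the per-base substitution probability; substituted bases
    are always different from the original, so realized identity to the source
    concentrates at 1 - divergence.  ``indel_rate`` optionally introduces
    single-base deletions (off by default: the identity-profile behaviour the
    package tests is substitution-driven).
    """
    if read_len > genome.length:
        raise ValueError("read_len exceeds genome length")
    if not 0.0 <= divergence < 0.5:
        raise ValueError("divergence must lie in [0, 0.5)")
    if not 0.0 <= indel_rate < 0.5:
        raise ValueError("indel_rate must lie in [0, 0.5)")
    rng = _rng(seed, "reads", genome.id, n_reads, read_len)
    prefix = read_prefix or f"{genome.id}_r"
    codes = encode(genome.sequence)
    starts = rng.integers(0, genome.length - read_len + 1, size=n_reads)
    reads = []
    for i, start in enumerate(starts):
        r = codes[start : start + read_len].copy()
        nsub = 0
        if divergence > 0:
            mask = rng.random(read_len) < divergence
            nsub = int(mask.sum())
            if nsub:
                shift = rng.integers(1, 4, size=nsub).astype(np.uint8)
                r[mask] = (r[mask] + shift) % 4
        if indel_rate > 0:
            keep = rng.random(read_len) >= indel_rate
            r = r[keep]
        reads.append(
            Read(
                id=f"{prefix}{i:06d}",
                sequence=decode(r),
                source_genome=genome.id,
                source_start=int(start),
                n_substitutions=nsub,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# community fixture
# ---------------------------------------------------------------------------

_DEFAULT_LINEAGES = (
    "Bacteria;Actinobacteria;Actinomycetales;acI",
    "Bacteria;Actinobacteria;Acidimicrobiales;acIV",
    "Bacteria;Proteobacteria;Alphaproteobacteria;SAR11",
    "Bacteria;Proteobacteria;Gammaproteobacteria;SAR86",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriaceae",
    "Bacteria;Cyanobacteria;Synechococcales;Cyanobium",
    "Bacteria;Verrucomicrobia;Verrucomicrobiae;LD19",
    "Archaea;Thaumarchaeota;Nitrosopumilales;Nitrosopumilaceae",
)

_COG_CATEGORIES = list("JKLMNOTUVCEFGHIPQ")


@dataclass(frozen=True)
class CommunityConfig:
    """Stated world of the synthetic community.

    Defaults emulate the study system: genomes of 1-3 Mb with varying GC, a
    36-marker general single-copy panel, 37 seasonal samples, substitution-only
    reads.  ``n_replicated`` genomes are emitted twice as near-identical bins
    (0.5 % divergence) so dereplication has true clusters to recover.
    """

    n_genomes: int = 6
    genome_length_range: tuple[int, int] = (1_000_000, 3_000_000)
    gc_range: tuple[float, float] = (0.30, 0.60)
    n_markers: int = 36
    marker_length: int = 500
    n_samples: int = 37
    contig_target_len: int = 20_000
    coverage_noise_sd: float = 0.0
    peak_height_range: tuple[float, float] = (5.0, 30.0)
    peak_width_range: tuple[float, float] = (1.5, 4.0)
    n_replicated: int = 2
    replicate_divergence: float = 0.005
    reads_per_sample: int = 500
    read_len: int = 100
    unmapped_read_fraction: float = 0.3
    gene_len: int = 900
    gene_gap: int = 100

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CommunityConfig":
        kwargs = dict(d)
        for key in ("genome_length_range", "gc_range", "peak_height_range", "peak_width_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class CommunityFixture:
    """Internally consistent synthetic community with full truth tables."""

    config: CommunityConfig
    seed: int
    genomes: list[SyntheticGenome]
    contigs: list[Contig]
    true_bins: dict[str, str]  # contig id -> genome id
    coverage: pd.DataFrame  # contig x sample
    reads_by_sample: dict[str, list[Read]]
    total_reads: dict[str, float]
    genes: pd.DataFrame  # contig_id, gene_id, start, end, strand, cog_category
    classifications: pd.DataFrame  # contig_id, lineage, probability

    @property
    def sample_names(self) -> list[str]:
        return list(self.coverage.columns)

    def bins(self) -> dict[str, list[Contig]]:
        out: dict[str, list[Contig]] = {}
        for contig in self.contigs:
            out.setdefault(self.true_bins[contig.id], []).append(contig)
        return out


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    codes = encode(sequence).copy()
    mask = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
    codes[mask] = (codes[mask] + shift) % 4
    return decode(codes)


def _gene_table(contigs: Sequence[Contig], cfg: CommunityConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    period = cfg.gene_len + cfg.gene_gap
    for contig in contigs:
        n_genes = max(0, (contig.length - cfg.gene_gap) // period)
        for j in range(n_genes):
            start = cfg.gene_gap + j * period
            rows.append(
                {
                    "contig_id": contig.id,
                    "gene_id": f"{contig.id}_g{j:03d}",
                    "start": start,
                    "end": start + cfg.gene_len,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "cog_category": _COG_CATEGORIES[int(rng.integers(0, len(_COG_CATEGORIES)))],
                }
            )
    return pd.DataFrame(rows, columns=["contig_id", "gene_id", "start", "end", "strand", "cog_category"])


def make_community_fixture(config: CommunityConfig | None = None, seed: int = 0) -> CommunityFixture:
    """Build the full synthetic community with truth tables; deterministic."""
    cfg = config or CommunityConfig()
    rng = _rng(seed, "fixture")
    genomes: list[SyntheticGenome] = []
    marker_ids = [f"scg_{i:02d}" for i in range(cfg.n_markers)]
    lo, hi = cfg.genome_length_range
    for g in range(cfg.n_genomes):
        length = int(rng.integers(lo, hi + 1))
        gc = float(rng.uniform(*cfg.gc_range))
        genome = make_genome(length, gc, seed=seed + g, genome_id=f"g{g:02d}")
        genome = SyntheticGenome(
            id=genome.id,
            sequence=genome.sequence,
            gc_target=genome.gc_target,
            truth_lineage=_DEFAULT_LINEAGES[g % len(_DEFAULT_LINEAGES)],
        )
        genome = embed_markers(genome, marker_ids, marker_length=cfg.marker_length, seed=seed + g)
        genomes.append(genome)
    # near-identical replicates of the first n_replicated genomes: the same
    # population recovered from another sample of the time series
    replicated: list[SyntheticGenome] = []
    for g in range(min(cfg.n_replicated, cfg.n_genomes)):
        src = genomes[g]
        rep_seq = _mutate(src.sequence, cfg.replicate_divergence, _rng(seed, "replicate", src.id))
        replicated.append(
            SyntheticGenome(
                id=f"{src.id}r",
                sequence=rep_seq,
                gc_target=src.gc_target,
                marker_map=src.marker_map,
                truth_lineage=src.truth_lineage,
            )
        )
    all_genomes = genomes + replicated
    contigs: list[Contig] = []
    true_bins: dict[str, str] = {}
    for genome in all_genomes:
        n_contigs = max(1, genome.length // cfg.contig_target_len)
        frags = fragment_genome(genome, n_contigs, min_len=1000, seed=seed)
        contigs.extend(frags)
        for f in frags:
            true_bins[f.id] = genome.id
    peaks = {
        genome.id: PeakModel(
            peak_sample=int(rng.integers(0, cfg.n_samples)),
            width=float(rng.uniform(*cfg.peak_width_range)),
            height=float(rng.uniform(*cfg.peak_height_range)),
        )
        for genome in all_genomes
    }
    coverage = simulate_coverage(contigs, peaks, cfg.n_samples, cfg.coverage_noise_sd, seed=seed)
    # reads per sample proportional to genome abundance at that sample
    reads_by_sample: dict[str, list[Read]] = {}
    total_reads: dict[str, float] = {}
    lengths = pd.Series({c.id: c.length for c in contigs})
    for s_i, sample in enumerate(coverage.columns):
        per_genome = {
            genome.id: peaks[genome.id].height
            * np.exp(-0.5 * ((s_i - peaks[genome.id].peak_sample) / peaks[genome.id].width) ** 2)
            for genome in all_genomes
        }
        weights = np.array([per_genome[g.id] for g in all_genomes])
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        counts = np.floor(cfg.reads_per_sample * weights / weights.sum()).astype(int)
        sample_reads: list[Read] = []
        for genome, cnt in zip(all_genomes, counts):
            if cnt > 0:
                sample_reads.extend(
                    simulate_reads(
                        genome, int(cnt), cfg.read_len, 0.0, seed=seed + 1000 + s_i,
                        read_prefix=f"{sample}_{genome.id}_r",
                    )
                )
        reads_by_sample[sample] = sample_reads
        mapped = float((coverage[sample] * lengths).sum()) / cfg.read_len
        total_reads[sample] = mapped / (1.0 - cfg.unmapped_read_fraction)
    genes = _gene_table(contigs, cfg, _rng(seed, "genes"))
    lineage_of = {g.id: g.truth_lineage for g in all_genomes}
    cls_rows = [
        {"contig_id": c.id, "lineage": lineage_of[true_bins[c.id]], "probability": 0.95}
        for c in contigs
    ]
    classifications = pd.DataFrame(cls_rows, columns=["contig_id", "lineage", "probability"])
    return CommunityFixture(
        config=cfg,
        seed=seed,
        genomes=all_genomes,
        contigs=contigs,
        true_bins=true_bins,
        coverage=coverage,
        reads_by_sample=reads_by_sample,
        total_reads=total_reads,
        genes=genes,
        classifications=classifications,
    )
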