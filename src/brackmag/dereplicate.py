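"""Pairwise ANI, genome-cluster dereplication and the shared local-alignment contract.

Approved bins recovered independently from different samples of a time series
may be the same population sequenced twice.  This module collapses them into
genome clusters: the distance between two bins is one minus their average
nucleotide identity (ANI), defined only when alignments cover at least half of
the smaller bin; pairs below that coverage are held at the maximal distance of
1.0 so they can never merge.  Agglomerative clustering cut at ``1 - ani_cutoff``
yields the clusters, and a stability check verifies that single, average and
complete linkage agree — the hallmark of a well-separated identity gap.

The local aligner used across the package (spike-in recovery evaluation, ANI,
fragment recruitment, filter-fraction matching) lives here.  It is an exact,
seeded, *ungapped* aligner: match +1 / mismatch -2 scoring, maximal-scoring
segments per diagonal (Kadane recurrence), seeds chosen so that any alignment
meeting the length/identity thresholds is guaranteed to contain a clean seed
k-mer (pigeonhole on mismatch runs) whenever the inputs are small enough for
that k to be affordable; for large inputs the seed grows to bound random hits
and the guarantee degrades gracefully (documented in the methods note).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import Bin, as_bin, encode

__all__ = [
    "LocalAlignment",
    "ANIResult",
    "GenomeCluster",
    "align_local",
    "pairwise_ani",
    "ani_matrix",
    "cluster_bins",
    "linkage_stability",
]

_MATCH = 1
_MISMATCH = -2

_LINKAGE_ALIASES = {"single": "single", "average": "average", "complete": "complete", "full": "complete"}


@dataclass(frozen=True)
class LocalAlignment:
    """One ungapped local alignment between a query and a target sequence.

    Coordinates are 0-based half-open on the forward strand of each sequence;
    for ``strand == '-'`` the query interval refers to the original (input)
    query orientation.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identity: float
    length: int
    strand: str
    score: float


@dataclass(frozen=True)
class ANIResult:
    """Symmetric ANI between two bins; ``ani is None`` marks an undefined pair
    (alignments cover less than half of the smaller bin)."""

    bin_a: str
    bin_b: str
    ani: float | None
    aligned_fraction_smaller: float

    @property
    def defined(self) -> bool:
        return self.ani is not None


@dataclass(frozen=True)
class GenomeCluster:
    cluster_id: str
    member_bins: tuple[str, ...]
    representative: str


# ---------------------------------------------------------------------------
# seeded ungapped local alignment
# ---------------------------------------------------------------------------


def _guaranteed_seed_k(min_len: int, min_identity: float) -> int:
    """Largest k such that every ungapped alignment of length >= min_len and
    identity >= min_identity contains an exact k-mer match (pigeonhole over
    mismatch-free runs), capped to [4, 31]."""
    best = None
    for length in range(min_len, 4 * min_len + 64):
        mism = math.floor((1.0 - min_identity) * length + 1e-9)
        run = math.ceil((length - mism) / (mism + 1))
        best = run if best is None else min(best, run)
    return max(4, min(int(best), 31))


def _auto_seed_k(min_len: int, min_identity: float, qlen: int, tlen: int) -> int:
    k_exact = _guaranteed_seed_k(min_len, min_identity)
    area = max(1, qlen) * max(1, tlen)
    if area <= 2_000_000:  # small enough that spurious seed hits are cheap
        return k_exact
    k_noise = math.ceil(math.log(area / 16, 4))
    return max(4, min(31, max(k_exact, k_noise)))


def _kmer_table(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and integer codes of all k-mers free of non-ACGT bases."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.uint64)
    kc = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        kc = kc * np.uint64(4) + codes[i : i + n].astype(np.uint64)
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.flatnonzero(valid).astype(np.int64)
    return pos, kc[valid]


def _seed_diagonals(qc: np.ndarray, tc: np.ndarray, k: int) -> np.ndarray:
    """Distinct diagonals (qpos - tpos) carrying at least one exact seed match."""
    qpos, qk = _kmer_table(qc, k)
    tpos, tk = _kmer_table(tc, k)
    if qpos.size == 0 or tpos.size == 0:
        return np.empty(0, np.int64)
    order = np.argsort(tk, kind="stable")
    tk_s = tk[order]
    tpos_s = tpos[order]
    left = np.searchsorted(tk_s, qk, side="left")
    right = np.searchsorted(tk_s, qk, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64)
    q_rep = np.repeat(qpos, counts)
    starts = np.repeat(left, counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    t_rep = tpos_s[starts + offs]
    diags = q_rep - t_rep
    uniq, cnt = np.unique(diags, return_counts=True)
    if uniq.size > 5000:  # large noisy input: demand two independent seeds
        uniq = uniq[cnt >= 2]
    return uniq


def _segments_on_diagonal(
    qc: np.ndarray, tc: np.ndarray, d: int, min_len: int, min_identity: float
) -> list[tuple[int, int, int, int, int, int, float]]:
    """Maximal-scoring ungapped segments on diagonal d (qpos = tpos + d).

    Returns tuples (score, q_start, q_end, t_start, t_end, length, identity).
    Non-ACGT positions act as hard breaks so alignments never span them.
    """
    lo_t = max(0, -d)
    hi_t = min(tc.size, qc.size - d)
    if hi_t - lo_t < min_len:
        return []
    q = qc[lo_t + d : hi_t + d]
    t = tc[lo_t:hi_t]
    valid = (q < 4) & (t < 4)
    match = (q == t) & valid
    s = np.where(match, _MATCH, _MISMATCH).astype(np.int64)
    big = 3 * (t.size + 10)
    s[~valid] = -big
    c = np.cumsum(s)
    runmin = np.minimum.accumulate(np.concatenate(([0], c[:-1])))
    h = c - runmin
    posmask = h > 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], posmask.view(np.int8), [0]))))
    out = []
    for s0, e0 in zip(edges[0::2], edges[1::2]):
        peak = s0 + int(np.argmax(h[s0:e0]))
        length = peak - s0 + 1
        score = int(h[peak])
        matches = round((score + 2 * length) / 3)
        ident = matches / length
        if length >= min_len and ident >= min_identity - 1e-12:
            t_start = lo_t + s0
            t_end = lo_t + peak + 1
            out.append((score, t_start + d, t_end + d, t_start, t_end, length, ident))
    return out


def _greedy_nonoverlapping(segs: list[tuple]) -> list[tuple]:
    """Keep highest-scoring segments that overlap no kept one in query or target."""
    segs = sorted(segs, key=lambda r: (-r[0], r[3], r[1], r[7]))
    kept: list[tuple] = []
    for seg in segs:
        _, qs, qe, ts, te, *_ = seg
        ok = True
        for k in kept:
            if qs < k[2] and k[1] < qe:
                ok = False
                break
            if ts < k[4] and k[3] < te:
                ok = False
                break
        if ok:
            kept.append(seg)
    return kept


def align_local(
    query: str,
    target: str,
    min_len: int = 100,
    min_identity: float = 0.9,
    *,
    both_strands: bool = True,
    seed_k: int | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> list[LocalAlignment]:
    """Maximal non-overlapping ungapped local alignments meeting both thresholds.

    Deterministic ordering: score descending, then target position, then query
    position, then strand ('+' before '-').
    """
    if not query or not target:
        raise ValueError("align_local requires non-empty sequences")
    qc_fwd = encode(query)
    tc = encode(target)
    k = seed_k if seed_k is not None else _auto_seed_k(min_len, min_identity, len(query), len(target))
    raw: list[tuple] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        if strand == "+":
            qc = qc_fwd
        else:
            qc = qc_fwd[::-1].copy()
            flip = qc < 4
            qc[flip] = 3 - qc[flip]
        for d in _seed_diagonals(qc, tc, k):
            for score, qs, qe, ts, te, length, ident in _segments_on_diagonal(
                qc, tc, int(d), min_len, min_identity
            ):
                if strand == "-":
                    qs, qe = len(query) - qe, len(query) - qs
                raw.append((score, qs, qe, ts, te, length, ident, 0 if strand == "+" else 1))
    kept = _greedy_nonoverlapping(raw)
    kept.sort(key=lambda r: (-r[0], r[3], r[1], r[7]))
    return [
        LocalAlignment(
            query_id=query_id,
            target_id=target_id,
            q_start=qs,
            q_end=qe,
            t_start=ts,
            t_end=te,
            identity=ident,
            length=length,
            strand="+" if st == 0 else "-",
            score=float(score),
        )
        for score, qs, qe, ts, te, length, ident, st in kept
    ]


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

_SEPARATOR = "N" * 35  # longer than any seed k, so k-mers never span contigs


def _concat(bin_: Bin) -> str:
    return _SEPARATOR.join(c.sequence for c in bin_.contigs)


def pairwise_ani(
    bin_a: Bin | dict | list | str,
    bin_b: Bin | dict | list | str,
    min_len: int = 100,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> ANIResult:
    """Alignment-length-weighted ANI between two bins.

    The result is undefined (``ani is None``) unless the alignments cover at
    least ``min_coverage`` of the smaller bin's bases, following the rule of a
    minimum of 50 % coverage of the smallest bin in each pair.
    """
    a = as_bin(bin_a, "bin_a")
    b = as_bin(bin_b, "bin_b")
    if a.size == 0 or b.size == 0:
        raise ValueError("pairwise_ani requires non-empty bins")
    # canonical orientation for exact symmetry
    first, second = (a, b) if a.id <= b.id else (b, a)
    alns = align_local(
        _concat(first),
        _concat(second),
        min_len=min_len,
        min_identity=min_identity,
        query_id=first.id,
        target_id=second.id,
    )
    small_size = min(a.size, b.size)
    total_cols = 0
    total_matches = 0.0
    for al in alns:
        total_cols += al.length
        total_matches += al.identity * al.length
    # ungapped + non-overlapping in both coordinates, so summed alignment
    # length is a valid base count on either side, in particular the smaller
    frac = min(1.0, total_cols / small_size)
    if frac < min_coverage or total_cols == 0:
        return ANIResult(a.id, b.id, None, frac)
    return ANIResult(a.id, b.id, total_matches / total_cols, frac)


def ani_matrix(bins: list[Bin], **kwargs) -> tuple[pd.DataFrame, dict[frozenset, ANIResult]]:
    """Square symmetric distance matrix (1 - ANI; undefined pairs -> 1.0)."""
    ids = [b.id for b in bins]
    if len(set(ids)) != len(ids):
        raise ValueError("bin ids must be unique")
    dist = pd.DataFrame(0.0, index=ids, columns=ids)
    results: dict[frozenset, ANIResult] = {}
    for x, y in itertools.combinations(bins, 2):
        res = pairwise_ani(x, y, **kwargs)
        results[frozenset((x.id, y.id))] = res
        d = 1.0 if res.ani is None else 1.0 - res.ani
        dist.loc[x.id, y.id] = d
        dist.loc[y.id, x.id] = d
    return dist, results


def _partition(dist: pd.DataFrame, cut: float, method: str) -> list[frozenset]:
    if dist.shape[0] == 1:
        return [frozenset(dist.index)]
    condensed = squareform(dist.values, checks=False)
    z = hierarchy.linkage(condensed, method=method)
    labels = hierarchy.fcluster(z, t=cut, criterion="distance")
    groups: dict[int, set[str]] = {}
    for bin_id, lab in zip(dist.index, labels):
        groups.setdefault(int(lab), set()).add(bin_id)
    return [frozenset(g) for g in groups.values()]


def cluster_bins(
    bins: list[Bin],
    ani_cutoff: float = 0.96,
    linkage: str = "average",
    distance: pd.DataFrame | None = None,
    cluster_prefix: str = "BACL",
    **ani_kwargs,
) -> list[GenomeCluster]:
    """Agglomerative dereplication of bins into genome clusters.

    Distance is 1 - ANI with undefined pairs at 1.0; the tree is cut at
    ``1 - ani_cutoff``.  Cluster ids are assigned by decreasing size, ties
    broken by the lexicographically smallest member id.  The representative is
    the member with the largest total assembly length (ties by id).
    """
    if not bins:
        raise ValueError("no bins to cluster")
    method = _LINKAGE_ALIASES.get(linkage)
    if method is None:
        raise ValueError(f"unknown linkage method {linkage!r}")
    order = sorted(bins, key=lambda b: b.id)
    if distance is None:
        distance, _ = ani_matrix(order, **ani_kwargs)
    else:
        distance = distance.loc[[b.id for b in order], [b.id for b in order]]
    parts = _partition(distance, 1.0 - ani_cutoff, method)
    sizes = {b.id: b.size for b in bins}
    parts.sort(key=lambda g: (-len(g), min(g)))
    clusters = []
    for i, members in enumerate(parts, start=1):
        rep = max(sorted(members), key=lambda m: (sizes[m], ))
        clusters.append(
            GenomeCluster(
                cluster_id=f"{cluster_prefix}{i}",
                member_bins=tuple(sorted(members)),
                representative=rep,
            )
        )
    return clusters


def linkage_stability(
    bins: list[Bin],
    ani_cutoff: float = 0.96,
    distance: pd.DataFrame | None = None,
    **ani_kwargs,
) -> tuple[bool, dict[str, list[frozenset]]]:
    """True iff single, average and complete linkage give identical partitions."""
    order = sorted(bins, key=lambda b: b.id)
    if distance is None:
        distance, _ = ani_matrix(order, **ani_kwargs)
    else:
        distance = distance.loc[[b.id for b in order], [b.id for b in order]]
    cut = 1.0 - ani_cutoff
    parts = {m: sorted(_partition(distance, cut, m), key=min) for m in ("single", "average", "complete")}
    vals = list(parts.values())
    stable = all(set(v) == set(vals[0]) for v in vals[1:])
    return stable, parts
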