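"""Ensemble-assembly merging: sliding-window cut-up, overlap-layout-consensus
reassembly, and the in-silico spike-in recovery evaluation.

Contigs produced by several de Bruijn assemblies of the same sample are merged
by cutting every contig into highly redundant sliding windows (2000 bp every
100 bp; contigs shorter than 1100 bp pass uncut in two copies, and the first
and last window of each contig are duplicated so every base is covered at
least twice) and re-assembling the windows with an overlap-layout-consensus
step whose only stated parameters are a minimum overlap length of 40 bp and a
minimum overlap identity of 90 %.

The OLC step here is a deterministic re-implementation of that contract:
suffix-prefix overlaps on both strands, greedy longest-overlap-first path
construction with ties broken by fragment id, per-column majority consensus
with lexicographic tie-breaking (A<C<G<T).  The approach is validated the way
the original procedure was: a reference genome is tiled into 1000-bp windows
every 100 bp, spiked into an unrelated contig background, re-assembled, and
the assembly compared back to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Contig, decode, encode, revcomp
from .dereplicate import align_local

__all__ = [
    "SubContig",
    "RecoveryReport",
    "cut_up",
    "tile_genome",
    "olc_assemble",
    "evaluate_recovery",
    "spike_in_experiment",
]


@dataclass(frozen=True)
class SubContig:
    """A sliding-window slice of a source contig.

    ``copy_number`` is 2 for edge windows and for whole small contigs that are
    not cut (they are emitted twice so consensus is defined everywhere)."""

    id: str
    sequence: str
    source_contig: str
    start: int
    copy_number: int


@dataclass(frozen=True)
class RecoveryReport:
    """Spike-in style comparison of an assembly against a reference genome."""

    pct_reference_recovered: float
    pct_identity: float
    n_contigs: int
    pct_bases_unmapped: float


def _as_id_seq(contigs: Sequence) -> list[tuple[str, str]]:
    out = []
    for i, c in enumerate(contigs):
        if isinstance(c, str):
            out.append((f"f{i:06d}", c))
        elif isinstance(c, tuple):
            out.append((c[0], c[1]))
        else:
            out.append((c.id, c.sequence))
    return out


def cut_up(
    contigs: Sequence,
    window: int = 2000,
    step: int = 100,
    small_cutoff: int = 1100,
) -> list[SubContig]:
    """Cut contigs into sliding windows of ``window`` bp every ``step`` bp.

    Contigs shorter than ``small_cutoff`` are emitted whole, twice.  For cut
    contigs, the first and the last window are emitted twice; a contig no
    longer than ``window`` yields a single (duplicated) window.  Every source
    base is therefore covered by at least two subcontig copies.
    """
    items = _as_id_seq(contigs)
    if not items:
        raise ValueError("empty contig list")
    if not window > step > 0:
        raise ValueError("require window > step > 0")
    out: list[SubContig] = []

    def emit(cid: str, seq: str, start: int, idx: int, copy_number: int, dup: bool) -> None:
        out.append(SubContig(f"{cid}.{idx}", seq, cid, start, copy_number))
        if dup:
            out.append(SubContig(f"{cid}.{idx}d", seq, cid, start, copy_number))

    for cid, seq in items:
        n = len(seq)
        if n < small_cutoff:
            emit(cid, seq, 0, 0, 2, dup=True)
            continue
        if n <= window:
            emit(cid, seq, 0, 0, 2, dup=True)
            continue
        offsets = list(range(0, n - window + 1, step))
        if offsets[-1] != n - window:
            offsets.append(n - window)
        last = len(offsets) - 1
        for idx, off in enumerate(offsets):
            edge = idx == 0 or idx == last
            emit(cid, seq[off : off + window], off, idx, 2 if edge else 1, dup=edge)
    return out


def tile_genome(genome: str, window: int = 1000, step: int = 100) -> list[str]:
    """Tile a genome into windows at offsets 0, step, 2*step, ...

    If the final regular window does not reach the last base, one extra
    full-length window anchored at the genome end is appended so every base is
    covered.
    """
    n = len(genome)
    if window > n:
        raise ValueError("window longer than genome")
    offsets = list(range(0, n - window + 1, step))
    if offsets[-1] != n - window:
        offsets.append(n - window)
    return [genome[o : o + window] for o in offsets]


# ---------------------------------------------------------------------------
# overlap detection
# ---------------------------------------------------------------------------


def _orient_codes(codes: np.ndarray, orient: int) -> np.ndarray:
    if orient == 1:
        return codes
    rc = codes[::-1].copy()
    mask = rc < 4
    rc[mask] = 3 - rc[mask]
    return rc


def _overlap_identity(a: np.ndarray, b: np.ndarray, length: int) -> float:
    """Hamming identity of a's suffix of ``length`` against b's prefix."""
    sa = a[a.size - length :]
    sb = b[:length]
    return float(((sa == sb) & (sa < 4)).sum()) / length


def _longest_overlap(a: np.ndarray, b: np.ndarray, min_overlap: int, min_identity: float) -> int | None:
    top = min(a.size, b.size) - 1  # full-length overlap is containment, not an edge
    for length in range(top, min_overlap - 1, -1):
        if _overlap_identity(a, b, length) >= min_identity - 1e-12:
            return length
    return None


def find_overlaps(
    fragments: Sequence[tuple[str, str]],
    min_overlap: int = 40,
    min_identity: float = 0.90,
    both_strands: bool = True,
    exhaustive: bool | None = None,
) -> list[tuple[str, int, str, int, int]]:
    """Suffix-prefix overlaps between oriented fragments.

    Returns the longest qualifying overlap per ordered oriented pair as tuples
    ``(a_id, a_orient, b_id, b_orient, length)`` with orientations +-1,
    deduplicated so each physical join appears once (canonical form).

    For small inputs every pair and every overlap length is enumerated
    exactly; for large inputs candidates are anchored on each fragment's
    prefix k-mer (k = min(31, min_overlap)), which is exact for noise-free
    fragments and heuristic when the first k bases of an overlap contain a
    mismatch.
    """
    ids = [fid for fid, _ in fragments]
    if len(set(ids)) != len(ids):
        raise ValueError("fragment ids must be unique")
    codes = {fid: encode(seq) for fid, seq in fragments}
    orients = (1, -1) if both_strands else (1,)
    oriented = {(fid, o): _orient_codes(codes[fid], o) for fid in ids for o in orients}
    if exhaustive is None:
        exhaustive = len(fragments) <= 64
    found: dict[tuple, int] = {}

    def record(a: str, oa: int, b: str, ob: int, length: int) -> None:
        e1 = (a, oa, b, ob)
        e2 = (b, -ob, a, -oa)
        key = min(e1, e2)
        if length > found.get(key, 0):
            found[key] = length

    if exhaustive:
        for a in ids:
            for oa in orients:
                ca = oriented[(a, oa)]
                for b in ids:
                    if a == b:
                        continue
                    for ob in orients:
                        length = _longest_overlap(ca, oriented[(b, ob)], min_overlap, min_identity)
                        if length is not None:
                            record(a, oa, b, ob, length)
    else:
        k = min(31, min_overlap)
        # index every k-mer of every oriented fragment
        all_pos, all_code, all_frag = [], [], []
        keys = sorted(oriented)
        for fi, key in enumerate(keys):
            arr = oriented[key]
            n = arr.size - k + 1
            if n <= 0:
                continue
            kc = np.zeros(n, dtype=np.uint64)
            for i in range(k):
                kc = kc * np.uint64(4) + arr[i : i + n].astype(np.uint64)
            all_pos.append(np.arange(n, dtype=np.int64))
            all_code.append(kc)
            all_frag.append(np.full(n, fi, dtype=np.int64))
        codes_cat = np.concatenate(all_code)
        pos_cat = np.concatenate(all_pos)
        frag_cat = np.concatenate(all_frag)
        order = np.argsort(codes_cat, kind="stable")
        codes_s, pos_s, frag_s = codes_cat[order], pos_cat[order], frag_cat[order]
        for bi, bkey in enumerate(keys):
            b, ob = bkey
            cb = oriented[bkey]
            if cb.size < k:
                continue
            anchor = np.uint64(0)
            for i in range(k):
                anchor = anchor * np.uint64(4) + np.uint64(cb[i])
            lo = np.searchsorted(codes_s, anchor, side="left")
            hi = np.searchsorted(codes_s, anchor, side="right")
            for j in range(lo, hi):
                ai = int(frag_s[j])
                a, oa = keys[ai]
                if a == b:
                    continue
                ca = oriented[keys[ai]]
                length = ca.size - int(pos_s[j])
                if length < min_overlap or length >= min(ca.size, cb.size):
                    continue
                if _overlap_identity(ca, cb, length) >= min_identity - 1e-12:
                    record(a, oa, b, ob, length)
    return [(a, oa, b, ob, ln) for (a, oa, b, ob), ln in sorted(found.items())]


# ---------------------------------------------------------------------------
# layout and consensus
# ---------------------------------------------------------------------------


class _Chains:
    """Greedy chain builder over oriented overlap edges with union-find cycle checks."""

    def __init__(self, ids: Sequence[str]):
        self.orient: dict[str, int] = {}
        self.succ: dict[str, tuple[str, int]] = {}
        self.pred: dict[str, tuple[str, int]] = {}
        self.parent = {i: i for i in ids}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def usable(self, x: str, ox: int, y: str, oy: int) -> bool:
        if x == y:
            return False
        if self.orient.get(x, ox) != ox or self.orient.get(y, oy) != oy:
            return False
        if x in self.succ or y in self.pred:
            return False
        return self.find(x) != self.find(y)

    def add(self, x: str, ox: int, y: str, oy: int, length: int) -> None:
        self.orient[x] = ox
        self.orient[y] = oy
        self.succ[x] = (y, length)
        self.pred[y] = (x, length)
        self.parent[self.find(x)] = self.find(y)


def olc_assemble(
    fragments: Sequence,
    min_overlap: int = 40,
    min_identity: float = 0.90,
    both_strands: bool = True,
) -> list[str]:
    """Overlap-layout-consensus merge of fragments into contigs.

    Exact duplicates and exact substrings (either strand) are removed, the
    overlap graph is chained greedily (longest overlap first, ties by fragment
    id), and each chain is collapsed by per-column majority vote with ties
    broken lexicographically.  Deterministic for a fixed input order.
    """
    items = _as_id_seq(fragments)
    if not items:
        raise ValueError("empty input")
    # exact duplicate removal, collapsing reverse-complement twins (first id wins)
    seen: set[str] = set()
    uniq: list[tuple[str, str]] = []
    for fid, seq in items:
        key = min(seq, revcomp(seq)) if both_strands else seq
        if key not in seen:
            seen.add(key)
            uniq.append((fid, seq))
    # exact containment removal against the pool of remaining fragments
    big_fwd = "#".join(seq for _, seq in uniq)
    big_rc = "#".join(revcomp(seq) for _, seq in uniq)
    kept = []
    for fid, seq in uniq:
        n_fwd = big_fwd.count(seq)
        n_rc = big_rc.count(seq)
        if n_fwd > 1 or n_rc > (1 if seq == revcomp(seq) else 0):
            continue  # contained in (or equal to the reverse complement of) another fragment
        kept.append((fid, seq))
    if not kept:  # everything mutually contained: keep the longest
        kept = [max(uniq, key=lambda t: (len(t[1]), t[0]))]
    edges = find_overlaps(kept, min_overlap, min_identity, both_strands=both_strands)
    edges.sort(key=lambda e: (-e[4], e[0], e[2], e[1], e[3]))
    chains = _Chains([fid for fid, _ in kept])
    for a, oa, b, ob, length in edges:
        for x, ox, y, oy in ((a, oa, b, ob), (b, -ob, a, -oa)):
            if chains.usable(x, ox, y, oy):
                chains.add(x, ox, y, oy, length)
                break
    seqs = dict(kept)
    contigs: list[str] = []
    for fid, _ in kept:
        if fid in chains.pred:
            continue  # not a chain head
        # walk the chain, accumulating offsets
        layout: list[tuple[str, int]] = []
        offset = 0
        cur = fid
        while True:
            layout.append((cur, offset))
            nxt = chains.succ.get(cur)
            if nxt is None:
                break
            offset += len(seqs[cur]) - nxt[1]
            cur = nxt[0]
        total = offset + len(seqs[cur])
        counts = np.zeros((total, 4), dtype=np.int32)
        for frag, off in layout:
            arr = _orient_codes(encode(seqs[frag]), chains.orient.get(frag, 1))
            valid = arr < 4
            idx = np.flatnonzero(valid) + off
            counts[idx, arr[valid]] += 1
        consensus = np.argmax(counts, axis=1).astype(np.uint8)  # argmax ties -> lowest code: A<C<G<T
        contigs.append(decode(consensus))
    # no output contig may be a substring of another
    final = []
    pool = "#".join(contigs)
    pool_rc = "#".join(revcomp(c) for c in contigs)
    for c in contigs:
        if pool.count(c) > 1 or pool_rc.count(c) > (1 if c == revcomp(c) else 0):
            continue
        final.append(c)
    return final if final else [max(contigs, key=len)]


def evaluate_recovery(
    assembled: Sequence[str],
    reference: str,
    min_identity: float = 0.90,
    min_len: int = 100,
) -> RecoveryReport:
    """Compare assembled contigs against a reference genome.

    ``pct_reference_recovered`` is the percentage of reference bases covered
    by at least one alignment at >= ``min_identity``; ``pct_identity`` the
    identity over all aligned columns; ``pct_bases_unmapped`` the percentage
    of assembled bases in no alignment.
    """
    assembled = [a.sequence if isinstance(a, Contig) else (a[1] if isinstance(a, tuple) else a) for a in assembled]
    if not assembled:
        raise ValueError("no assembled contigs")
    if not reference:
        raise ValueError("empty reference")
    covered = np.zeros(len(reference), dtype=bool)
    total_cols = 0
    total_matches = 0.0
    total_bases = 0
    unmapped = 0
    for i, contig in enumerate(assembled):
        total_bases += len(contig)
        alns = align_local(
            contig, reference, min_len=min(min_len, len(contig)), min_identity=min_identity,
            query_id=f"contig{i}", target_id="reference",
        )
        qcov = np.zeros(len(contig), dtype=bool)
        for al in alns:
            covered[al.t_start : al.t_end] = True
            qcov[al.q_start : al.q_end] = True
            total_cols += al.length
            total_matches += al.identity * al.length
        unmapped += int((~qcov).sum())
    return RecoveryReport(
        pct_reference_recovered=100.0 * float(covered.sum()) / len(reference),
        pct_identity=(100.0 * total_matches / total_cols) if total_cols else 0.0,
        n_contigs=len(assembled),
        pct_bases_unmapped=100.0 * unmapped / total_bases,
    )


def spike_in_experiment(
    seed: int = 0,
    reference_length: int = 100_000,
    n_background: int = 20,
    background_length: int = 25_000,
    background_contigs: int = 25,
    window: int = 1000,
    step: int = 100,
    min_overlap: int = 40,
    min_identity: float = 0.90,
) -> RecoveryReport:
    """Synthetic analog of the in-silico spike-in validation.

    A seeded random reference genome is tiled into ``window``-bp fragments
    every ``step`` bp, mixed with contigs fragmented from ``n_background``
    unrelated random genomes, re-assembled with the OLC contract, and the
    output compared back to the reference.
    """
    from .synthetic_community import fragment_genome, make_genome

    reference = make_genome(reference_length, 0.5, seed=seed, genome_id="spike_ref")
    fragments: list[tuple[str, str]] = [
        (f"tile{i:05d}", t) for i, t in enumerate(tile_genome(reference.sequence, window, step))
    ]
    for b in range(n_background):
        g = make_genome(background_length, 0.45, seed=seed + 7919 * (b + 1), genome_id=f"bg{b:02d}")
        for contig in fragment_genome(g, background_contigs, min_len=500, seed=seed + b):
            fragments.append((contig.id, contig.sequence))
    assembled = olc_assemble(fragments, min_overlap=min_overlap, min_identity=min_identity)
    return evaluate_recovery(assembled, reference.sequence, min_identity=0.90)
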