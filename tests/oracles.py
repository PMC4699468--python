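"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the ungapped
Smith-Waterman recurrence is evaluated over the full dynamic-programming
matrix, and overlap detection enumerates every overlap length of every
oriented pair.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -2

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def dp_best_local(
    query: str,
    target: str,
    min_len: int,
    min_identity: float,
    both_strands: bool = True,
) -> tuple[int, int, int] | None:
    """Best ungapped local alignment by full-matrix DP.

    H[i,j] = max(0, H[i-1,j-1] + s(i,j)); returns (score, length, matches) of
    the best-scoring cell whose since-restart segment meets both thresholds,
    or None.  Ties resolved toward larger score only (the caller compares the
    triple, which is unique given the scoring scheme: length determines the
    mismatch count at fixed score).
    """
    best: tuple[int, int, int] | None = None
    strands = (query, rc(query)) if both_strands else (query,)
    ta = np.frombuffer(target.encode(), np.uint8)
    for q in strands:
        qa = np.frombuffer(q.encode(), np.uint8)
        n = ta.size
        h_prev = np.zeros(n + 1, np.int64)
        l_prev = np.zeros(n + 1, np.int64)
        m_prev = np.zeros(n + 1, np.int64)
        for i in range(qa.size):
            s = np.where(ta == qa[i], MATCH, MISMATCH)
            cand = h_prev[:-1] + s
            take = cand > 0
            h_cur = np.concatenate(([0], np.where(take, cand, 0)))
            l_cur = np.concatenate(([0], np.where(take, l_prev[:-1] + 1, 0)))
            m_cur = np.concatenate(([0], np.where(take, m_prev[:-1] + (s > 0), 0)))
            ok = (l_cur >= min_len) & (m_cur >= min_identity * l_cur - 1e-9)
            if ok.any():
                j = int(np.argmax(np.where(ok, h_cur, -1)))
                cell = (int(h_cur[j]), int(l_cur[j]), int(m_cur[j]))
                if best is None or cell[0] > best[0]:
                    best = cell
            h_prev, l_prev, m_prev = h_cur, l_cur, m_cur
    return best


def brute_force_overlaps(
    fragments: list[tuple[str, str]],
    min_overlap: int,
    min_identity: float,
    both_strands: bool = True,
) -> set[tuple[str, int, str, int, int]]:
    """Longest qualifying suffix-prefix Hamming overlap per ordered oriented
    pair, in the same canonical (deduplicated) form the package reports."""
    orients = (1, -1) if both_strands else (1,)
    oriented = {
        (fid, o): (seq if o == 1 else rc(seq)) for fid, seq in fragments for o in orients
    }
    found: dict[tuple, int] = {}
    for (a, oa), sa in oriented.items():
        for (b, ob), sb in oriented.items():
            if a == b:
                continue
            top = min(len(sa), len(sb)) - 1
            for length in range(top, min_overlap - 1, -1):
                suffix = sa[-length:]
                prefix = sb[:length]
                matches = sum(1 for x, y in zip(suffix, prefix) if x == y)
                if matches / length >= min_identity - 1e-12:
                    key = min((a, oa, b, ob), (b, -ob, a, -oa))
                    if length > found.get(key, 0):
                        found[key] = length
                    break
    return {(a, oa, b, ob, ln) for (a, oa, b, ob), ln in found.items()}
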