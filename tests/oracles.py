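"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through different algorithms/code
paths than the package: a Needleman-Wunsch DP for global identity, a
sliding-offset scan for ungapped placement, and direct rule arithmetic
for the homology filter.
"""

from __future__ import annotations

import numpy as np

GAP = -2
MATCH = 1
MISMATCH = -1
_K = 1 << 20  # packs (score, matches) as score*_K + matches for lexicographic max


def nw_score_matches(a: str, b: str) -> tuple[int, int]:
    """Optimal global alignment score (match +1 / mismatch −1 / gap −2)
    and the maximum match count among score-optimal alignments."""
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    js = np.arange(m + 1, dtype=np.int64)
    prev = GAP * _K * js  # row 0: leading gaps
    for i in range(1, n + 1):
        eq = bb == aa[i - 1]
        sub = np.where(eq, MATCH * _K + 1, MISMATCH * _K)
        diag = prev[:-1] + sub
        up = prev[1:] + GAP * _K
        best = np.maximum(diag, up)
        # horizontal gaps via running max of best[k] - gap*k
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = prev[0] + GAP * _K
        shifted = np.concatenate(([cur[0]], best))
        cur = np.maximum.accumulate(shifted - GAP * _K * np.arange(m + 1)) + GAP * _K * js
        prev = cur
    combined = int(prev[m])
    matches = combined % _K
    score = (combined - matches) // _K
    return score, matches


def nw_identity(a: str, b: str) -> float:
    """matches / alignment-length identity for the alignment found above.

    With linear gaps, gaps = len(a)+len(b) − 2·aligned and the score pins
    down the mismatch count, so the denominator follows from (score, M).
    """
    score, m = nw_score_matches(a, b)
    n_tot = len(a) + len(b)
    # score = 5M + 3X - 2(n_tot)  =>  X = (score + 2 n_tot - 5M) / 3
    x = (score + 2 * n_tot - 5 * m) / 3
    alen = n_tot - m - x
    return m / alen


def greedy_cluster_exhaustive(uniques, identity_threshold, identity_fn):
    """Greedy centroid clustering with an exhaustive candidate scan.

    ``uniques`` must already be in (size desc, sequence) order.  Returns
    the centroid index each unique was assigned to.
    """
    centroids: list[str] = []
    sizes: list[int] = []
    assignment = []
    for seq, size in uniques:
        hit = None
        for i, centroid in enumerate(centroids):
            if seq == centroid or identity_fn(seq, centroid) >= identity_threshold:
                hit = i
                break
        if hit is None:
            centroids.append(seq)
            sizes.append(size)
            assignment.append(len(centroids) - 1)
        else:
            sizes[hit] += size
            assignment.append(hit)
    return assignment, centroids, sizes


def sliding_matches(query: str, reference: str) -> int:
    """Max matching positions over every ungapped offset of query along
    reference, including partial overhangs; independent of the package's
    correlation-based implementation."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(reference.encode(), dtype=np.uint8)
    n_mask = q == ord("N")
    best = 0
    for offset in range(-(len(q) - 1), len(r)):
        lo = max(0, -offset)
        hi = min(len(q), len(r) - offset)
        if hi <= lo:
            continue
        seg_q = q[lo:hi]
        seg_r = r[lo + offset : hi + offset]
        matches = int(np.count_nonzero((seg_q == seg_r) & ~n_mask[lo:hi]))
        if matches > best:
            best = matches
    return best


def homology_rules(target: float, nontargets: dict, min_target: float, ratio_max: float):
    """Direct transcription of the three removal rules; returns the first
    rule fired or None."""
    worst = max(nontargets.values()) if nontargets else 0.0
    if worst > target:
        return 1
    if target < min_target:
        return 2
    if worst > ratio_max * target:
        return 3
    return None
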