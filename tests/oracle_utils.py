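"""Independent brute-force oracles used across the test suite.

Everything here is deliberately simple and slow: exhaustive scans,
textbook formulas and dense dynamic programming, kept free of any code
path from the package under test.
"""

from __future__ import annotations

import numpy as np

COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}


def revcomp_list(seq: list[int] | np.ndarray) -> list[int]:
    return [COMP[int(b)] for b in list(seq)[::-1]]


def smith_waterman(query, ref, match=1, mismatch=-4, gap=-6):
    """Full local-alignment DP; returns (best score, q_end, r_end).

    Linear gap penalty; used on fixtures small enough for an O(nm)
    Python loop.
    """
    q = list(query)
    r = list(ref)
    h = np.zeros((len(q) + 1, len(r) + 1))
    best, qe, re_ = 0.0, 0, 0
    for i in range(1, len(q) + 1):
        for j in range(1, len(r) + 1):
            s = match if q[i - 1] == r[j - 1] and q[i - 1] != 4 else mismatch
            val = max(0.0, h[i - 1, j - 1] + s, h[i - 1, j] + gap, h[i, j - 1] + gap)
            h[i, j] = val
            if val > best:
                best, qe, re_ = val, i, j
    return best, qe, re_


def best_ungapped_all_offsets(query: np.ndarray, ref: np.ndarray,
                              match=1, mismatch=-4):
    """Exhaustive scan of every full-containment offset for the
    maximal-scoring ungapped segment (vectorized Kadane per offset).
    Returns (score, q_start, q_end, ref_start).  Adequate for fixtures
    whose query is an interior (mutated) copy of the reference."""
    lq = len(query)
    windows = np.lib.stride_tricks.sliding_window_view(ref, lq)
    scores = np.where(windows == query[None, :], match, mismatch).astype(np.int64)
    prefix = np.concatenate(
        [np.zeros((scores.shape[0], 1), np.int64), np.cumsum(scores, axis=1)], axis=1)
    prefix_min = np.minimum.accumulate(prefix[:, :-1], axis=1)
    gains = prefix[:, 1:] - prefix_min
    per_offset = gains.max(axis=1)
    off = int(np.argmax(per_offset))
    j = int(np.argmax(gains[off]))
    i = int(np.argmin(prefix[off, : j + 1]))
    return int(gains[off, j]), i, j + 1, off + i


def exact_occurrences(needle: str, haystack: str) -> list[int]:
    """All exact match positions of needle in haystack."""
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def single_linkage_clusters(positions: list[int], window: int) -> list[list[int]]:
    """Brute-force transitive clustering over all pairs (union-find)."""
    n = len(positions)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted([sorted(g) for g in groups.values()])


def two_by_two_log_or(y: np.ndarray, x: np.ndarray) -> float:
    """ln(ad/bc) from the 2x2 table of binary outcome vs binary exposure."""
    a = np.sum((y == 1) & (x == 1))
    b = np.sum((y == 1) & (x == 0))
    c = np.sum((y == 0) & (x == 1))
    d = np.sum((y == 0) & (x == 0))
    return float(np.log((a * d) / (b * c)))


def classical_mds_oracle(dist: np.ndarray, k: int) -> np.ndarray:
    """Dense eigendecomposition of the double-centered squared distances."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    out = np.zeros((n, k))
    for c, idx in enumerate(order):
        if vals[idx] > 1e-12 * max(vals.max(), 1.0):
            out[:, c] = vecs[:, idx] * np.sqrt(vals[idx])
    return out


def haplotype_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Classic D^2 / (p1 q1 p2 q2) from phased haplotype indicators."""
    pa, pb = hap_a.mean(), hap_b.mean()
    d = (hap_a * hap_b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def student_t_equal_var(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1)) + ((ny - 1) * y.var(ddof=1))) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return float(t), float(p)
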