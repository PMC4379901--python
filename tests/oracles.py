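"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive the expected behavior from first principles
(per-block formulas, exhaustive search) and never call the package code
they check.
"""

from __future__ import annotations

import numpy as np


def block_analyze_oracle(x: np.ndarray):
    """Per-block evaluation of the morphological analysis formulas."""
    rows, cols = x.shape
    assert rows % 2 == 0 and cols % 2 == 0
    m = np.empty((rows // 2, cols // 2))
    yv = np.empty_like(m)
    yh = np.empty_like(m)
    yd = np.empty_like(m)
    for bi in range(rows // 2):
        for bj in range(cols // 2):
            r, c = 2 * bi, 2 * bj
            block_max = max(x[r, c], x[r, c + 1], x[r + 1, c], x[r + 1, c + 1])
            m[bi, bj] = block_max
            yv[bi, bj] = abs(block_max - x[r, c + 1])
            yh[bi, bj] = abs(block_max - x[r + 1, c])
            yd[bi, bj] = abs(block_max - x[r + 1, c + 1])
    return m, yv, yh, yd


def block_synthesize_oracle(m, yv, yh, yd) -> np.ndarray:
    """Per-block evaluation of the morphological synthesis formulas."""
    rows, cols = m.shape
    out = np.empty((2 * rows, 2 * cols))
    for bi in range(rows):
        for bj in range(cols):
            r, c = 2 * bi, 2 * bj
            mm = m[bi, bj]
            out[r, c] = mm + min(yv[bi, bj], yh[bi, bj], yd[bi, bj], 0.0)
            out[r, c + 1] = mm + min(-yv[bi, bj], 0.0)
            out[r + 1, c] = mm + min(-yh[bi, bj], 0.0)
            out[r + 1, c + 1] = mm + min(-yd[bi, bj], 0.0)
    return out


def bh_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg by literal definition: k* = max{k: p(k) <= kq/m}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def min_sliding_dist_oracle(candidate, series) -> float:
    """Minimum Euclidean distance of a subsequence over all alignments."""
    length = len(candidate)
    best = np.inf
    for start in range(len(series) - length + 1):
        d = np.sqrt(((series[start : start + length] - candidate) ** 2).sum())
        best = min(best, d)
    return best


def _entropy_bits(labels) -> float:
    labels = np.asarray(labels)
    h = 0.0
    n = len(labels)
    for cls in np.unique(labels):
        p = (labels == cls).sum() / n
        h -= p * np.log2(p)
    return h


def shapelet_oracle(series, labels, lmin, lmax):
    """Exhaustive shapelet search by definition; returns best info gain.

    Only the achieved information gain is compared (several candidates may
    tie at the same gain with different tie-break outcomes).
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels)
    n, t = series.shape
    h_parent = _entropy_bits(labels)
    best_gain = 0.0
    for length in range(lmin, lmax + 1):
        for s_idx in range(n):
            for start in range(t - length + 1):
                cand = series[s_idx, start : start + length]
                dists = np.array(
                    [min_sliding_dist_oracle(cand, series[j]) for j in range(n)]
                )
                order = np.argsort(dists, kind="stable")
                d_sorted = dists[order]
                lab_sorted = labels[order]
                for j in range(n - 1):
                    if d_sorted[j + 1] == d_sorted[j]:
                        continue
                    left = lab_sorted[: j + 1]
                    right = lab_sorted[j + 1 :]
                    gain = h_parent - (
                        len(left) * _entropy_bits(left)
                        + len(right) * _entropy_bits(right)
                    ) / n
                    best_gain = max(best_gain, gain)
    return best_gain
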