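"""Independent brute-force oracles used by the test suite.

Kept deliberately naive and separate from the package implementation:
interval searches enumerate all O(n^2) intervals with sequential Python
sums, and hypergeometric weights are exact integers from factorials.
"""

from __future__ import annotations

import math


def brute_force_intervals(
    x, sigma: float, threshold: float
) -> list[tuple[int, int]]:
    """All disjoint maximal-|S| intervals with |S| >= threshold.

    Repeatedly scans every interval inside the not-yet-claimed segments,
    takes the best (ties: leftmost start, then shortest), and claims it.
    """
    x = [float(v) for v in x]
    free = [(0, len(x) - 1)]
    found: list[tuple[int, int]] = []
    while True:
        best_val = None
        best = None
        best_seg = None
        free.sort()  # scan segments left to right so ties resolve leftmost
        for seg_idx, (lo, hi) in enumerate(free):
            for i in range(lo, hi + 1):
                s = 0.0
                for j in range(i, hi + 1):
                    s += x[j]
                    val = abs(s) / (sigma * math.sqrt(j - i + 1))
                    if best_val is None or val > best_val:
                        best_val, best, best_seg = val, (i, j), seg_idx
        if best_val is None or best_val < threshold:
            break
        found.append(best)
        lo, hi = free.pop(best_seg)
        i, j = best
        if i > lo:
            free.append((lo, i - 1))
        if j < hi:
            free.append((j + 1, hi))
        if not free:
            break
    return sorted(found)


def fisher_pvalues_exact(total: int, row1: int, col1: int):
    """Exact two-sided Fisher p for every feasible top-left cell, via
    factorial-based integer hypergeometric weights."""
    f = [math.factorial(i) for i in range(total + 1)]

    def choose(n: int, k: int) -> int:
        return f[n] // (f[k] * f[n - k])

    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    nums = [choose(col1, a) * choose(total - col1, row1 - a)
            for a in range(lo, hi + 1)]
    denom = choose(total, row1)
    pvals = []
    for a in range(len(nums)):
        pvals.append(sum(n for n in nums if n <= nums[a]) / denom)
    return list(range(lo, hi + 1)), pvals
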