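"""Maximal-scoring-interval segmentation of corrected log2-ratio profiles.

A candidate interval I of member probes x_1..x_k scores

    S(I) = (sum x_i) / (sigma * sqrt(k))

with sigma the sample's noise SD (by default its DLRS).  Detection extracts
disjoint, per-chromosome maximal intervals with |S| >= threshold by greedy
search: find the best-scoring interval, record it, and recurse into the
flanking remainders.  Ties are broken by leftmost start, then shortest
length.  Threshold 6 is the package default, matching the score cut-off at
which commercial aberration-detection pipelines are typically run.

A deterministic "visual rescue" pass emulates the whole-genome manual
review used alongside the software call: runs of >= 2 consecutive probes
all above +0.5 (gain) or all below -1.0 (loss) that the score threshold
missed are added as calls with ``source="visual"``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .design import ProbeDesign

DEFAULT_THRESHOLD = 6.0
VISUAL_GAIN = 0.5
VISUAL_LOSS = -1.0
VISUAL_MIN_RUN = 2

CALL_COLUMNS = [
    "sample_id", "chrom", "probe_lo", "probe_hi",
    "inner_start", "inner_end", "outer_start", "outer_end",
    "type", "probe_count", "score", "mean_ratio", "malr", "source",
]


def interval_score(values: np.ndarray, sigma: float) -> float:
    """Score of one interval: sum / (sigma * sqrt(probe count))."""
    values = np.asarray(values, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if values.size == 0:
        raise ValueError("interval must be non-empty")
    return float(values.sum() / (sigma * math.sqrt(values.size)))


def _best_interval(x: np.ndarray, sigma: float) -> tuple[int, int, float]:
    """Interval (i, j) of ``x`` maximising |S|; ties -> leftmost, shortest.

    Runs in O(m^2) time but O(m) memory by sweeping interval lengths.
    """
    m = len(x)
    c = np.empty(m + 1)
    c[0] = 0.0
    np.cumsum(x, out=c[1:])
    best_val = -1.0
    best_i = best_k = 0
    for k in range(1, m + 1):
        s = (c[k:] - c[: m - k + 1]) / (sigma * math.sqrt(k))
        np.abs(s, out=s)
        i = int(np.argmax(s))
        v = float(s[i])
        if v > best_val or (v == best_val and i < best_i):
            best_val, best_i, best_k = v, i, k
    return best_i, best_i + best_k - 1, best_val


def _greedy_segments(
    x: np.ndarray, sigma: float, threshold: float
) -> list[tuple[int, int]]:
    """Disjoint maximal intervals with |S| >= threshold within one block."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x) - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi < lo:
            continue
        i, j, val = _best_interval(x[lo : hi + 1], sigma)
        if val < threshold:
            continue
        out.append((lo + i, lo + j))
        stack.append((lo, lo + i - 1))
        stack.append((lo + j + 1, hi))
    return sorted(out)


def _call_row(
    design: ProbeDesign,
    ratios: np.ndarray,
    sample_id: str,
    chrom: str,
    block_lo: int,
    block_hi: int,
    lo: int,
    hi: int,
    sigma: float,
    source: str,
) -> dict:
    starts = design.starts
    ends = design.ends
    member = ratios[lo : hi + 1]
    total = float(member.sum())
    k = hi - lo + 1
    # outer boundaries: the flanking normal probes; the true breakpoint lies
    # between outer and inner.  At chromosome ends the outer collapses onto
    # the inner boundary.
    outer_start = int(ends[lo - 1]) if lo > block_lo else int(starts[lo])
    outer_end = int(starts[hi + 1]) if hi < block_hi else int(ends[hi])
    return {
        "sample_id": sample_id,
        "chrom": chrom,
        "probe_lo": lo,
        "probe_hi": hi,
        "inner_start": int(starts[lo]),
        "inner_end": int(ends[hi]),
        "outer_start": outer_start,
        "outer_end": outer_end,
        "type": "gain" if total > 0 else "loss",
        "probe_count": k,
        "score": total / (sigma * math.sqrt(k)),
        "mean_ratio": total / k,
        "malr": float(np.abs(member).mean()),
        "source": source,
    }


def detect_aberrations(
    design: ProbeDesign,
    ratios: np.ndarray,
    sigma: float,
    threshold: float = DEFAULT_THRESHOLD,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Greedy per-chromosome maximal-interval detection at |S| >= threshold.

    ``sigma`` is normally the sample's DLRS.  The profile is expected to be
    centralized and GC-corrected.  Returns one row per call (see
    ``CALL_COLUMNS``); an empty frame on a null profile.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (design.n_probes,):
        raise ValueError("ratio vector does not match design probe count")
    rows = []
    for chrom, lo, hi in design.chrom_blocks():
        for i, j in _greedy_segments(ratios[lo : hi + 1], sigma, threshold):
            rows.append(
                _call_row(design, ratios, sample_id, chrom, lo, hi,
                          lo + i, lo + j, sigma, "software")
            )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.sort_values(["chrom", "probe_lo"], key=_sort_key).reset_index(drop=True)


def _sort_key(col: pd.Series) -> pd.Series:
    from .design import chrom_sort_key

    if col.name == "chrom":
        return col.map(lambda c: tuple(chrom_sort_key(c)))
    return col


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as (lo, hi) inclusive."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def visual_rescue(
    design: ProbeDesign,
    ratios: np.ndarray,
    calls: pd.DataFrame,
    sigma: float,
    sample_id: str = "sample",
    gain_threshold: float = VISUAL_GAIN,
    loss_threshold: float = VISUAL_LOSS,
    min_run: int = VISUAL_MIN_RUN,
) -> pd.DataFrame:
    """Deterministic emulation of the manual whole-genome review.

    Flags runs of >= ``min_run`` consecutive probes all above
    ``gain_threshold`` or all below ``loss_threshold`` whose probes are not
    already covered by a software call, and appends them with
    ``source="visual"``.  This is an approximation of an inherently human
    step; visual calls stay distinguishable downstream.
    """
    ratios = np.asarray(ratios, dtype=float)
    called = np.zeros(design.n_probes, dtype=bool)
    for _, row in calls.iterrows():
        called[row["probe_lo"] : row["probe_hi"] + 1] = True
    rows = []
    for chrom, lo, hi in design.chrom_blocks():
        block = ratios[lo : hi + 1]
        for mask in (block > gain_threshold, block < loss_threshold):
            for i, j in _runs(mask):
                if j - i + 1 < min_run:
                    continue
                if called[lo + i : lo + j + 1].any():
                    continue
                rows.append(
                    _call_row(design, ratios, sample_id, chrom, lo, hi,
                              lo + i, lo + j, sigma, "visual")
                )
    if not rows:
        return calls.reset_index(drop=True)
    extra = pd.DataFrame(rows, columns=CALL_COLUMNS)
    frames = [f for f in (calls, extra) if len(f)]
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "probe_lo"], key=_sort_key).reset_index(drop=True)
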