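"""Population-database consistency matching, frequency classes and
case/control frequency tests.

A detected CNV is *consistent* with a database record (or with another
call) when both are of the same kind (gain/loss), the overlap covers at
least 80% of the query interval, and the two intervals differ by at most
two probes on either side, counted on the array design.  When the query's
probe-level ratios are available, query-side differing probes only count
if their |log2 ratio| reaches the compatibility threshold (0.3 by
default) -- a quiet flanking probe is noise, not evidence of a distinct
event.

Frequency classes follow the two bands used for population CNVs: common
above 5%, rare at 1% or below (non-zero); the band in between is labelled
intermediate.  Calls with no database match are novel.

Case/control frequency differences are tested with Fisher's exact test,
or with the chi-square test with Yates continuity correction when all
expected cell counts reach 5.  Fisher p-values are computed exactly from
integer hypergeometric weights, so they are reproducible to full printed
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .design import ProbeDesign

OVERLAP_MIN = 0.80
MAX_PROBE_DIFF = 2
COMPAT_RATIO = 0.3
FREQ_COMMON = 0.05
FREQ_RARE = 0.01

DB_COLUMNS = ["chrom", "start", "end", "type", "carriers", "cohort",
              "frequency", "source"]


# ---------------------------------------------------------------------------
# interval consistency

def intervals_consistent(
    design: ProbeDesign,
    chrom: str,
    a: tuple[int, int],
    b: tuple[int, int],
    type_a: str,
    type_b: str,
    ratios_a: np.ndarray | None = None,
    ratios_b: np.ndarray | None = None,
    overlap_min: float = OVERLAP_MIN,
    max_probe_diff: int = MAX_PROBE_DIFF,
    compat_ratio: float = COMPAT_RATIO,
    reciprocal: bool = False,
) -> bool:
    """Consistency rule between interval ``a`` (the query) and ``b``.

    Intervals are 1-based closed on the same chromosome.  ``ratios_a``/``b``
    are optional full-length profile vectors used to gate that side's
    differing probes by |log2 ratio| >= ``compat_ratio``; when no profile is
    known for a side (a database record), all of its differing probes count.
    """
    if type_a != type_b:
        return False
    (sa, ea), (sb, eb) = a, b
    overlap = min(ea, eb) - max(sa, sb) + 1
    if overlap <= 0:
        return False
    if overlap / (ea - sa + 1) < overlap_min:
        return False
    if reciprocal and overlap / (eb - sb + 1) < overlap_min:
        return False
    pa = set(design.probes_in(chrom, sa, ea).tolist())
    pb = set(design.probes_in(chrom, sb, eb).tolist())

    def n_diff(only: set[int], ratios: np.ndarray | None) -> int:
        if ratios is None:
            return len(only)
        return sum(1 for i in only if abs(ratios[i]) >= compat_ratio)

    if n_diff(pa - pb, ratios_a) > max_probe_diff:
        return False
    if n_diff(pb - pa, ratios_b) > max_probe_diff:
        return False
    return True


def calls_consistent(
    design: ProbeDesign,
    call_a: pd.Series,
    call_b: pd.Series,
    ratios_a: np.ndarray | None = None,
    ratios_b: np.ndarray | None = None,
    **kwargs,
) -> bool:
    """Consistency between two calls, on their inner (probe-backed) intervals."""
    if call_a["chrom"] != call_b["chrom"]:
        return False
    return intervals_consistent(
        design,
        call_a["chrom"],
        (call_a["inner_start"], call_a["inner_end"]),
        (call_b["inner_start"], call_b["inner_end"]),
        call_a["type"],
        call_b["type"],
        ratios_a=ratios_a,
        ratios_b=ratios_b,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# matching and frequency classes

@dataclass
class MatchResult:
    """Database lookup outcome for one call."""

    matched: pd.DataFrame  # matching database rows
    frequency_class: str  # common | intermediate | rare | novel
    best_frequency: float | None  # highest matched (non-zero) frequency
    source_frequency: dict[str, float]  # best matched frequency per source


def frequency_class(
    frequencies,
    common: float = FREQ_COMMON,
    rare: float = FREQ_RARE,
) -> str:
    """Band of the best (highest) matched population frequency.

    Zero-frequency records carry no population evidence and are ignored; a
    call matching nothing (or only zero-frequency records) is novel.
    """
    freqs = [f for f in frequencies if f > 0]
    if not freqs:
        return "novel"
    best = max(freqs)
    if best > common:
        return "common"
    if best <= rare:
        return "rare"
    return "intermediate"


def match(
    design: ProbeDesign,
    call: pd.Series,
    db: pd.DataFrame,
    ratios: np.ndarray | None = None,
    overlap_min: float = OVERLAP_MIN,
    max_probe_diff: int = MAX_PROBE_DIFF,
    compat_ratio: float = COMPAT_RATIO,
    reciprocal: bool = False,
    common: float = FREQ_COMMON,
    rare: float = FREQ_RARE,
) -> MatchResult:
    """Match one curated call against population-database entries."""
    known = {c for c, _, _ in design.chrom_blocks()}
    hits = []
    for idx, entry in db.iterrows():
        if entry["chrom"] != call["chrom"]:
            continue
        if entry["chrom"] not in known:
            import warnings

            warnings.warn(f"database entry on unknown chromosome {entry['chrom']!r}")
            continue
        if intervals_consistent(
            design,
            call["chrom"],
            (call["inner_start"], call["inner_end"]),
            (entry["start"], entry["end"]),
            call["type"],
            entry["type"],
            ratios_a=ratios,
            overlap_min=overlap_min,
            max_probe_diff=max_probe_diff,
            compat_ratio=compat_ratio,
            reciprocal=reciprocal,
        ):
            hits.append(idx)
    matched = db.loc[hits]
    fclass = frequency_class(matched["frequency"], common, rare)
    nonzero = matched.loc[matched["frequency"] > 0]
    best = float(nonzero["frequency"].max()) if len(nonzero) else None
    per_source = {
        src: float(grp["frequency"].max())
        for src, grp in nonzero.groupby("source")
    }
    return MatchResult(matched=matched, frequency_class=fclass,
                       best_frequency=best, source_frequency=per_source)


# ---------------------------------------------------------------------------
# frequency tests

def fisher_pvalues(total: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p-values for every table with the given margins.

    Returns ``(support, pvalues)`` where ``support`` enumerates the feasible
    top-left cell a.  p(a) sums the hypergeometric probabilities of all
    tables no more probable than the observed one; weights are exact
    integers, so ties are handled without floating-point guards.
    """
    if not (0 <= row1 <= total and 0 <= col1 <= total):
        raise ValueError("invalid margins")
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    nums = [comb(col1, a) * comb(total - col1, row1 - a) for a in support]
    denom = comb(total, row1)
    order = sorted(range(len(nums)), key=nums.__getitem__)
    csum = 0
    cum = [0] * len(nums)
    pos = 0
    while pos < len(order):
        # advance over ties so equal weights share a cumulative sum
        tie_end = pos
        while tie_end + 1 < len(order) and nums[order[tie_end + 1]] == nums[order[pos]]:
            tie_end += 1
        for q in range(pos, tie_end + 1):
            csum += nums[order[q]]
        for q in range(pos, tie_end + 1):
            cum[order[q]] = csum
        pos = tie_end + 1
    p = np.array([c / denom for c in cum], dtype=float)
    return support, p


def fisher_exact_pvalue(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table ``[[a, b], [c, d]]``."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty table")
    support, p = fisher_pvalues(total, a + b, a + c)
    return float(p[int(a) - support[0]])


def odds_ratio(table) -> tuple[float, bool]:
    """Sample odds ratio; Haldane 0.5 correction (flagged) on a zero cell."""
    (a, b), (c, d) = (float(x) for x in table[0]), (float(x) for x in table[1])
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def frequency_test(
    case_carriers: int,
    case_total: int,
    control_carriers: int,
    control_total: int,
) -> dict:
    """Compare carrier frequencies between two cohorts.

    Fisher's exact test by default; chi-square with Yates continuity
    correction when all expected cell counts reach 5.  Returns a dict with
    ``odds_ratio``, ``p_value``, ``method`` and ``or_corrected`` (True when
    the Haldane correction was needed).
    """
    if case_total <= 0 and control_total <= 0:
        raise ValueError("both cohorts empty")
    if case_total <= 0 or control_total <= 0:
        raise ValueError("cohort totals must be positive")
    if not (0 <= case_carriers <= case_total and 0 <= control_carriers <= control_total):
        raise ValueError("carrier counts out of range")
    table = np.array(
        [[case_carriers, case_total - case_carriers],
         [control_carriers, control_total - control_carriers]]
    )
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        method = "chi2_yates"
    else:
        p = fisher_exact_pvalue(table)
        method = "fisher"
    or_, flagged = odds_ratio(table)
    return {
        "odds_ratio": float(or_),
        "p_value": float(min(p, 1.0)),
        "method": method,
        "or_corrected": flagged,
    }


def cohort_frequency_report(
    design: ProbeDesign,
    variants: pd.DataFrame,
    db: pd.DataFrame,
    n_samples: int,
    overlap_min: float = OVERLAP_MIN,
    max_probe_diff: int = MAX_PROBE_DIFF,
) -> pd.DataFrame:
    """Per-variant sample frequency versus each database source.

    ``variants`` needs columns chrom/inner_start/inner_end/type plus
    ``carriers`` (number of cohort samples sharing the consistent variant).
    A source with no consistent record yields NaN frequency and no test
    for that row, not an error.
    """
    sources = sorted(db["source"].unique()) if len(db) else []
    rows = []
    for _, v in variants.iterrows():
        row: dict = {
            "chrom": v["chrom"],
            "start": int(v["inner_start"]),
            "end": int(v["inner_end"]),
            "type": v["type"],
            "carriers": int(v["carriers"]),
            "sample_frequency": v["carriers"] / n_samples,
        }
        for src in sources:
            sub = db.loc[db["source"] == src]
            m = match(design, v, sub, overlap_min=overlap_min,
                      max_probe_diff=max_probe_diff)
            if len(m.matched) == 0:
                row[f"{src}_frequency"] = np.nan
                row[f"{src}_p"] = np.nan
                row[f"{src}_method"] = "not_tested"
                continue
            best = m.matched.sort_values("frequency", ascending=False).iloc[0]
            res = frequency_test(int(v["carriers"]), n_samples,
                                 int(best["carriers"]), int(best["cohort"]))
            row[f"{src}_frequency"] = float(best["frequency"])
            row[f"{src}_p"] = res["p_value"]
            row[f"{src}_method"] = res["method"]
            row[f"{src}_odds_ratio"] = res["odds_ratio"]
        rows.append(row)
    return pd.DataFrame(rows)
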