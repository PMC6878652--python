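"""Post-detection call curation: amplitude/probe-count filters, split/merge
of nearby intervals, visual triage bands, replicate concordance and cohort
recurrence.

Software calls are retained only with at least 2 consecutive probes and a
mean absolute log2 ratio (MALR) strictly above 0.30; calls added by the
visual-review pass are exempt from the MALR filter.  Nearby same-type
intervals are a single CNV when separated by at most 2 intervening probes
none of which opposes the call's sign at |log2| > 0.3; a wider gap, or an
opposing intervening signal, keeps them separate events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ProbeDesign
from .popdb import calls_consistent
from .segment import CALL_COLUMNS, _call_row
from .simulate import SampleProfile

MALR_MIN = 0.30
MIN_PROBES = 2
MAX_GAP_PROBES = 2
OPPOSE_RATIO = 0.3
TREND_MIN = 0.15  # replicate trend threshold: half the MALR filter


@dataclass(frozen=True)
class TriageBands:
    """Thresholds of the deterministic visual-triage emulation.

    ``likely``: amplitude the manual review pays attention to (gain mean
    above +0.5 or loss mean below -1.0).  ``unlikely``: low-amplitude or
    minimal two-probe calls.  Everything else is ``possible``.  Triage only
    labels calls; it never removes them.
    """

    likely_gain: float = 0.5
    likely_loss: float = -1.0
    unlikely_malr: float = 0.35
    unlikely_two_probe_mean: float = 0.4


def filter_calls(
    calls: pd.DataFrame,
    malr_min: float = MALR_MIN,
    min_probes: int = MIN_PROBES,
) -> pd.DataFrame:
    """Pure retention filter: >= min_probes probes, and MALR > malr_min
    (strict) for software calls; visual calls bypass the MALR rule."""
    keep = (calls["probe_count"] >= min_probes) & (
        (calls["malr"] > malr_min) | (calls["source"] == "visual")
    )
    return calls.loc[keep].reset_index(drop=True)


def split_merge(
    calls: pd.DataFrame,
    design: ProbeDesign,
    ratios: np.ndarray,
    sigma: float,
    max_gap_probes: int = MAX_GAP_PROBES,
    oppose_ratio: float = OPPOSE_RATIO,
) -> pd.DataFrame:
    """Merge nearby same-type calls of one sample; keep distinct events apart.

    Adjacent same-type calls separated by <= ``max_gap_probes`` intervening
    probes are merged unless any intervening probe opposes the call sign at
    |log2| > ``oppose_ratio``.  Overlapping opposite-type calls violate the
    segmentation contract and raise.  Idempotent.
    """
    if len(calls) == 0:
        return calls.copy()
    ratios = np.asarray(ratios, dtype=float)
    df = calls.sort_values(["chrom", "probe_lo"], kind="stable").reset_index(drop=True)
    blocks = {c: (lo, hi) for c, lo, hi in design.chrom_blocks()}
    rows = [df.iloc[0].to_dict()]
    for _, cur in df.iloc[1:].iterrows():
        prev = rows[-1]
        if cur["chrom"] == prev["chrom"] and cur["probe_lo"] <= prev["probe_hi"]:
            if cur["type"] != prev["type"]:
                raise ValueError("overlapping same-sample calls of opposite type")
        gap = cur["probe_lo"] - prev["probe_hi"] - 1
        mergeable = (
            cur["chrom"] == prev["chrom"]
            and cur["type"] == prev["type"]
            and 0 <= gap <= max_gap_probes
        )
        if mergeable and gap > 0:
            between = ratios[prev["probe_hi"] + 1 : cur["probe_lo"]]
            sign = 1.0 if cur["type"] == "gain" else -1.0
            if np.any(sign * between < -oppose_ratio):
                mergeable = False
        if mergeable:
            lo, hi = prev["probe_lo"], cur["probe_hi"]
            block_lo, block_hi = blocks[cur["chrom"]]
            source = "visual" if prev["source"] == cur["source"] == "visual" else "software"
            merged = _call_row(design, ratios, cur["sample_id"], cur["chrom"],
                               block_lo, block_hi, lo, hi, sigma, source)
            rows[-1] = merged
        else:
            rows.append(cur.to_dict())
    return pd.DataFrame(rows, columns=CALL_COLUMNS).reset_index(drop=True)


def triage(calls: pd.DataFrame, bands: TriageBands = TriageBands()) -> pd.DataFrame:
    """Label each call likely / possible / unlikely.  Adds a ``triage`` column."""
    labels = []
    for _, c in calls.iterrows():
        mean = c["mean_ratio"]
        if (c["type"] == "gain" and mean >= bands.likely_gain) or (
            c["type"] == "loss" and mean <= bands.likely_loss
        ):
            labels.append("likely")
        elif c["malr"] <= bands.unlikely_malr or (
            c["probe_count"] == 2 and abs(mean) < bands.unlikely_two_probe_mean
        ):
            labels.append("unlikely")
        else:
            labels.append("possible")
    out = calls.copy()
    out["triage"] = labels
    return out


def replicate_concordance(
    design: ProbeDesign,
    call: pd.Series,
    replicate_calls: list[pd.DataFrame],
    replicate_ratios: list[np.ndarray],
    trend_min: float = TREND_MIN,
    **consistency_kwargs,
) -> str:
    """Concordance of one call across the sample's replicate arrays.

    - ``not_evaluable``: no replicate exists.
    - ``confirmed``: some replicate holds a consistent call (same rule as
      database matching).
    - ``not_excluded``: no consistent call, but some replicate trends the
      same way over the call's probes (matching mean sign, |mean| > trend_min).
    - ``not_confirmed`` otherwise.
    """
    if not replicate_calls:
        return "not_evaluable"
    lo, hi = int(call["probe_lo"]), int(call["probe_hi"])
    sign = 1.0 if call["type"] == "gain" else -1.0
    trend = False
    for rep_calls, rep_ratios in zip(replicate_calls, replicate_ratios):
        for _, other in rep_calls.iterrows():
            if calls_consistent(design, call, other, **consistency_kwargs):
                return "confirmed"
        mean = float(np.asarray(rep_ratios)[lo : hi + 1].mean())
        if sign * mean > trend_min:
            trend = True
    return "not_excluded" if trend else "not_confirmed"


def compute_recurrence(design: ProbeDesign, calls: pd.DataFrame) -> pd.Series:
    """Number of distinct cohort samples sharing each call's consistent variant
    (always counts the call's own sample)."""
    counts = []
    for i, call in calls.iterrows():
        samples = {call["sample_id"]}
        for j, other in calls.iterrows():
            if i == j or other["sample_id"] in samples:
                continue
            if calls_consistent(design, call, other):
                samples.add(other["sample_id"])
        counts.append(len(samples))
    return pd.Series(counts, index=calls.index, name="recurrence")


def curate_sample(
    design: ProbeDesign,
    calls: pd.DataFrame,
    ratios: np.ndarray,
    sigma: float,
    malr_min: float = MALR_MIN,
    min_probes: int = MIN_PROBES,
    max_gap_probes: int = MAX_GAP_PROBES,
    oppose_ratio: float = OPPOSE_RATIO,
    bands: TriageBands = TriageBands(),
) -> pd.DataFrame:
    """Full single-sample curation: split/merge, filter, triage."""
    merged = split_merge(calls, design, ratios, sigma, max_gap_probes, oppose_ratio)
    kept = filter_calls(merged, malr_min, min_probes)
    return triage(kept, bands)
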