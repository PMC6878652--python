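"""Per-sample noise estimation (DLRS), centralization, GC correction and the
replication gate.

DLRS (derivative log ratio spread) is the robust per-probe noise estimate
used throughout array-CGH QC: the IQR of consecutive-probe log2-ratio
differences, scaled by 1.349*sqrt(2) so that it estimates the per-probe
noise SD under i.i.d. Gaussian noise.  Differences are never taken across
chromosome boundaries.  Samples at DLRS >= 0.3 (boundary inclusive) are
flagged for replication on another array.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .design import ProbeDesign
from .simulate import SampleProfile

_DLRS_SCALE = 1.349 * math.sqrt(2.0)
DLRS_GATE = 0.3


def compute_dlrs(design: ProbeDesign, ratios: np.ndarray) -> float:
    """Robust per-probe noise SD from within-chromosome consecutive differences.

    Requires at least 3 probes; a constant profile or a strict linear ramp
    gives 0.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (design.n_probes,):
        raise ValueError("ratio vector does not match design probe count")
    if design.n_probes < 3:
        raise ValueError("DLRS undefined for fewer than 3 probes")
    diffs = [
        np.diff(ratios[lo : hi + 1])
        for _, lo, hi in design.chrom_blocks()
        if hi > lo
    ]
    if not diffs:
        raise ValueError("no within-chromosome consecutive probe pairs")
    d = np.concatenate(diffs)
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / _DLRS_SCALE)


def qc_gate(dlrs: float, gate: float = DLRS_GATE) -> str:
    """``replicate_required`` iff DLRS >= gate (inclusive), else ``pass``."""
    if dlrs < 0:
        raise ValueError("DLRS must be non-negative")
    return "replicate_required" if dlrs >= gate else "pass"


def centralize(ratios: np.ndarray) -> np.ndarray:
    """Shift the profile so its median log2 ratio is 0.  Idempotent."""
    ratios = np.asarray(ratios, dtype=float)
    return ratios - np.median(ratios)


def gc_correct(
    ratios: np.ndarray, gc: np.ndarray
) -> tuple[np.ndarray, float]:
    """Subtract a least-squares linear fit of ratio on centred GC fraction.

    Returns the corrected vector and the fitted slope.  Constant GC across
    probes makes the fit degenerate: the profile is returned unchanged with
    a warning.
    """
    ratios = np.asarray(ratios, dtype=float)
    gc = np.asarray(gc, dtype=float)
    x = gc - gc.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        warnings.warn("constant GC fraction: GC correction is a no-op")
        return ratios.copy(), 0.0
    slope = float(np.dot(x, ratios) / denom)
    return ratios - slope * x, slope


def preprocess(
    design: ProbeDesign,
    profile: SampleProfile,
    apply_gc: bool = True,
    dlrs_gate: float = DLRS_GATE,
) -> SampleProfile:
    """Centralize, GC-correct, and annotate DLRS and the QC flag in place.

    The DLRS gate is applied to the corrected profile (the corrections only
    remove systematic trend, so the noise estimate is essentially unchanged).
    """
    ratios = centralize(profile.ratios)
    if apply_gc:
        ratios, _ = gc_correct(ratios, design.gc)
        ratios = centralize(ratios)
    profile.ratios = ratios
    profile.dlrs = compute_dlrs(design, ratios)
    profile.qc_flag = qc_gate(profile.dlrs, dlrs_gate)
    return profile
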