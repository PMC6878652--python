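"""Parental origin of validated CNVs and the maternal-transmission test.

Origin assignment is purely CNV-consistency based: a parent transmits a
child's variant when the parent's own profile yields a consistent call
(same rule as database matching).  No SNP phasing or haplotype inference
is attempted.

The transmission bias among inherited CNVs is tested with a one-sided
exact binomial test against p = 0.5 (are mothers over-represented among
transmitting parents?), with a two-sided 95% Clopper-Pearson interval for
the maternal proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .design import ProbeDesign
from .popdb import calls_consistent


@dataclass(frozen=True)
class OriginCall:
    """Parental-origin resolution for one variant."""

    variant_id: str
    origin: str  # maternal | paternal | de_novo | unknown | ambiguous
    mother_evidence: str  # consistent | negative | unavailable
    father_evidence: str


@dataclass(frozen=True)
class TransmissionTest:
    """Exact binomial test of the maternal share among inherited CNVs."""

    n_inherited: int
    n_maternal: int
    p_value: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    sided: str = "one"


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for a proportion.

    Closed-form edges: k = n gives low = (alpha/2)^(1/n), high = 1;
    k = 0 gives low = 0, high = 1 - (alpha/2)^(1/n).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    low = float(stats.beta.ppf(alpha / 2, k, n - k + 1)) if k > 0 else 0.0
    high = float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k)) if k < n else 1.0
    return low, high


def binomial_bias_test(
    n_maternal: int,
    n_inherited: int,
    p0: float = 0.5,
    sided: str = "one",
    alpha: float = 0.05,
) -> TransmissionTest:
    """Exact binomial test of maternal transmission among inherited CNVs.

    One-sided by default: P(X >= n_maternal | n_inherited, p0), the upper
    tail (0.5^n when every inherited CNV is maternal).  A two-sided option
    doubles the smaller tail in the usual minlike sense.
    """
    if n_inherited < 1:
        raise ValueError("transmission test undefined with no inherited CNVs")
    if not 0 <= n_maternal <= n_inherited:
        raise ValueError("n_maternal out of range")
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    p = float(stats.binomtest(n_maternal, n_inherited, p0,
                              alternative=alternative).pvalue)
    low, high = clopper_pearson(n_maternal, n_inherited, alpha)
    return TransmissionTest(
        n_inherited=n_inherited,
        n_maternal=n_maternal,
        p_value=p,
        ci_low=low,
        ci_high=high,
        alpha=alpha,
        sided=sided,
    )


def assign_origin(
    design: ProbeDesign,
    call: pd.Series,
    mother_calls: pd.DataFrame | None,
    father_calls: pd.DataFrame | None,
    variant_id: str | None = None,
    **consistency_kwargs,
) -> OriginCall:
    """Resolve one child variant against the parents' call sets.

    ``None`` marks a parent as unavailable (not tested); an empty frame is
    a tested-negative parent.  Exactly one positive parent gives that
    origin; two tested-negative parents give de novo; a positive in both
    parents is surfaced as ``ambiguous`` rather than silently resolved;
    anything needing an unavailable parent is ``unknown``.
    """

    def evidence(parent: pd.DataFrame | None) -> str:
        if parent is None:
            return "unavailable"
        for _, other in parent.iterrows():
            if calls_consistent(design, call, other, **consistency_kwargs):
                return "consistent"
        return "negative"

    mo, fa = evidence(mother_calls), evidence(father_calls)
    if mo == "consistent" and fa == "consistent":
        origin = "ambiguous"
    elif mo == "consistent":
        origin = "maternal"
    elif fa == "consistent":
        origin = "paternal"
    elif mo == "negative" and fa == "negative":
        origin = "de_novo"
    else:
        origin = "unknown"
    vid = variant_id if variant_id is not None else str(call.get("variant_id", ""))
    return OriginCall(variant_id=vid, origin=origin,
                      mother_evidence=mo, father_evidence=fa)
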