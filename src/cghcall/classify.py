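"""'True variant' classification, validation bookkeeping and cohort summary.

A variant is *true* when at least one evidence channel supports it: it is
reported in a population database (at any non-zero frequency), it was
confirmed on a second array replicate, or it was validated with an
orthogonal assay (qPCR, PCR or a higher-density array -- validation
outcomes enter the pipeline as labels, the chemistry is out of scope).

Novelty is counted separately: a variant is ``on_dgv`` only when its
database match is above the rare band; a variant matched only at very low
frequency (<= 1%) is still true via the database channel but counts among
the novel ("not reported") variants in the stratified summary, mirroring
how very rare database hits are conventionally tabulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PATIENT_COLUMNS = ["sample_id", "sex", "hscr_form", "syndromic", "ret_status",
                   "haplotype"]

RET_ANOMALY = {"mutation", "deletion"}


def classify_truth(
    frequency_class: str,
    dgv_class: str,
    replicate_status: str,
    validation_outcome: str,
) -> tuple[bool, str]:
    """Resolve the three evidence channels into ``(is_true, novelty)``.

    ``frequency_class`` is the overall band across reported sources,
    ``dgv_class`` the band restricted to DGV-like sources (both ``novel``
    when unmatched).  Adding evidence can only turn a variant true, never
    falsify it.
    """
    db_true = frequency_class in ("common", "intermediate", "rare")
    is_true = (
        db_true
        or replicate_status == "confirmed"
        or validation_outcome == "validated"
    )
    novelty = "on_dgv" if dgv_class in ("common", "intermediate") else "novel"
    return is_true, novelty


def annotate_truth(variants: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify_truth` over a variant table.

    Expects columns ``frequency_class``, ``dgv_class``, ``replicate_status``
    and ``validation_outcome`` (missing ones default to no evidence), and
    adds ``is_true`` and ``novelty``.
    """
    df = variants.copy()
    for col, default in (
        ("frequency_class", "novel"),
        ("dgv_class", "novel"),
        ("replicate_status", "not_evaluable"),
        ("validation_outcome", "not_attempted"),
    ):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)
    out = [
        classify_truth(r["frequency_class"], r["dgv_class"],
                       r["replicate_status"], r["validation_outcome"])
        for _, r in df.iterrows()
    ]
    df["is_true"] = [t for t, _ in out]
    df["novelty"] = [n for _, n in out]
    return df


def count_confirmed(variants: pd.DataFrame) -> int:
    """Number of validation-selected variants resolved as true."""
    if len(variants) == 0:
        return 0
    df = variants
    if "is_true" not in df.columns:
        df = annotate_truth(df)
    sel = df["selected"] if "selected" in df.columns else pd.Series(True, index=df.index)
    return int((sel & df["is_true"]).sum())


def _strata(patients: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    form = patients["hscr_form"]
    return [
        ("HSCR form", "L/TCA", form.isin(["L", "TCA"])),
        ("HSCR form", "S", form.isin(["S", "ultraS"])),
        ("HSCR form", "unknown", ~form.isin(["L", "TCA", "S", "ultraS"])),
        ("gender", "M", patients["sex"] == "M"),
        ("gender", "F", patients["sex"] == "F"),
        ("syndromic", "no", patients["syndromic"] == "no"),
        ("syndromic", "yes", patients["syndromic"] == "yes"),
        ("RET anomaly", "no", ~patients["ret_status"].isin(RET_ANOMALY)),
        ("RET anomaly", "yes", patients["ret_status"].isin(RET_ANOMALY)),
        ("total", "patients", pd.Series(True, index=patients.index)),
    ]


def cohort_summary(variants: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Stratified patient counts: analyzed / with aberration / with true /
    true on database / true not on database.

    A patient is counted once per column even with multiple qualifying
    CNVs, so the two novelty sub-columns can sum to more than the "true"
    column.  A variant referencing an unknown patient is an error.
    """
    unknown = set(variants["sample_id"]) - set(patients["sample_id"])
    if unknown:
        raise ValueError(f"variants reference unknown patients: {sorted(unknown)}")
    v = variants if "is_true" in variants.columns else annotate_truth(variants)
    with_call = set(v["sample_id"])
    with_true = set(v.loc[v["is_true"], "sample_id"])
    true_on = set(v.loc[v["is_true"] & (v["novelty"] == "on_dgv"), "sample_id"])
    true_novel = set(v.loc[v["is_true"] & (v["novelty"] == "novel"), "sample_id"])
    rows = []
    for feature, level, mask in _strata(patients):
        ids = set(patients.loc[mask, "sample_id"])
        rows.append({
            "feature": feature,
            "level": level,
            "analyzed": len(ids),
            "with_aberration": len(ids & with_call),
            "with_true": len(ids & with_true),
            "true_on_db": len(ids & true_on),
            "true_not_on_db": len(ids & true_novel),
        })
    return pd.DataFrame(rows)


def size_comparison(
    sizes_a,
    sizes_b,
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> dict:
    """Median CNV sizes of two patient groups plus a two-sided Wilcoxon
    rank-sum p-value (NaN when a group is empty)."""
    a = np.asarray(list(sizes_a), dtype=float)
    b = np.asarray(list(sizes_b), dtype=float)
    med_a = float(np.median(a)) if a.size else np.nan
    med_b = float(np.median(b)) if b.size else np.nan
    if a.size and b.size:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        p = np.nan
    return {
        labels[0] + "_median": med_a,
        labels[1] + "_median": med_b,
        "p_value": p,
        "n": (int(a.size), int(b.size)),
    }


def validation_summary(variants: pd.DataFrame, patients: pd.DataFrame) -> dict:
    """Headline numbers of a validation follow-up.

    Reports how many validation-selected variants were confirmed true, how
    many novel (not-on-database) true CNVs there are overall, and how the
    carriers of novel true CNVs compare with the whole cohort for RET
    anomalies, sex and short-segment disease.  Percentages are rounded to
    one decimal; form fractions are computed among patients of known form.
    """
    v = variants if "is_true" in variants.columns else annotate_truth(variants)
    sel = v["selected"] if "selected" in v.columns else pd.Series(True, index=v.index)
    confirmed = int((sel & v["is_true"]).sum())
    novel_true = v.loc[v["is_true"] & (v["novelty"] == "novel")]
    carrier_ids = sorted(set(novel_true["sample_id"]))
    carriers = patients.set_index("sample_id").loc[carrier_ids]

    def pct(k: int, n: int) -> float:
        return round(100.0 * k / n, 1) if n else float("nan")

    known_form = patients["hscr_form"].isin(["S", "ultraS", "L", "TCA"])
    c_known = carriers["hscr_form"].isin(["S", "ultraS", "L", "TCA"])
    return {
        "n_selected": int(sel.sum()),
        "n_confirmed": confirmed,
        "n_novel_true": int(len(novel_true)),
        "n_patients_novel_true": len(carrier_ids),
        "ret_pct_carriers": pct(int(carriers["ret_status"].isin(RET_ANOMALY).sum()),
                                len(carriers)),
        "ret_pct_cohort": pct(int(patients["ret_status"].isin(RET_ANOMALY).sum()),
                              len(patients)),
        "female_pct_carriers": pct(int((carriers["sex"] == "F").sum()), len(carriers)),
        "female_pct_cohort": pct(int((patients["sex"] == "F").sum()), len(patients)),
        "s_form_pct_carriers": pct(
            int(carriers.loc[c_known, "hscr_form"].isin(["S", "ultraS"]).sum()),
            int(c_known.sum())),
        "s_form_pct_cohort": pct(
            int(patients.loc[known_form, "hscr_form"].isin(["S", "ultraS"]).sum()),
            int(known_form.sum())),
    }
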