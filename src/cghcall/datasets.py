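"""Bundled reference cohort: a 59-patient Hirschsprung-disease candidate-region
aCGH screen, encoded at the level the pipeline consumes.

The validation table lists the aberrations that went into orthogonal
validation (qPCR/PCR/higher-density array) plus one initially unselected
variant later confirmed on replicates, with the evidence-channel outcomes
encoded as labels.  The patient manifest covers all 59 patients: carriers
of validated variants are encoded individually; the remaining patients'
attributes are synthetic fills (see ``_FILLER``) that reproduce the
cohort's marginal composition (42 M / 17 F; 21 L/TCA, 30 S, 8 unknown
form; 10 syndromic; 14 with a RET anomaly).  Only marginal totals of the
filler block are meaningful, not joint combinations.

These tables drive the worked example and the printed-count checks; no
raw probe data exists for them.
"""

from __future__ import annotations

import pandas as pd

# variant_id, sample_id, chrom, start, end, type, probe_count, source,
# selected, validation_outcome, replicate_status, frequency_class,
# dgv_class, parental_origin
_VALIDATION = [
    ("v001", "HSCR000", "9", 110381888, 110401999, "gain", 9, "software",
     True, "validated", "confirmed", "novel", "novel", "maternal"),
    ("v005", "HSCR005", "7", 84217007, 84225649, "loss", 4, "software",
     True, "validated", "not_evaluable", "rare", "rare", "maternal"),
    ("v006", "HSCR005", "10", 43679892, 43680816, "loss", 5, "software",
     True, "failed", "not_evaluable", "novel", "novel", "none"),
    ("v008", "HSCR006", "10", 43679612, 43680816, "loss", 6, "software",
     True, "failed", "not_evaluable", "novel", "novel", "none"),
    ("v020", "HSCR018", "9", 109336464, 109348467, "gain", 6, "visual",
     True, "validated", "not_evaluable", "novel", "novel", "maternal"),
    ("v021", "HSCR019", "1", 146638075, 147824207, "loss", 4, "software",
     True, "validated", "confirmed", "novel", "novel", "maternal"),
    ("v027", "HSCR043", "9", 109273643, 109275694, "loss", 2, "visual",
     True, "validated", "not_evaluable", "novel", "novel", "maternal"),
    ("v028", "HSCR045", "7", 84594683, 84607065, "loss", 6, "visual",
     True, "failed", "not_evaluable", "novel", "novel", "unknown"),
    ("v029", "HSCR045", "8", 32597644, 32598929, "loss", 3, "visual",
     True, "validated", "not_evaluable", "novel", "novel", "unknown"),
    ("v030", "HSCR045", "10", 43679612, 43680816, "loss", 6, "software",
     True, "failed", "not_evaluable", "novel", "novel", "none"),
    ("v035", "HSCR146", "15", 58257674, 59009890, "gain", 2, "software",
     True, "validated", "not_evaluable", "novel", "novel", "maternal"),
    ("v036", "HSCR146", "19", 30888070, 30891329, "gain", 2, "software",
     True, "failed", "not_evaluable", "novel", "novel", "none"),
    ("v042", "HSCR195", "9", 112078131, 112089193, "loss", 5, "software",
     True, "not_conclusive", "confirmed", "novel", "novel", "unknown"),
    ("v043", "HSCR217", "16", 82200334, 82202467, "gain", 2, "software",
     True, "validated", "not_evaluable", "novel", "novel", "de_novo"),
    ("v060", "HSCR349", "10", 43573685, 43574005, "gain", 2, "software",
     True, "failed", "not_evaluable", "novel", "novel", "none"),
    ("v061", "HSCR374", "10", 43473690, 43474033, "gain", 4, "software",
     True, "failed", "not_evaluable", "novel", "novel", "none"),
    ("v069", "HSCR403", "4", 41746863, 41751291, "loss", 11, "software",
     True, "validated", "confirmed", "novel", "novel", "maternal"),
    ("v082", "HSCR481", "19", 31954093, 31966036, "loss", 5, "software",
     True, "validated", "not_evaluable", "novel", "novel", "unknown"),
    # initially judged unlikely on review, hence unselected; later found
    # concordant on two replicates and recurrent in two further samples
    ("v072", "HSCR403", "22", 21494163, 21704972, "gain", 5, "software",
     False, "not_attempted", "confirmed", "novel", "novel", "none"),
]

_VALIDATION_COLUMNS = [
    "variant_id", "sample_id", "chrom", "inner_start", "inner_end", "type",
    "probe_count", "source", "selected", "validation_outcome",
    "replicate_status", "frequency_class", "dgv_class", "parental_origin",
]

# sample_id, sex, hscr_form, syndromic, ret_status, haplotype
_CARRIERS = [
    ("HSCR000", "F", "TCA", "no", "deletion", "unknown"),
    ("HSCR005", "M", "S", "no", "none", "risk_homo"),
    ("HSCR006", "M", "L", "no", "none", "risk_homo"),
    ("HSCR018", "M", "L", "no", "mutation", "no_risk"),
    ("HSCR019", "F", "S", "yes", "none", "risk_homo"),
    ("HSCR043", "M", "S", "no", "mutation", "risk_homo"),
    ("HSCR045", "M", "L", "no", "none", "unknown"),
    ("HSCR146", "M", "S", "no", "none", "risk_homo"),
    ("HSCR195", "M", "S", "no", "mutation", "risk_homo"),
    ("HSCR217", "M", "S", "no", "mutation", "risk_homo"),
    ("HSCR349", "F", "unknown", "no", "none", "risk_homo"),
    ("HSCR374", "F", "L", "no", "none", "risk_homo"),
    ("HSCR403", "F", "S", "no", "none", "risk_homo"),
    ("HSCR481", "F", "unknown", "yes", "none", "unknown"),
]

# synthetic filler: 45 further patients hitting the cohort marginals
# (11 F / 34 M; 23 S / 16 L / 6 unknown; 8 syndromic; 9 RET mutations)
_FILLER = [
    (
        f"HSCR9{i:02d}",
        "F" if i < 11 else "M",
        "S" if i < 23 else ("L" if i < 39 else "unknown"),
        "yes" if i < 8 else "no",
        "mutation" if i < 9 else "none",
        "risk_homo",
    )
    for i in range(45)
]


def reference_validation_table() -> pd.DataFrame:
    """The validation follow-up table (18 selected aberrations in 14
    patients, plus one replicate-confirmed unselected variant)."""
    return pd.DataFrame(_VALIDATION, columns=_VALIDATION_COLUMNS)


def reference_patient_manifest() -> pd.DataFrame:
    """All 59 patients of the reference cohort (carriers individually
    encoded, the rest synthetic marginal fills)."""
    return pd.DataFrame(
        _CARRIERS + _FILLER,
        columns=["sample_id", "sex", "hscr_form", "syndromic", "ret_status",
                 "haplotype"],
    )
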