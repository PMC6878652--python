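"""Truth classification, cohort summaries, and trio/inheritance statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cghcall.classify import (annotate_truth, classify_truth, cohort_summary,
                              count_confirmed, size_comparison,
                              validation_summary)
from cghcall.datasets import (reference_patient_manifest,
                              reference_validation_table)
from cghcall.trio import (assign_origin, binomial_bias_test, clopper_pearson)
from tests.conftest import uniform_design


class TestClassifyTruth:
    def test_db_channel(self):
        is_true, novelty = classify_truth("common", "common",
                                          "not_evaluable", "not_attempted")
        assert is_true and novelty == "on_dgv"

    def test_no_evidence_not_true(self):
        is_true, _ = classify_truth("novel", "novel", "not_evaluable", "failed")
        assert not is_true

    def test_replicate_rescues_inconclusive_validation(self):
        is_true, novelty = classify_truth("novel", "novel", "confirmed",
                                          "not_conclusive")
        assert is_true and novelty == "novel"

    def test_rare_db_hit_is_true_but_novel(self):
        is_true, novelty = classify_truth("rare", "rare", "not_evaluable",
                                          "not_attempted")
        assert is_true and novelty == "novel"

    def test_monotone_in_evidence(self):
        channels = [
            ("novel", "novel", "not_evaluable", "not_attempted"),
            ("rare", "rare", "not_evaluable", "not_attempted"),
            ("rare", "rare", "confirmed", "not_attempted"),
            ("common", "common", "confirmed", "validated"),
        ]
        values = [classify_truth(*c)[0] for c in channels]
        assert values == sorted(values)  # once true, stays true


class TestReferenceCohort:
    def test_manifest_marginals(self):
        p = reference_patient_manifest()
        assert len(p) == 59
        assert (p["sex"] == "F").sum() == 17
        assert p["hscr_form"].isin(["S", "ultraS"]).sum() == 30
        assert p["hscr_form"].isin(["L", "TCA"]).sum() == 21
        assert (p["syndromic"] == "yes").sum() == 10
        assert p["ret_status"].isin(["mutation", "deletion"]).sum() == 14

    def test_count_confirmed_on_validation_table(self):
        v = reference_validation_table()
        assert int(v["selected"].sum()) == 18
        assert count_confirmed(v) == 11
        failed = v.copy()
        failed["validation_outcome"] = "failed"
        failed["replicate_status"] = "not_confirmed"
        failed["frequency_class"] = "novel"
        assert count_confirmed(failed) == 0
        assert count_confirmed(v.iloc[0:0]) == 0

    def test_unselected_replicate_confirmed_variant_completes_the_dozen(self):
        v = annotate_truth(reference_validation_table())
        novel_true = v[v["is_true"] & (v["novelty"] == "novel")]
        assert len(novel_true) == 12
        assert novel_true["sample_id"].nunique() == 11

    def test_summary_strata(self):
        v = annotate_truth(reference_validation_table())
        p = reference_patient_manifest()
        s = cohort_summary(v, p).set_index(["feature", "level"])
        ret_yes = s.loc[("RET anomaly", "yes")]
        assert ret_yes["analyzed"] == 14
        assert ret_yes["true_not_on_db"] == 5
        total = s.loc[("total", "patients")]
        assert total["analyzed"] == 59
        assert total["with_aberration"] == 14
        # column ordering invariant
        assert (s["with_true"] <= s["with_aberration"]).all()
        assert (s["true_on_db"] <= s["with_true"]).all()
        assert (s["true_not_on_db"] <= s["with_true"]).all()


class TestCohortSummaryContracts:
    def _patients(self):
        return pd.DataFrame({
            "sample_id": ["p1", "p2"],
            "sex": ["M", "F"],
            "hscr_form": ["S", "L"],
            "syndromic": ["no", "no"],
            "ret_status": ["none", "none"],
        })

    def test_no_cnvs_gives_zero_columns(self):
        v = pd.DataFrame(columns=["sample_id", "is_true", "novelty"])
        s = cohort_summary(v, self._patients())
        assert (s["with_aberration"] == 0).all()
        assert (s["with_true"] == 0).all()

    def test_patient_counted_once_per_column(self):
        # one patient with two true CNVs, one on-db and one novel: counted
        # once in "true" but once in each novelty column
        v = pd.DataFrame([
            {"sample_id": "p1", "is_true": True, "novelty": "on_dgv"},
            {"sample_id": "p1", "is_true": True, "novelty": "novel"},
        ])
        s = cohort_summary(v, self._patients()).set_index(["feature", "level"])
        total = s.loc[("total", "patients")]
        assert total["with_true"] == 1
        assert total["true_on_db"] == 1
        assert total["true_not_on_db"] == 1

    def test_unknown_patient_errors(self):
        v = pd.DataFrame([{"sample_id": "ghost", "is_true": True,
                           "novelty": "novel"}])
        with pytest.raises(ValueError):
            cohort_summary(v, self._patients())


class TestSizeComparison:
    def test_symmetry_gives_p_one(self):
        res = size_comparison([10, 20, 30], [10, 20, 30])
        assert res["group_a_median"] == res["group_b_median"] == 20
        assert res["p_value"] > 0.99

    def test_single_elements(self):
        res = size_comparison([100], [200])
        assert res["group_a_median"] == 100
        assert res["group_b_median"] == 200
        assert res["p_value"] > 0.99  # no power at n=1 vs 1

    def test_large_vs_small_events_detected(self):
        rng = np.random.default_rng(32)
        big = rng.uniform(1e6, 5e6, 12)    # syndromic-like multi-Mb events
        small = rng.uniform(5e3, 5e4, 12)  # isolated-like multi-kb events
        res = size_comparison(big, small)
        assert res["group_a_median"] > res["group_b_median"]
        assert res["p_value"] < 0.05

    def test_empty_group(self):
        res = size_comparison([1.0, 2.0], [])
        assert np.isnan(res["p_value"])


class TestValidationSummary:
    def test_reference_numbers(self):
        out = validation_summary(reference_validation_table(),
                                 reference_patient_manifest())
        assert out["n_confirmed"] == 11
        assert out["n_selected"] == 18
        assert out["n_novel_true"] == 12
        assert out["n_patients_novel_true"] == 11
        assert out["ret_pct_carriers"] == 45.5
        assert out["ret_pct_cohort"] == 23.7
        assert out["female_pct_carriers"] == 36.4
        assert out["female_pct_cohort"] == 28.8
        assert out["s_form_pct_carriers"] == 70.0
        assert out["s_form_pct_cohort"] == 58.8


class TestClopperPearson:
    def test_closed_form_edges(self):
        low, high = clopper_pearson(7, 7)
        assert low == pytest.approx(0.025 ** (1 / 7))
        assert high == 1.0
        assert clopper_pearson(1, 1) == pytest.approx((0.025, 1.0))
        assert clopper_pearson(0, 1) == pytest.approx((0.0, 0.975))

    @given(st.integers(0, 30), st.integers(1, 30))
    def test_mirror_symmetry(self, k, n):
        if k > n:
            k = k % (n + 1)
        low, high = clopper_pearson(k, n)
        mlow, mhigh = clopper_pearson(n - k, n)
        assert low == pytest.approx(1 - mhigh, abs=1e-12)
        assert high == pytest.approx(1 - mlow, abs=1e-12)
        assert low <= k / n <= high

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(2, 1)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


class TestBinomialBias:
    def test_exact_tail_examples(self):
        assert binomial_bias_test(7, 7).p_value == pytest.approx(0.5 ** 7)
        assert binomial_bias_test(4, 8).p_value == pytest.approx(0.63671875)
        assert binomial_bias_test(0, 7).p_value == pytest.approx(1.0)

    def test_two_sided_option(self):
        assert binomial_bias_test(7, 7, sided="two").p_value == pytest.approx(
            2 * 0.5 ** 7)

    def test_monotone_in_maternal_count(self):
        ps = [binomial_bias_test(k, 8).p_value for k in range(9)]
        assert ps == sorted(ps, reverse=True)

    def test_zero_inherited_errors(self):
        with pytest.raises(ValueError):
            binomial_bias_test(0, 0)


class TestAssignOrigin:
    def _call(self, design, lo, hi, typ="gain", sample="kid"):
        return pd.Series({
            "sample_id": sample, "chrom": design.df["chrom"].iat[lo],
            "inner_start": int(design.starts[lo]),
            "inner_end": int(design.ends[hi]), "type": typ,
        })

    def test_rule_table(self):
        d = uniform_design(60)
        child = self._call(d, 10, 15)
        mo_pos = pd.DataFrame([self._call(d, 10, 15, sample="mo")])
        neg = pd.DataFrame(columns=child.index)
        assert assign_origin(d, child, mo_pos, neg).origin == "maternal"
        assert assign_origin(d, child, neg, mo_pos).origin == "paternal"
        assert assign_origin(d, child, neg, neg).origin == "de_novo"
        assert assign_origin(d, child, neg, None).origin == "unknown"
        assert assign_origin(d, child, None, None).origin == "unknown"
        # one parent missing but the other positive resolves anyway
        assert assign_origin(d, child, mo_pos, None).origin == "maternal"
        # both positive is surfaced, not resolved
        assert assign_origin(d, child, mo_pos, mo_pos).origin == "ambiguous"

    def test_shifted_parent_call_within_two_probes_still_transmits(self):
        d = uniform_design(60)
        child = self._call(d, 10, 19)
        mo = pd.DataFrame([self._call(d, 10, 21, sample="mo")])
        assert assign_origin(d, child, mo, pd.DataFrame(columns=child.index)
                             ).origin == "maternal"
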