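"""Database consistency matching, frequency classes and frequency tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cghcall.popdb import (calls_consistent, cohort_frequency_report,
                           fisher_exact_pvalue, fisher_pvalues,
                           frequency_class, frequency_test,
                           intervals_consistent, match, odds_ratio)
from cghcall.simulate import make_population_db
from tests.conftest import uniform_design
from tests.oracle import fisher_pvalues_exact


def call_series(design, lo, hi, typ="gain", sample_id="s1"):
    return pd.Series({
        "sample_id": sample_id,
        "chrom": design.df["chrom"].iat[lo],
        "inner_start": int(design.starts[lo]),
        "inner_end": int(design.ends[hi]),
        "type": typ,
    })


class TestConsistency:
    def setup_method(self):
        self.d = uniform_design(100)

    def test_identical_intervals_match(self):
        c = call_series(self.d, 10, 19)
        db = make_population_db(
            [("1", int(self.d.starts[10]), int(self.d.ends[19]), "gain", 6, 100)],
            "dgv")
        res = match(self.d, c, db)
        assert len(res.matched) == 1
        assert res.frequency_class == "common"

    def test_overlap_boundary_at_80_percent(self):
        c = call_series(self.d, 10, 19)
        length = int(self.d.ends[19]) - int(self.d.starts[10]) + 1
        # entry trimmed from the left so that probes 10-11 fall outside
        for frac, expected in ((0.79, 0), (0.80, 1)):
            delta = length - int(np.ceil(frac * length))
            start = int(self.d.starts[10]) + delta
            ok = intervals_consistent(
                self.d, "1", (int(self.d.starts[10]), int(self.d.ends[19])),
                (start, int(self.d.ends[19])), "gain", "gain")
            assert int(ok) == expected, frac

    def test_same_kind_required(self):
        c = call_series(self.d, 10, 19, typ="gain")
        db = make_population_db(
            [("1", int(self.d.starts[10]), int(self.d.ends[19]), "loss", 6, 100)],
            "dgv")
        res = match(self.d, c, db)
        assert len(res.matched) == 0
        assert res.frequency_class == "novel"

    def test_probe_difference_cap(self):
        a = (int(self.d.starts[10]), int(self.d.ends[19]))
        # entry extends over 3 extra probes on the right -> inconsistent
        b3 = (a[0], int(self.d.ends[22]))
        assert not intervals_consistent(self.d, "1", a, b3, "gain", "gain")
        b2 = (a[0], int(self.d.ends[21]))
        assert intervals_consistent(self.d, "1", a, b2, "gain", "gain")

    def test_quiet_query_probes_do_not_count(self):
        # call probes outside the entry are gated by |log2| >= 0.3: a 20-probe
        # call whose first 3 probes are quiet still matches an entry that
        # starts 3 probes in (overlap 84%), but not when the probes are loud
        ratios = np.zeros(100)
        ratios[13:30] = 0.8  # probes 10-12 quiet
        a = (int(self.d.starts[10]), int(self.d.ends[29]))
        b = (int(self.d.starts[13]), int(self.d.ends[29]))
        assert not intervals_consistent(self.d, "1", a, b, "gain", "gain")
        assert intervals_consistent(self.d, "1", a, b, "gain", "gain",
                                    ratios_a=ratios)

    def test_reflexive_and_symmetric(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            lo = int(rng.integers(0, 80))
            hi = lo + int(rng.integers(0, 15))
            a = call_series(self.d, lo, hi)
            assert calls_consistent(self.d, a, a)
            lo2 = int(rng.integers(0, 80))
            hi2 = lo2 + int(rng.integers(0, 15))
            b = call_series(self.d, lo2, hi2)
            kw = dict(overlap_min=0.0)  # isolate the probe-diff criterion
            assert calls_consistent(self.d, a, b, **kw) == \
                calls_consistent(self.d, b, a, **kw)


class TestFrequencyClass:
    @pytest.mark.parametrize("freqs,expected", [
        ([0.06], "common"),
        ([0.008], "rare"),
        ([], "novel"),
        ([0.0], "novel"),
        ([0.03], "intermediate"),
        ([0.008, 0.2], "common"),
    ])
    def test_bands(self, freqs, expected):
        assert frequency_class(freqs) == expected


class TestFrequencyTest:
    def test_sparse_table_uses_fisher_and_direction(self):
        res = frequency_test(3, 59, 3, 1000)
        assert res["method"] == "fisher"
        assert res["p_value"] < 0.01
        assert res["odds_ratio"] > 1

    def test_identical_frequencies_null(self):
        res = frequency_test(5, 100, 5, 100)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["method"] == "chi2_yates"  # all expected counts are 5

    def test_degenerate_zero_cells_flagged(self):
        res = frequency_test(0, 10, 0, 10)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["or_corrected"] is True
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_empty_cohorts_error(self):
        with pytest.raises(ValueError):
            frequency_test(0, 0, 0, 0)

    def test_or_invariant_under_double_swap(self):
        a, _ = odds_ratio([[7, 13], [2, 38]])
        b, _ = odds_ratio([[38, 2], [13, 7]])
        assert a == pytest.approx(b)

    @given(st.integers(1, 25), st.integers(1, 25), st.integers(1, 25),
           st.integers(1, 25))
    def test_p_in_unit_interval(self, a, b, c, d):
        res = frequency_test(a, a + b, c, c + d)
        assert 0 < res["p_value"] <= 1

    def test_fisher_matches_scipy_spot_checks(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_pvalue(t) == pytest.approx(
                stats.fisher_exact(t)[1], abs=1e-12)

    def test_fisher_matches_enumeration_small(self):
        for total in (1, 7, 18, 30):
            for r1 in range(total + 1):
                for c1 in range(total + 1):
                    _, p_impl = fisher_pvalues(total, r1, c1)
                    _, p_oracle = fisher_pvalues_exact(total, r1, c1)
                    assert np.max(np.abs(p_impl - np.array(p_oracle))) < 1e-12


class TestCohortReport:
    def test_planted_enrichment_detected(self):
        # locus carried by ~20% of 59 cases vs 5% of a 1000-control fixture
        d = uniform_design(60)
        db = make_population_db(
            [("1", int(d.starts[20]), int(d.ends[27]), "gain", 50, 1000)],
            "gnomad")
        from cghcall.qc import preprocess
        from cghcall.segment import detect_aberrations
        from cghcall.simulate import PlantedCNV, plant_cnvs, render_profile

        powered = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(4000 + seed)
            carriers = 0
            for s in range(59):
                cnvs = []
                if rng.random() < 0.20:
                    cnvs = [PlantedCNV("1", int(d.starts[20]), int(d.ends[27]),
                                       "gain", 3)]
                prof = render_profile(d, plant_cnvs(d, cnvs), 0.12,
                                      seed=rng.integers(2**31),
                                      sample_id=f"c{s}")
                calls = detect_aberrations(d, prof.ratios, 0.12)
                carriers += len(calls) > 0
            variants = pd.DataFrame([{
                "chrom": "1", "inner_start": int(d.starts[20]),
                "inner_end": int(d.ends[27]), "type": "gain",
                "carriers": carriers,
            }])
            rep = cohort_frequency_report(d, variants, db, 59)
            powered += rep.iloc[0]["gnomad_p"] < 0.05
        assert powered >= 0.8 * n_seeds

    def test_empty_cohort_and_missing_source(self):
        d = uniform_design(30)
        db = make_population_db(
            [("1", int(d.starts[2]), int(d.ends[5]), "gain", 10, 100)], "ddd")
        empty = pd.DataFrame(
            columns=["chrom", "inner_start", "inner_end", "type", "carriers"])
        assert len(cohort_frequency_report(d, empty, db, 10)) == 0
        variants = pd.DataFrame([{
            "chrom": "1", "inner_start": int(d.starts[20]),
            "inner_end": int(d.ends[24]), "type": "loss", "carriers": 2,
        }])
        rep = cohort_frequency_report(d, variants, db, 10)
        assert rep.iloc[0]["ddd_method"] == "not_tested"
        assert np.isnan(rep.iloc[0]["ddd_p"])
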