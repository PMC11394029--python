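"""Rank-sum exactness, quartiles, correlation/regression, cohort arithmetic."""

import numpy as np
import pytest

from msiburden.cohort_burden import BurdenRecord
from msiburden.cohort_stats import (
    burden_tmb_association,
    cohort_count_summary,
    histotype_summary,
    quartile_summary,
    wilcoxon_pairwise,
)
from msiburden.tmb_calc import TMBResult

from oracles import exact_mannwhitney_p


class TestQuartiles:
    def test_singleton(self):
        assert quartile_summary([5]) == (1, 5.0, 5.0, 5.0)

    def test_even_n_midpoint_median(self):
        n, med, q1, q3 = quartile_summary([1, 2, 3, 4])
        assert med == 2.5

    def test_type7_interpolation_on_1_to_100(self):
        n, med, q1, q3 = quartile_summary(list(range(1, 101)))
        assert (q1, q3) == (25.75, 75.25)
        assert med == 50.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quartile_summary([])


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        p = wilcoxon_pairwise({"a": [1, 2, 3], "b": [1, 2, 3]})[("a", "b")]
        assert p == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        # all 3 observations of one group above the other: p = 2/C(6,3) = 0.1
        p = wilcoxon_pairwise({"a": [1, 2, 3], "b": [10, 11, 12]})[("a", "b")]
        assert p == pytest.approx(0.1)

    def test_three_categories_give_three_pairs(self):
        out = wilcoxon_pairwise({"a": [1.0], "b": [2.0], "c": [3.0]})
        assert len(out) == 3

    def test_empty_category_not_computable(self):
        out = wilcoxon_pairwise({"a": [1, 2], "b": []})
        assert out[("a", "b")] is None

    def test_exact_agrees_with_enumeration(self, rng):
        """Full-enumeration agreement on tie-free inputs with n1+n2 <= 12."""
        for n1 in range(1, 7):
            for n2 in range(n1, 7):
                if n1 + n2 > 12:
                    continue
                for _ in range(3):
                    pool = rng.choice(np.arange(1, 200), size=n1 + n2, replace=False)
                    x = [float(v) for v in pool[:n1]]
                    y = [float(v) for v in pool[n1:]]
                    got = wilcoxon_pairwise({"x": x, "y": y})[("x", "y")]
                    assert got == pytest.approx(exact_mannwhitney_p(x, y)), (x, y)


class TestAssociation:
    def test_perfect_linearity(self):
        b = [0.0, 0.1, 0.2, 0.3]
        out = burden_tmb_association(b, [2 * v for v in b])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(0.0)

    def test_constant_burden_not_computable(self):
        assert burden_tmb_association([0.1, 0.1, 0.1], [1.0, 2.0, 3.0]) is None

    def test_affine_invariance_of_r(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r0 = burden_tmb_association(list(x), list(y))["pearson_r"]
        r1 = burden_tmb_association(list(3 * x + 1), list(y))["pearson_r"]
        r2 = burden_tmb_association(list(-2 * x), list(y))["pearson_r"]
        assert r1 == pytest.approx(r0)
        assert r2 == pytest.approx(-r0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            burden_tmb_association([1, 2, 3], [1, 2])


def brec(sample, histotype, affected, burden, raw, category):
    return BurdenRecord(sample, histotype, affected, 100, burden, raw, category)


class TestHistotypeSummary:
    def test_all_stable_prevalence_zero(self):
        recs = [brec(f"s{i}", "ost", 0, 0.0, 0, "MSS") for i in range(4)]
        df = histotype_summary(recs)
        assert df.loc[0, "msi_prevalence_pct"] == 0.0
        assert df.loc[0, "n_MSS"] == 4

    def test_disjoint_histotypes_independent(self):
        recs = [brec("a", "h1", 1, 0.01, 1, "MSI-L"),
                brec("b", "h2", 0, 0.0, 0, "MSS")]
        df = histotype_summary(recs).set_index("histotype")
        assert df.loc["h1", "msi_prevalence_pct"] == 100.0
        assert df.loc["h2", "msi_prevalence_pct"] == 0.0

    def test_prevalence_matches_brute_force(self, rng):
        recs = []
        for i in range(60):
            raw = int(rng.integers(0, 5))
            aff = min(raw, int(rng.integers(0, 4)))
            cat = ("MSS" if raw == 0 else
                   "EXCLUDED" if aff == 0 else
                   "MSI-L")
            recs.append(brec(f"s{i}", f"h{i % 3}", aff, aff / 100, raw, cat))
        df = histotype_summary(recs).set_index("histotype")
        for h in ("h0", "h1", "h2"):
            expected = sum(1 for r in recs if r.histotype == h and r.raw_event_count >= 1)
            assert df.loc[h, "n_msi_positive"] == expected

    def test_sample_mismatch_raises(self):
        recs = [brec("a", "h", 0, 0.0, 0, "MSS")]
        tmb = [TMBResult("b", 0, 57.0, 0.0)]
        with pytest.raises(ValueError, match="b"):
            histotype_summary(recs, tmb)


# printed per-histotype sample counts of the reference canine WES cohort,
# used as a fixture table for the report arithmetic
COHORT_COUNTS = {
    "melanoma": 137, "mammary_carcinoma": 136, "b_cell_lymphoma": 103,
    "osteosarcoma": 98, "t_cell_lymphoma": 65, "hemangiosarcoma": 64,
    "glioma": 52, "mast_cell_tumor": 28, "pulmonary_adenocarcinoma": 5,
    "urinary_carcinoma": 4,
}


class TestCohortArithmetic:
    def test_totals_prevalence_and_exclusions(self):
        out = cohort_count_summary(COHORT_COUNTS, n_msi_positive=446, n_classified=430)
        assert out["total_samples"] == 692
        assert out["msi_prevalence_pct"] == 64
        assert out["n_patient_specific_excluded"] == 16

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cohort_count_summary({"a": 10}, n_msi_positive=11, n_classified=5)
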