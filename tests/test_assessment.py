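import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gmoequiv.assessment import (
    AssessmentConfig,
    CATEGORY_OF_TYPE,
    EquivalenceLimits,
    assess_analyte,
    assess_from_summary,
    classify_outcome,
    estimate_equivalence_limits,
    run_equivalence_tests,
)
from gmoequiv.assessment import test_difference as difference_test
from gmoequiv.mixed_model import ContrastEstimate, fit_model
from gmoequiv.fixtures import assess_maize_example, load_maize_summary


def _niacin_limits():
    # reference geometric mean 20.915, model-2 sed 0.1178, df 10.8
    c = ContrastEstimate(math.log(0.7602), 0.1178, 10.8)
    return estimate_equivalence_limits(m_r=math.log(20.915), contrast=c,
                                       degenerate=False)


class TestEquivalenceLimits:
    def test_niacin_natural_scale(self):
        lo, hi = _niacin_limits().natural()
        assert lo == pytest.approx(16.1, abs=0.1)
        assert hi == pytest.approx(27.1, abs=0.1)

    def test_niacin_ratio_scale(self):
        m_g = math.log(20.915) + math.log(0.7602)
        lo, hi = _niacin_limits().ratio_to_reference(m_g)
        assert lo == pytest.approx(0.59, abs=0.01)
        assert hi == pytest.approx(0.99, abs=0.01)

    def test_zero_sed_collapses_to_reference_mean(self):
        c = ContrastEstimate(0.0, 0.0, 10.0)
        lim = estimate_equivalence_limits(m_r=1.5, contrast=c, degenerate=False)
        assert lim.lower == lim.upper == lim.center == 1.5

    def test_requires_variant2_fit(self, balanced_fits):
        f1, f2 = balanced_fits
        with pytest.raises(ValueError, match="variant-2"):
            estimate_equivalence_limits(f1)
        lim = estimate_equivalence_limits(f2)
        assert lim.lower < f2.m_r < lim.upper
        assert (lim.upper - lim.center) == pytest.approx(lim.center - lim.lower)


class TestDifference:
    def test_niacin_ci_reproduced(self):
        c = ContrastEstimate(math.log(0.872), 0.0216, 41.7)
        d = difference_test(contrast=c)
        lo, hi = d.ratio_interval()
        assert lo == pytest.approx(0.8405, abs=0.001)
        assert hi == pytest.approx(0.904, abs=0.001)
        assert d.significant

    def test_acid_detergent_fiber_not_significant(self):
        c = ContrastEstimate(math.log(1.103), 0.07046, 51.9)
        d = difference_test(contrast=c)
        lo, hi = d.ratio_interval()
        assert lo < 1.0 < hi
        assert not d.significant

    def test_equal_means_never_significant(self):
        d = difference_test(contrast=ContrastEstimate(0.0, 0.01, 40.0))
        assert d.estimate == 0.0 and not d.significant


class TestEquivalenceTests:
    def test_niacin_e1_outside(self):
        lim = _niacin_limits()
        m_g = math.log(20.915) + math.log(0.7602)
        sed_gr1 = math.sqrt(0.1178**2 - 0.01264)
        eq = run_equivalence_tests(
            None, None, lim, m_g=m_g,
            interval_contrast=ContrastEstimate(math.log(0.7602), sed_gr1, 41.7),
        )
        assert eq.e1 == "nonequiv_more_likely"
        assert not eq.e2_proven and not eq.e3_proven

    def test_exact_match_with_zero_sed_proves_equivalence(self):
        lim = EquivalenceLimits(-0.1, 0.1, 0.0, 0.1, 97.5)
        eq = run_equivalence_tests(
            None, None, lim, m_g=0.0,
            interval_contrast=ContrastEstimate(0.0, 0.0, 10.0),
        )
        assert eq.e1 == "equiv_more_likely" and eq.e2_proven

    def test_boundary_tie_is_non_rejection(self):
        lim = EquivalenceLimits(-0.1, 0.1, 0.0, 0.1, 97.5)
        # point estimate exactly on the upper limit: still "inside" for E1
        eq = run_equivalence_tests(
            None, None, lim, m_g=0.1,
            interval_contrast=ContrastEstimate(0.1, 0.0, 10.0),
        )
        assert eq.e1 == "equiv_more_likely"
        assert not eq.e2_proven and not eq.e3_proven


class TestClassification:
    @pytest.mark.parametrize(
        "analyte,expected_type,expected_cat",
        [("16:0 Palmitic", 5, "iii"), ("Niacin", 6, "iii"), ("Lysine", 4, "ii")],
    )
    def test_named_field_examples(self, analyte, expected_type, expected_cat):
        a = {x.analyte: x for x in assess_maize_example()}[analyte]
        assert a.outcome_type == expected_type
        assert a.category == expected_cat

    def test_degenerate_cases_have_no_type(self):
        by = {x.analyte: x for x in assess_maize_example()}
        for analyte in ("Ash", "Phytic acid"):
            assert by[analyte].degenerate
            assert by[analyte].outcome_type is None
            assert by[analyte].category is None

    @given(
        m_g=st.floats(-0.5, 0.5),
        m_c=st.floats(-0.3, 0.3),
        half=st.floats(0.01, 0.4),
        lsd=st.floats(0.001, 0.3),
        sig=st.booleans(),
    )
    @settings(max_examples=300, deadline=None)
    def test_partition_exactly_one_type(self, m_g, m_c, half, lsd, sig):
        lim = EquivalenceLimits(-half, half, 0.0, half, 97.5)
        eq = run_equivalence_tests(
            None, None, lim, m_g=m_g,
            interval_contrast=ContrastEstimate(m_g, lsd / 1.645, 1e9),
        )
        diff = difference_test(
            contrast=ContrastEstimate(m_g - m_c if sig else 0.0, 0.01, 50.0)
        )
        otype, cat, _ = classify_outcome(diff, eq, lim, m_c)
        assert otype in range(1, 8)
        assert cat == CATEGORY_OF_TYPE[otype]
        # consistency of the three binary verdicts with the type
        assert eq.e2_proven == (otype in (1, 2))
        assert eq.e3_proven == (otype == 7)
        if otype in (1, 2, 3, 4):
            assert eq.e1 == "equiv_more_likely"

    def test_e1_e2_e3_mutual_constraints(self):
        for a in assess_maize_example():
            eq = a.equivalence
            if eq.e2_proven:
                assert eq.e1 == "equiv_more_likely"
            if eq.e3_proven:
                assert eq.e1 == "nonequiv_more_likely"
            assert not (eq.e2_proven and eq.e3_proven)


class TestFieldStudyTallies:
    def test_published_counts_reproduced(self):
        a = assess_maize_example()
        assert len(a) == 53
        assert sum(x.difference.significant for x in a) == 23
        assert sorted(x.analyte for x in a if x.degenerate) == ["Ash", "Phytic acid"]
        outside = [x.analyte for x in a
                   if not x.degenerate and x.equivalence.e1 == "nonequiv_more_likely"]
        assert sorted(outside) == ["16:0 Palmitic", "Niacin"]

    def test_equivalence_category_counts(self):
        a = [x for x in assess_maize_example() if not x.degenerate]
        assert sum(x.equivalence.e2_proven for x in a) == 44
        cat_ii = sorted(x.analyte for x in a if x.category == "ii")
        assert cat_ii == ["Lysine", "Phosphorus", "Potassium",
                          "Vitamin B6", "Vitamin E"]


class TestE1Duality:
    def test_e1_equals_model2_difference_test(self):
        # E1 'inside' is exactly a non-significant two-sided 95% model-2
        # test of m_G - m_R
        table = load_maize_summary()
        for row in table.itertuples(index=False):
            if row.var_genotype <= 0:
                continue
            c = ContrastEstimate(math.log(row.ratio_gr), row.sed_gr2, row.df_gr2)
            lim = estimate_equivalence_limits(
                m_r=0.0, contrast=c, degenerate=False
            )
            inside = lim.contains(math.log(row.ratio_gr))
            lo, hi = c.confidence_interval(95.0)
            assert inside == (lo <= 0.0 <= hi)


@pytest.fixture(scope="module")
def baseline_assessment(balanced_dataset):
    return assess_analyte(balanced_dataset)


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [0.073, 3.7, 250.0])
    def test_verdicts_invariant_under_rescaling(self, c, balanced_dataset,
                                                baseline_assessment):
        from gmoequiv.trial_data import AnalyteDataset

        a1 = baseline_assessment
        shifted = AnalyteDataset(
            analyte=balanced_dataset.analyte,
            data=balanced_dataset.data.assign(
                y=balanced_dataset.data["y"] + math.log(c)
            ),
            exclusions=balanced_dataset.exclusions,
            design=balanced_dataset.design,
            transform="ln",
        )
        a2 = assess_analyte(shifted)
        assert a1.outcome_type == a2.outcome_type
        assert a1.difference.significant == a2.difference.significant
        assert a1.equivalence.e1 == a2.equivalence.e1
        assert a1.equivalence.e2_proven == a2.equivalence.e2_proven
        assert a1.equivalence.e3_proven == a2.equivalence.e3_proven


def test_assess_analyte_end_to_end(balanced_dataset):
    a = assess_analyte(balanced_dataset)
    assert a.analyte == balanced_dataset.analyte
    assert a.outcome_type in range(1, 8)
    assert a.limits.lower < a.m_r < a.limits.upper
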