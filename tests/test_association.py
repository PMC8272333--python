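"""Odds-ratio arithmetic, z comparisons, BH adjustment and the HWE test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cehrisk.association import (
    ContingencyTable,
    ORResult,
    bh_adjust,
    build_table,
    compare_ors,
    hwe_test,
    invert_or,
    ln_or_ratio,
    odds_ratio,
    rereference,
    se_from_ci,
)
from cehrisk.errors import DegenerateTableError

from conftest import make_cohort


class TestOddsRatio:
    def test_balanced_table_is_null(self):
        res = odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert res.or_value == 1.0
        assert res.ln_or == 0.0
        assert res.ci_low < 1 < res.ci_high

    def test_cross_product_by_hand(self):
        res = odds_ratio(ContingencyTable(30, 10, 70, 90))
        assert res.or_value == pytest.approx((30 * 90) / (10 * 70))
        assert res.se_ln_or == pytest.approx(math.sqrt(1 / 30 + 1 / 10 + 1 / 70 + 1 / 90))

    def test_haldane_correction_flagged(self):
        res = odds_ratio(ContingencyTable(10, 0, 10, 10), zero_correction=True)
        assert res.or_value == pytest.approx((10.5 * 10.5) / (0.5 * 10.5))
        assert res.corrected

    def test_zero_cell_without_correction_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            odds_ratio(ContingencyTable(10, 0, 10, 10))

    def test_na_flag_respects_min_marginal(self):
        assert odds_ratio(ContingencyTable(7, 7, 50, 50)).na_flag
        assert not odds_ratio(ContingencyTable(8, 7, 50, 50)).na_flag

    @given(st.integers(1, 5), st.integers(1, 5), st.integers(1, 5), st.integers(1, 5))
    def test_exact_rational_oracle(self, a, b, c, d):
        res = odds_ratio(ContingencyTable(a, b, c, d))
        assert res.or_value == float(Fraction(a * d, b * c))

    def test_ci_brackets_or(self):
        res = odds_ratio(ContingencyTable(12, 34, 56, 78), level=0.9)
        assert res.ci_low <= res.or_value <= res.ci_high
        assert res.or_value == pytest.approx(math.exp(res.ln_or))


class TestSeFromCi:
    def test_point_interval(self):
        assert se_from_ci(1.0, 1.0) == 0.0

    @pytest.mark.parametrize(
        "lo,hi,expected", [(2.8, 3.2, 0.03406), (2.4, 2.8, 0.03933)]
    )
    def test_printed_interval_recovery(self, lo, hi, expected):
        assert se_from_ci(lo, hi, 0.95) == pytest.approx(expected, abs=1e-5)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            se_from_ci(-1.0, 2.0)
        with pytest.raises(ValueError):
            se_from_ci(3.0, 2.0)


def _orr(or_value, se):
    ln = math.log(or_value)
    return ORResult(
        or_value=or_value, ln_or=ln, se_ln_or=se,
        ci_low=math.exp(ln - 1.96 * se), ci_high=math.exp(ln + 1.96 * se),
        p_value=0.5, n_exposed=100, n_reference=100,
    )


class TestCompareOrs:
    def test_identical_ors_give_zero(self):
        r = _orr(2.5, 0.1)
        cmp = compare_ors(r, r)
        assert cmp.z == 0.0
        assert cmp.p == 1.0

    def test_hand_calculation(self):
        cmp = compare_ors(_orr(2.0, 0.1), _orr(1.0, 0.1))
        assert cmp.z == pytest.approx(math.log(2) / math.sqrt(0.02), rel=1e-6)
        assert cmp.z == pytest.approx(4.901, abs=5e-4)

    @given(
        st.floats(0.1, 10), st.floats(0.01, 1), st.floats(0.1, 10), st.floats(0.01, 1)
    )
    def test_antisymmetry(self, or1, se1, or2, se2):
        a, b = _orr(or1, se1), _orr(or2, se2)
        fwd, rev = compare_ors(a, b), compare_ors(b, a)
        assert fwd.z == pytest.approx(-rev.z, rel=1e-12, abs=1e-12)

    @given(st.floats(0.2, 5), st.floats(0.05, 0.5), st.floats(0.2, 5), st.floats(0.05, 0.5),
           st.floats(0.2, 5))
    def test_invariant_under_joint_rescaling(self, or1, se1, or2, se2, scale):
        a, b = _orr(or1, se1), _orr(or2, se2)
        a2, b2 = _orr(or1 * scale, se1), _orr(or2 * scale, se2)
        assert compare_ors(a, b).z == pytest.approx(compare_ors(a2, b2).z, rel=1e-9, abs=1e-9)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            compare_ors(_orr(2.0, 0.0), _orr(1.0, 0.1))


class TestRereference:
    def test_multiplicativity(self):
        assert rereference(2.0, 3.0) == 6.0
        assert rereference(0.13, 1.0) == 0.13

    def test_reciprocal_reference_swap(self):
        assert invert_or(0.13) == pytest.approx(7.692, abs=5e-4)

    def test_ln_ratio(self):
        assert ln_or_ratio(3.67, 2.17) == pytest.approx(math.log(3.67 / 2.17))

    def test_rejects_nonpositive(self):
        for fn in (lambda: rereference(-1, 2), lambda: invert_or(0), lambda: ln_or_ratio(1, 0)):
            with pytest.raises(ValueError):
                fn()


def _bh_definitional(p):
    """Quadratic-time step-up straight from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100)
    def test_dominated_by_bonferroni(self, p):
        adj = bh_adjust(p)
        bonf = np.minimum(np.asarray(p) * len(p), 1.0)
        assert np.all(adj <= bonf + 1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(max_examples=100)
    def test_matches_definitional_implementation(self, p):
        assert bh_adjust(p) == pytest.approx(_bh_definitional(p), rel=1e-12, abs=1e-12)


class TestHWE:
    def test_exact_equilibrium(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_heterozygote_deficit_by_hand(self):
        res = hwe_test((30, 40, 30))
        assert res.chi2 == pytest.approx(4.0)
        assert res.df == 1
        assert res.p == pytest.approx(0.0455, abs=1e-3)

    def test_multiallelic_counts(self):
        counts = {("a", "a"): 16, ("a", "b"): 48, ("b", "b"): 36}
        res = hwe_test(counts)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1
        three = {("a", "a"): 10, ("a", "b"): 20, ("b", "b"): 15, ("a", "c"): 8,
                 ("b", "c"): 12, ("c", "c"): 5}
        res3 = hwe_test(three)
        assert res3.df == 3  # 6 genotype cells - 3 alleles

    def test_small_expected_cells_pooled(self):
        counts = {("a", "a"): 500, ("a", "b"): 80, ("b", "b"): 4, ("a", "c"): 2,
                  ("c", "c"): 0, ("b", "c"): 1}
        res = hwe_test(counts)
        assert res.pooled

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((100, 0, 0))


class TestBuildTable:
    def test_toy_counts(self):
        coh = make_cohort(
            [("case", "F", "H+", "0", 0, 0, 0), ("control", "M", "H+", "0", 0, 0, 0),
             ("case", "F", "0", "0", 0, 0, 0), ("control", "M", "0", "0", 0, 0, 0)]
        )
        t = build_table(
            coh,
            exposed=(coh["mhc_h1"] == "H+"),
            reference=(coh["mhc_h1"] == "0"),
        )
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_overlapping_predicates_rejected(self):
        coh = make_cohort([("case", "F", "H+", "0", 0, 0, 0)])
        with pytest.raises(ValueError, match="overlap"):
            build_table(coh, exposed=(coh["status"] == "case"), reference=(coh["mhc_h1"] == "H+"))

    def test_empty_reference_degenerate(self):
        coh = make_cohort([("case", "F", "H+", "0", 0, 0, 0)])
        with pytest.raises(DegenerateTableError):
            build_table(coh, exposed=(coh["mhc_h1"] == "H+"), reference=(coh["mhc_h1"] == "c1"))

    def test_strata_restricts_counts(self, study_cohort):
        exposed = study_cohort["mhc_h2"].eq("H+") & study_cohort["mhc_h1"].eq("0")
        reference = study_cohort["mhc_h1"].eq("0") & study_cohort["mhc_h2"].eq("0")
        full = build_table(study_cohort, exposed, reference)
        females = build_table(study_cohort, exposed, reference, strata=study_cohort["sex"].eq("F"))
        males = build_table(study_cohort, exposed, reference, strata=study_cohort["sex"].eq("M"))
        assert females.a + males.a == full.a
        assert females.d + males.d == full.d
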