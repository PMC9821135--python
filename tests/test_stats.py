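import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from upcr import (
    ValidationError,
    cohens_kappa,
    fisher_exact_2x2,
    mann_whitney,
    pearson_chi2_2x2,
    welch_t,
)


class TestWelchT:
    def test_identical_samples_null_identity(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Welch formulas by hand: t = -1/sqrt(2/3), Satterthwaite df = 4
        r = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.p == pytest.approx(0.2879, abs=1e-4)

    def test_bootstrap_p_tracks_analytic_p(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.5, 1.0, 30)
        analytic = welch_t(a, b)
        boot = welch_t(a, b, bootstrap=10_000, seed=99)
        assert boot.test == "student_t_bootstrap"
        assert abs(boot.p - analytic.p) <= 0.02

    def test_degenerate_zero_variance_flagged(self):
        r = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0 and r.flags["degenerate_zero_variance"]

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [2.0, 3.0])

    @given(shift=st.floats(min_value=-50, max_value=50))
    def test_location_shift_invariance(self, shift):
        a = np.array([0.3, 1.1, 2.2, 0.9])
        b = np.array([1.4, 2.0, 2.6, 3.1, 0.5])
        base = welch_t(a, b)
        moved = welch_t(a + shift, b + shift)
        assert moved.statistic == pytest.approx(base.statistic, rel=1e-9, abs=1e-9)


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        # all 6 label assignments of {1,2,3,4} into groups of 2: U=0 is one
        # of the two most extreme values -> two-sided p = 2/6
        r = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.test == "mann_whitney_exact"
        assert r.p == pytest.approx(1.0 / 3.0)

    def test_identical_samples_symmetric_null(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(4.5)  # n_a*n_b/2
        assert r.p == pytest.approx(1.0)

    def test_u_statistic_reflection_identity(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=9)
        u_ab = mann_whitney(a, b).statistic
        u_ba = mann_whitney(b, a).statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(8)
        a = np.round(rng.normal(0, 1, 40), 1)
        b = np.round(rng.normal(0.4, 1, 35), 1)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.integers(min_value=0, max_value=6))
    def test_monotone_transform_invariance(self, k):
        a = np.array([0.2, 0.5, 1.7, 2.2, 3.0])
        b = np.array([0.9, 1.1, 2.8, 3.3])
        f = lambda x: np.exp(x) + k * x  # strictly increasing
        assert mann_whitney(a, b).p == pytest.approx(mann_whitney(f(a), f(b)).p)


class TestPearsonChi2:
    def test_reproduces_published_severe_smallness_comparison(self):
        r = pearson_chi2_2x2([[18, 19], [20, 57]])
        assert r.statistic == pytest.approx(5.782, abs=1e-3)
        assert round(r.p, 3) == 0.016

    def test_independent_table_null(self):
        r = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_closed_form_diagonal_table(self):
        # N(ad-bc)^2/(r1 r2 c1 c2) = 10*625/(5*5*5*5) = 10
        assert pearson_chi2_2x2([[5, 0], [0, 5]]).statistic == pytest.approx(10.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            pearson_chi2_2x2([[0, 0], [5, 5]])

    def test_equals_squared_two_proportion_z(self):
        t = np.array([[12, 30], [22, 25]])
        stat = pearson_chi2_2x2(t).statistic
        p1, p2 = 12 / 42, 22 / 47
        pooled = 34 / 89
        z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / 42 + 1 / 47))
        assert stat == pytest.approx(z * z, rel=1e-12)

    @pytest.mark.parametrize(
        "table",
        [[[18, 19], [20, 57]], [[60, 40], [45, 55]], [[35, 15], [15, 35]], [[60, 40], [40, 60]]],
    )
    def test_exact_and_asymptotic_agree_in_the_significance_tail(self, table):
        # the conditional exact p is discretely conservative for mid-range p,
        # but tracks the chi-square tail closely where significance is decided
        asym = pearson_chi2_2x2(table).p
        exact = pearson_chi2_2x2(table, exact=True).p
        assert abs(asym - exact) <= 0.02

    def test_yates_correction_shrinks_statistic(self):
        t = [[18, 19], [20, 57]]
        assert pearson_chi2_2x2(t, yates=True).statistic < pearson_chi2_2x2(t).statistic


class TestFisherExact:
    def test_most_probable_table_has_p_one(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]).p == pytest.approx(1.0)

    def test_perfectly_discordant_table(self):
        assert fisher_exact_2x2([[0, 5], [5, 0]]).p == pytest.approx(2 / 252)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]).p == 1.0

    def test_matches_independent_oracle_on_all_small_tables(self):
        # exhaustively over every 2x2 table with positive margins, N <= 12
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        ours = fisher_exact_2x2(t).p
                        ref = sps.fisher_exact(t).pvalue
                        assert ours == pytest.approx(ref, abs=1e-12), t


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([[12, 0], [0, 30]]).kappa == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = cohens_kappa([[20, 5], [10, 15]])
        assert r.p_observed == pytest.approx(0.7)
        assert r.p_expected == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.4)

    def test_chance_level_agreement_is_zero(self):
        # table proportional to the outer product of its margins
        margins_r = np.array([0.6, 0.4])
        margins_c = np.array([0.3, 0.7])
        table = 100 * np.outer(margins_r, margins_c)
        assert cohens_kappa(table).kappa == pytest.approx(0.0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa([[0, 0], [0, 0]])

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa([[1, 2, 3], [4, 5, 6]])
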