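import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exprdist import (
    ExpressionMatrix,
    kurtosis_lower_bound,
    lmoment_tau4_lower_bound,
    moment_table,
    product_moments,
    sample_lmoments,
    theoretical_lmoment_curve,
)
from exprdist.moments import _polynomial_tau4_approx

finite_samples = st.lists(
    st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False), min_size=5, max_size=40
).filter(lambda xs: max(xs) - min(xs) > 1e-6)


class TestProductMoments:
    def test_symmetric_two_value_sample_attains_bound(self):
        ms = product_moments([-1.0, 1.0, -1.0, 1.0])
        assert ms.mean == 0.0
        assert ms.skewness == pytest.approx(0.0)
        assert ms.kurtosis == pytest.approx(1.0)  # equality case of K >= S^2 + 1

    def test_matches_direct_summation_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        n = x.size
        mean = sum(x) / n
        m2 = sum((v - mean) ** 2 for v in x) / n
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        ms = product_moments(x)
        assert ms.mean == pytest.approx(mean, abs=1e-12)
        assert ms.sd == pytest.approx(np.sqrt(m2), abs=1e-12)
        assert ms.skewness == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert ms.kurtosis == pytest.approx(m4 / m2**2, abs=1e-12)

    def test_normal_reference_values(self):
        x = np.random.default_rng(2024).standard_normal(1_000_000)
        ms = product_moments(x)
        assert abs(ms.skewness) < 0.02
        assert abs(ms.kurtosis - 3.0) < 0.02

    def test_constant_data_flagged_degenerate(self):
        ms = product_moments([3.0, 3.0, 3.0, 3.0])
        assert ms.degenerate
        assert ms.sd == 0.0
        assert np.isnan(ms.skewness) and np.isnan(ms.kurtosis)


class TestSampleLmoments:
    def test_hand_pwm_computation(self):
        l1, l2, tau3, tau4 = sample_lmoments([1.0, 2.0, 3.0, 4.0])
        assert l1 == pytest.approx(2.5)
        assert l2 == pytest.approx(5 / 6)  # b1 = 5/3, l2 = 2 b1 - b0

    def test_symmetric_sample_has_zero_l_skewness(self):
        _, _, tau3, _ = sample_lmoments([-3.0, -1.0, 0.0, 1.0, 3.0])
        assert tau3 == pytest.approx(0.0, abs=1e-14)

    def test_matches_order_statistic_subset_oracle(self, rng):
        """Independent oracle: the definitional U-statistics over all
        subsets of sizes 2..4, e.g. l2 = mean over pairs of (max-min)/2."""
        x = rng.normal(size=8)
        l1, l2, tau3, tau4 = sample_lmoments(x)
        pairs = [max(c) - min(c) for c in itertools.combinations(x, 2)]
        trips = [
            (c2 - 2 * c1 + c0) / 3.0
            for c0, c1, c2 in (sorted(c) for c in itertools.combinations(x, 3))
        ]
        quads = [
            (c3 - 3 * c2 + 3 * c1 - c0) / 4.0
            for c0, c1, c2, c3 in (sorted(c) for c in itertools.combinations(x, 4))
        ]
        l2_oracle = np.mean(pairs) / 2.0
        l3_oracle = np.mean(trips)
        l4_oracle = np.mean(quads)
        assert l1 == pytest.approx(np.mean(x), abs=1e-12)
        assert l2 == pytest.approx(l2_oracle, abs=1e-12)
        assert tau3 == pytest.approx(l3_oracle / l2_oracle, abs=1e-10)
        assert tau4 == pytest.approx(l4_oracle / l2_oracle, abs=1e-10)

    def test_exponential_population_ratios(self):
        x = np.random.default_rng(99).standard_exponential(1_000_000)
        _, _, tau3, tau4 = sample_lmoments(x)
        assert tau3 == pytest.approx(1 / 3, abs=0.002)
        assert tau4 == pytest.approx(1 / 6, abs=0.002)

    def test_constant_data_gives_zero_scale(self):
        l1, l2, tau3, tau4 = sample_lmoments([5.0] * 6)
        assert l2 == 0.0
        assert np.isnan(tau3) and np.isnan(tau4)


class TestMomentTable:
    def test_matches_scalar_api_row_by_row(self, small_matrix):
        table = moment_table(small_matrix)
        for gi, gene in enumerate(small_matrix.gene_ids[:5]):
            ms = product_moments(small_matrix.values[gi])
            row = table.loc[gene]
            assert row["skewness"] == pytest.approx(ms.skewness, abs=1e-12)
            assert row["tau4"] == pytest.approx(ms.tau4, abs=1e-12)

    def test_blocked_computation_independent_of_block_size(self, small_matrix):
        t1 = moment_table(small_matrix, block=3)
        t2 = moment_table(small_matrix, block=512)
        assert np.allclose(t1["kurtosis"], t2["kurtosis"])


class TestTheoreticalCurves:
    def test_symmetric_point_families(self):
        nor = theoretical_lmoment_curve("NOR")
        uni = theoretical_lmoment_curve("UNI")
        assert nor.tau3.iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert nor.tau4.iloc[0] == pytest.approx(0.1226, abs=2e-4)
        assert uni.tau3.iloc[0] == 0.0 and uni.tau4.iloc[0] == 0.0

    def test_gpa_curve_passes_through_exponential_point(self):
        curve = theoretical_lmoment_curve("GPA", [1 / 3])
        assert curve.tau4.iloc[0] == pytest.approx(1 / 6, abs=1e-12)

    def test_gumbel_point(self):
        gum = theoretical_lmoment_curve("GUM")
        assert gum.tau3.iloc[0] == pytest.approx(0.1699, abs=2e-4)
        assert gum.tau4.iloc[0] == pytest.approx(0.1504, abs=2e-4)

    @pytest.mark.parametrize("family", ["GNO", "PE3"])
    def test_quadrature_matches_published_polynomial_approximations(self, family):
        grid = np.array([-0.5, -0.2, 0.1, 0.3, 0.5])
        curve = theoretical_lmoment_curve(family, grid)
        approx = _polynomial_tau4_approx(family, grid)
        np.testing.assert_allclose(curve.tau4.to_numpy(), approx, atol=2e-3)

    def test_glo_curve_matches_large_sample_simulation(self):
        """Simulation oracle: sample L-moment ratios of generalized-logistic
        draws at three shapes agree with the theoretical curve."""
        rng = np.random.default_rng(7)
        for k in (-0.3, 0.0, 0.25):
            u = rng.uniform(size=1_000_000)
            if abs(k) < 1e-12:
                x = np.log(u / (1 - u))
            else:
                x = (1 - ((1 - u) / u) ** k) / k
            _, _, t3, t4 = sample_lmoments(x)
            expected = theoretical_lmoment_curve("GLO", [t3]).tau4.iloc[0]
            assert t4 == pytest.approx(expected, abs=0.002)

    def test_point_family_rejects_grid_and_range_checked(self):
        with pytest.raises(ValueError):
            theoretical_lmoment_curve("NOR", [0.1])
        with pytest.raises(ValueError):
            theoretical_lmoment_curve("GLO", [1.2])
        with pytest.raises(ValueError):
            theoretical_lmoment_curve("GPA", [-0.5])


class TestBounds:
    @pytest.mark.parametrize("s, expected", [(0.0, 1.0), (2.0, 5.0), (-2.0, 5.0)])
    def test_kurtosis_bound_values(self, s, expected):
        assert kurtosis_lower_bound(s) == expected

    @given(finite_samples)
    @settings(max_examples=200, deadline=None)
    def test_plug_in_moments_never_violate_pearson_bound(self, xs):
        ms = product_moments(np.array(xs))
        assert ms.kurtosis >= kurtosis_lower_bound(ms.skewness) - 1e-7

    def test_sample_lmoment_ratios_respect_attainability_bound(self, rng):
        """The tau4 lower bound is a population property; samples of size 50
        from continuous families respect it in practice (tiny, tied or
        two-cluster samples can dip below it, so this is a distributional
        check, not an algebraic one)."""
        from exprdist.moments import _lmoments_rows

        draws = np.vstack(
            [
                rng.normal(size=(4000, 50)),
                rng.lognormal(0, 1, (4000, 50)),
                rng.standard_exponential((4000, 50)),
                rng.uniform(size=(4000, 50)),
            ]
        )
        _, l2, tau3, tau4 = _lmoments_rows(draws)
        assert np.all(tau4 >= lmoment_tau4_lower_bound(tau3) - 1e-12)
        assert np.all(np.abs(tau3) < 1.0)

    @given(finite_samples)
    @settings(max_examples=100, deadline=None)
    def test_negation_flips_l_skewness_only(self, xs):
        x = np.array(xs)
        _, l2a, t3a, t4a = sample_lmoments(x)
        _, l2b, t3b, t4b = sample_lmoments(-x)
        if l2a > 0:
            assert t3b == pytest.approx(-t3a, abs=1e-9)
            assert t4b == pytest.approx(t4a, abs=1e-9)
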