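"""Correlation, effect sizes, reliability, and exact power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facesym import (
    cohen_class,
    correlation_sample_size,
    correlation_table,
    dahlberg_tem,
    exact_correlation_power,
    icc_absolute_agreement,
    landis_koch_label,
    pearson,
    r2_matrix,
    reliability_coefficient,
)
from facesym.stats import UndefinedCorrelationError, fisher_z_sample_size


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        s = pearson(x, 2 * x + 1)
        assert s.r == pytest.approx(1.0)
        assert s.r_squared == pytest.approx(1.0)
        assert s.effect_class == "substantial"

    def test_orthogonal_vectors_give_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson(x, y).r == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        s = pearson(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert s.r == pytest.approx(num / den, abs=1e-12)
        assert s.r_squared == pytest.approx(s.r**2, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        assert pearson(a * x + b, y).r == pytest.approx(pearson(x, y).r, abs=1e-9)


class TestCohenClass:
    @pytest.mark.parametrize(
        "r2,expected",
        [
            (0.186, "moderate"),   # published midface maximum
            (0.630, "substantial"),  # published menton-deviation effect
            (0.019, "very_weak"),
            (0.02, "weak"),
            (0.13, "moderate"),
            (0.26, "substantial"),
            (0.1299999, "weak"),
        ],
    )
    def test_half_open_boundaries(self, r2, expected):
        assert cohen_class(r2) == expected

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            cohen_class(1.2)
        with pytest.raises(ValueError):
            cohen_class(-0.01)


class TestReliability:
    def test_tem_closed_forms(self):
        assert dahlberg_tem([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        assert dahlberg_tem(x1 + 1.0, x1) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_tem_homogeneity_under_unit_change(self):
        x1 = np.array([1.0, 2.5, 3.0])
        x2 = np.array([1.2, 2.1, 3.3])
        assert dahlberg_tem(10 * x1, 10 * x2) == pytest.approx(
            10 * dahlberg_tem(x1, x2), abs=1e-12
        )

    def test_reliability_coefficient_values(self):
        assert reliability_coefficient(0.0, 3.0) == 1.0
        assert reliability_coefficient(2.0, 4.0) == 0.0
        assert reliability_coefficient(0.5, 4.0) == pytest.approx(0.9375)
        with pytest.raises(ValueError):
            reliability_coefficient(1.0, 0.0)

    def test_icc_identical_columns(self):
        x = np.column_stack([[1.0, 2.0, 3.0, 4.0]] * 2)
        icc, label = icc_absolute_agreement(x)
        assert icc == pytest.approx(1.0)
        assert label == "almost_perfect"

    def test_icc_matches_anova_oracle(self):
        X = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        icc, _ = icc_absolute_agreement(X)
        # explicit two-way ANOVA decomposition, written out independently
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((X.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((X - X.mean(1, keepdims=True) - X.mean(0) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc == pytest.approx(expected, abs=1e-12)

    def test_icc_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = rng.normal(10, 3, 8)
        X = np.column_stack([vals + rng.normal(0, 1, 8), vals + rng.normal(0, 1, 8)])
        icc, _ = icc_absolute_agreement(X)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 2),
                "rater": np.tile([0, 1], 8),
                "score": X.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        expected = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc == pytest.approx(expected, abs=1e-9)

    def test_absolute_agreement_penalizes_bias(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, _ = icc_absolute_agreement(np.column_stack([x, x + 50.0]))
        assert icc < 0.2

    @pytest.mark.parametrize(
        "icc,label",
        [(-0.1, "poor"), (0.1, "slight"), (0.3, "fair"), (0.5, "moderate"),
         (0.7, "substantial"), (0.9, "almost_perfect")],
    )
    def test_landis_koch_bands(self, icc, label):
        assert landis_koch_label(icc) == label


class TestSampleSize:
    def test_exact_bivariate_normal_value(self):
        assert correlation_sample_size(0.50, 0.05, 0.80, two_tailed=True) == 29

    def test_exact_and_fisher_z_differ_by_at_most_one(self):
        exact = correlation_sample_size(0.50, 0.05, 0.80)
        approx = fisher_z_sample_size(0.50, 0.05, 0.80)
        assert approx == 30
        assert abs(exact - approx) <= 1

    def test_monotone_in_effect_size_and_alpha(self):
        n_small = correlation_sample_size(0.99)
        n_mid = correlation_sample_size(0.70)
        n_big = correlation_sample_size(0.50)
        assert n_small <= n_mid <= n_big
        assert n_small <= 8
        assert correlation_sample_size(0.50, alpha=0.10) <= n_big

    def test_power_brackets_the_target_at_the_returned_n(self):
        n = correlation_sample_size(0.50, 0.05, 0.80)
        assert exact_correlation_power(0.50, n) >= 0.80
        assert exact_correlation_power(0.50, n - 1) < 0.80

    def test_monte_carlo_power_agrees_with_exact_density(self):
        """Simulation oracle for the exact r-density integration."""
        from scipy import stats as sps

        n, reps, rho = 29, 50_000, 0.5
        rng = np.random.default_rng(42)
        x = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        tcrit = sps.t.ppf(0.975, n - 2)
        rcrit = tcrit / np.sqrt(n - 2 + tcrit**2)
        mc_power = np.mean(np.abs(r) > rcrit)
        exact = exact_correlation_power(rho, n)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(mc_power - exact) < 4 * se
        assert mc_power >= 0.80 - 4 * se


class TestCorrelationTable:
    def _cohort(self, n=400, seed=5):
        rng = np.random.default_rng(seed)
        me = rng.normal(4, 3, n)
        return pd.DataFrame(
            {
                "midline_me": me,
                "ang_mea": rng.normal(3, 2, n),
                "volume_whole": 2.0 * me + 1.0,
                "volume_mid": rng.normal(2, 3, n),
                "volume_lower": rng.normal(8, 6, n),
            }
        )

    def test_exact_linear_dependence_gives_unit_r2(self):
        table = correlation_table(self._cohort())
        cell = table[(table.variable == "midline_me") & (table.region == "whole")]
        assert cell.r_squared.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert cell.stars.iloc[0] == "**"

    def test_independent_columns_give_near_zero_r2(self):
        table = correlation_table(self._cohort(n=5000))
        cell = table[(table.variable == "ang_mea") & (table.region == "lower")]
        assert cell.r_squared.iloc[0] < 0.01

    def test_missing_columns_is_schema_error(self):
        with pytest.raises(KeyError, match="volume_lower"):
            correlation_table(self._cohort().drop(columns=["volume_lower"]))

    def test_degenerate_volume_column_reports_undefined(self):
        cohort = self._cohort()
        cohort["volume_mid"] = 0.0
        table = correlation_table(cohort)
        cell = table[(table.variable == "midline_me") & (table.region == "mid")]
        assert cell.effect_class.iloc[0] == "undefined"
        assert cell.stars.iloc[0] == ""

    def test_bh_adjustment_is_monotone(self):
        table = correlation_table(self._cohort(), bh_correction=True)
        assert (table.p_adjusted >= table.p_value - 1e-15).all()

    def test_r2_matrix_shape_and_order(self):
        mat = r2_matrix(correlation_table(self._cohort()))
        assert list(mat.index) == ["midline_me", "ang_mea"]
        assert list(mat.columns) == ["whole", "mid", "lower"]
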