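"""Inverted-U model tests: KS gate, OLS fits, nested comparison, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cesdr_mobile import CohortConfig, LatencySchemaModel
from cesdr_mobile.schema_model import (
    compare_trends,
    ks_normality,
    polyfit_ols,
    residual_diagnostics,
)
from cesdr_mobile.simulate import simulate_cohort

from conftest import fit_cohort


def normal_equations_oracle(score, rt, degree):
    """Brute-force OLS through the normal equations."""
    X = np.vander(np.asarray(score, float), degree + 1, increasing=True)
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(rt, float))
    fitted = X @ beta
    resid = rt - fitted
    ss_res = (resid**2).sum()
    ss_tot = ((rt - np.mean(rt)) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    return beta, r2


class TestKSNormality:
    def test_edf_hugging_construction(self):
        n = 100
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        res = ks_normality(x, mean=0.0, sd=1.0)
        assert res.stat < 0.02

    def test_uniform_sample_strongly_rejected(self):
        rng = np.random.default_rng(10)
        res = ks_normality(rng.uniform(0, 1, 1000))
        assert res.p_value < 1e-3

    def test_duplication_identity_with_fixed_reference(self):
        rng = np.random.default_rng(11)
        x = rng.normal(2.0, 3.0, 80)
        a = ks_normality(x, mean=2.0, sd=3.0)
        b = ks_normality(np.concatenate([x, x]), mean=2.0, sd=3.0)
        assert b.stat == pytest.approx(a.stat, abs=1e-12)
        assert b.z == pytest.approx(a.z * math.sqrt(2), abs=1e-9)

    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(12)
        res = ks_normality(rng.normal(5.0, 2.0, 200))
        assert res.p_value > 0.05
        assert res.z == pytest.approx(math.sqrt(res.n) * res.stat)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ks_normality(np.full(20, 1.0))

    def test_lilliefors_flag_returns_probability(self):
        rng = np.random.default_rng(13)
        res = ks_normality(rng.normal(0, 1, 100), lilliefors=True)
        assert 0.0 <= res.p_value <= 1.0


class TestPolyfit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        fit = polyfit_ols(x, 2 + 3 * x, 1)
        assert fit.params == pytest.approx([2.0, 3.0], abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_parabola_symmetry(self):
        x = np.arange(-2.0, 3.0)
        quad = polyfit_ols(x, x**2, 2)
        assert quad.params == pytest.approx([0.0, 0.0, 1.0], abs=1e-10)
        assert quad.r_squared == pytest.approx(1.0)
        lin = polyfit_ols(x, x**2, 1)
        assert lin.params[1] == pytest.approx(0.0, abs=1e-10)
        assert lin.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            x = rng.uniform(0, 30, 10)
            y = rng.normal(0, 5, 10) + 0.3 * x
            for degree in (1, 2):
                fit = polyfit_ols(x, y, degree)
                beta, r2 = normal_equations_oracle(x, y, degree)
                assert fit.params == pytest.approx(beta, abs=1e-8)
                assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_f_statistic_identity(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(0, 20, 40)
        y = 1000 - 3 * (x - 9) ** 2 + rng.normal(0, 80, 40)
        for degree in (1, 2):
            fit = polyfit_ols(x, y, degree)
            expect = (fit.r_squared / fit.df_model) / ((1 - fit.r_squared) / fit.df_resid)
            assert fit.f_stat == pytest.approx(expect, rel=1e-9)
            assert fit.df_model == degree
            assert fit.df_resid == len(x) - degree - 1
            assert abs(fit.residuals.sum()) < 1e-6

    @pytest.mark.parametrize(
        "score, rt, degree, match",
        [
            ([1, 1, 1, 2, 2], [1, 2, 3, 4, 5], 2, "rank-deficient"),
            ([1, 2, 3], [1, 2, 3], 2, "n > degree"),
            ([1, 2, 3, 4], [1, 2, 3, 4], 3, "degree"),
        ],
    )
    def test_degenerate_designs_rejected(self, score, rt, degree, match):
        with pytest.raises(ValueError, match=match):
            polyfit_ols(score, rt, degree)


class TestCompareTrends:
    def test_zero_increment_prefers_linear(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(0, 10, 30)
        y = rng.normal(0, 1, 30) + x
        quad = polyfit_ols(x, y, 2)
        # strip the quadratic component: both fits now coincide exactly
        y2 = y - quad.params[2] * x**2
        lin2 = polyfit_ols(x, y2, 1)
        quad2 = polyfit_ols(x, y2, 2)
        cmp = compare_trends(lin2, quad2)
        assert cmp.delta_r2 == pytest.approx(0.0, abs=1e-12)
        assert cmp.delta_r2_f == pytest.approx(0.0, abs=1e-8)
        assert cmp.preferred == "linear"

    def test_mismatched_n_rejected(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, 30)
        y = rng.normal(0, 1, 30)
        lin = polyfit_ols(x[:20], y[:20], 1)
        quad = polyfit_ols(x, y, 2)
        with pytest.raises(ValueError, match="different n"):
            compare_trends(lin, quad)

    def test_inverted_u_cohort_prefers_quadratic(self):
        records, _ = simulate_cohort(CohortConfig(n_participants=500, seed=18))
        results = fit_cohort(records)
        assert results.preferred == "quadratic"
        assert results.comparison.quad_coefficient_sign == "negative"
        assert results.quadratic.r_squared >= results.linear.r_squared

    def test_nested_r2_dominance_random_data(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            x = rng.uniform(0, 25, 20)
            y = rng.normal(0, 1, 20)
            assert polyfit_ols(x, y, 2).r_squared >= polyfit_ols(x, y, 1).r_squared - 1e-12


class TestResidualDiagnostics:
    def test_perfect_fit_unflagged(self):
        x = np.arange(10.0)
        fit = polyfit_ols(x, 1 + 2 * x, 1)
        table = residual_diagnostics(fit)
        assert np.allclose(table["residual"], 0.0, atol=1e-9)
        assert not table["outlier"].any()

    def test_injected_extreme_point_flagged(self):
        rng = np.random.default_rng(20)
        x = np.linspace(0, 10, 50)
        y = 5 + 2 * x + rng.normal(0, 1, 50)
        y[25] += 30.0
        table = residual_diagnostics(polyfit_ols(x, y, 1))
        assert table.loc[25, "outlier"]
        assert table["outlier"].sum() <= 3

    def test_quadratic_residuals_less_skewed_on_default_cohort(self, default_cohort):
        _, records, _ = default_cohort
        results = fit_cohort(records)
        skew_lin = sps.skew(results.linear.residuals)
        skew_quad = sps.skew(results.quadratic.residuals)
        assert abs(skew_quad) <= abs(skew_lin) + 0.1


class TestModelInterface:
    def test_from_dataframe_roundtrip(self, default_cohort):
        _, records, _ = default_cohort
        results = fit_cohort(records)
        d = results.to_dict()
        assert d["n"] == results.linear.nobs
        assert set(d) >= {"ks", "linear", "quadratic", "delta_r2_f", "preferred"}
        assert "Inverted-U" in results.summary()

    def test_residual_table_shapes(self, default_cohort):
        _, records, _ = default_cohort
        results = fit_cohort(records)
        table = results.residual_table()
        assert len(table) == results.linear.nobs
        assert {"fitted_linear", "residual_quadratic"} <= set(table.columns)

    def test_preferred_implies_significant_increment(self, default_cohort):
        _, records, _ = default_cohort
        results = fit_cohort(records, alpha=0.05)
        if results.preferred == "quadratic":
            assert results.comparison.delta_r2_p < 0.05

    def test_vertex_recovery_within_confidence_band(self):
        """Fitting the quadratic against the latent expected total (the axis
        the latency curve is defined on, recorded in the truth sidecar)
        recovers the known vertex within its 95% delta-method confidence
        band in at least 90% of replicates at n=500. Severity spread is kept
        moderate so the latency law stays in its positive range."""
        import pandas as pd

        from cesdr_mobile.rt import rt_profiles

        hits = 0
        reps = 40
        for rep in range(reps):
            config = CohortConfig(n_participants=500, severity_sd=0.75, seed=700_000 + rep)
            records, truth = simulate_cohort(config)
            profiles = rt_profiles(records)
            merged = profiles.merge(
                pd.DataFrame(
                    {
                        "participant_id": truth["participant_id"],
                        "expected_total": truth["expected_total"],
                    }
                ),
                on="participant_id",
            )
            x = merged["expected_total"].to_numpy()
            q = polyfit_ols(x, merged["mean_centered_rt"].to_numpy(), 2)
            b1, b2 = q.params[1], q.params[2]
            v = -b1 / (2 * b2)
            # delta-method SE of -b1/(2*b2) with the full coefficient covariance
            X = np.vander(x, 3, increasing=True)
            sigma2 = (q.residuals**2).sum() / q.df_resid
            cov = sigma2 * np.linalg.inv(X.T @ X)
            grad = np.array([0.0, -1 / (2 * b2), b1 / (2 * b2**2)])
            se_v = math.sqrt(grad @ cov @ grad)
            if abs(v - config.rt_quad_center) <= 1.96 * se_v:
                hits += 1
        assert hits / reps >= 0.9
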