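import numpy as np
import pandas as pd
import pytest

from cse_recall.cse_pcr import (
    comparison_table,
    cse_contributions,
    explanatory_correlations,
    fit_cse,
    pca_explanatory,
    subgroup_cse,
)
from cse_recall.errors import DegeneratePCAError, ParameterError


class TestPcaExplanatory:
    def test_reference_pc1_loadings(self, explanatory15):
        pc1 = pca_explanatory(explanatory15).component(1)
        assert round(pc1["primacy"], 2) == 0.77
        assert round(pc1["recency"], 2) == -0.64
        assert round(pc1["frequency"], 2) == 0.02

    def test_single_variable(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0, 7.0]})
        res = pca_explanatory(df)
        assert res.loadings == pytest.approx(np.array([[1.0]]))
        assert res.eigenvalues[0] == pytest.approx(df["x"].var(ddof=1))

    def test_two_anticorrelated_equal_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"a": x, "b": -x})
        res = pca_explanatory(df)
        assert np.abs(res.loadings[:, 0]) == pytest.approx([1 / np.sqrt(2)] * 2)
        assert res.loadings[0, 0] > 0 and res.loadings[1, 0] < 0
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_loadings_and_eigenvalue_sum(self, explanatory15):
        res = pca_explanatory(explanatory15)
        V = res.loadings
        assert V.T @ V == pytest.approx(np.eye(3), abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        total_var = np.var(explanatory15.variable_matrix(), axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var)

    def test_correlation_mode_symmetric_loadings(self, explanatory15):
        res = pca_explanatory(explanatory15, mode="correlation")
        # standardized primacy/recency dominate symmetrically (~1/sqrt(2))
        pc1 = res.component(1)
        assert abs(abs(pc1["primacy"]) - abs(pc1["recency"])) < 0.05

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"c": np.ones(5)})
        with pytest.raises(DegeneratePCAError):
            pca_explanatory(df)

    def test_bad_mode(self, explanatory15):
        with pytest.raises(ParameterError):
            pca_explanatory(explanatory15, mode="svd")


class TestExplanatoryCorrelations:
    def test_primacy_recency(self, explanatory15):
        corr = explanatory_correlations(explanatory15)
        assert round(corr.loc["primacy", "recency"], 2) == -0.94

    def test_recency_frequency(self, explanatory15):
        corr = explanatory_correlations(explanatory15)
        assert round(corr.loc["recency", "frequency"], 2) == -0.18

    def test_diagonal_unity(self, explanatory15):
        corr = explanatory_correlations(explanatory15)
        assert np.diag(corr) == pytest.approx(np.ones(3))


class TestFitCse:
    def test_reference_coefficients_and_r(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15, U_delta=table1.U_delta)
        assert round(m.pearson_r, 2) == 0.80
        assert round(m.intercept) == 5
        assert round(m.coefficients[0], 1) == 0.7  # primacy
        assert round(m.coefficients[1], 1) == 0.8  # recency
        assert round(m.coefficients[2], 1) == 0.2  # frequency

    def test_fitted_item1(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15)
        assert round(m.fitted[0], 2) == -0.80

    def test_perfect_linear_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": rng.normal(size=10)})
        y = 2.0 + 3.0 * x
        m = fit_cse(y, df)
        assert m.coefficients[0] == pytest.approx(3.0, abs=1e-10)
        assert m.coefficients[1] == pytest.approx(0.0, abs=1e-10)
        assert m.intercept == pytest.approx(2.0, abs=1e-10)
        assert m.pearson_r == pytest.approx(1.0)

    def test_pcr_full_rank_equals_ols(self, rng):
        for _ in range(5):
            X = rng.normal(size=(12, 3))
            y = rng.normal(size=12)
            m = fit_cse(y, pd.DataFrame(X, columns=list("abc")))
            A = np.column_stack([np.ones(12), X])
            beta_ols, *_ = np.linalg.lstsq(A, y, rcond=None)
            fitted_ols = A @ beta_ols
            assert np.max(np.abs(m.fitted - fitted_ols)) < 1e-10
            assert m.intercept == pytest.approx(beta_ols[0])
            assert m.coefficients == pytest.approx(beta_ols[1:])

    def test_r_squared_variance_identity(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15)
        r2 = m.pearson_r**2
        ratio = np.var(m.fitted) / np.var(table1.delta)
        assert r2 == pytest.approx(ratio, abs=1e-10)
        assert 0.6 < r2 < 0.68  # ~0.64 on the reference inputs

    def test_fitted_mean_equals_input_mean(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15)
        assert m.fitted.mean() == pytest.approx(table1.delta.mean(), abs=1e-12)

    def test_dropping_smallest_component_never_raises_r(self, table1, explanatory15):
        full = fit_cse(table1.delta, explanatory15, n_components=3)
        reduced = fit_cse(table1.delta, explanatory15, n_components=2)
        assert reduced.pearson_r <= full.pearson_r + 1e-12

    def test_uncertainties_positive_and_k2(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15, U_delta=table1.U_delta)
        assert m.U_intercept > 0
        assert np.all(m.U_coefficients > 0)
        assert np.all(m.U_fitted > 0)
        # measurement uncertainty strictly widens the bands
        m0 = fit_cse(table1.delta, explanatory15)
        assert np.all(m.U_coefficients >= m0.U_coefficients)

    def test_equation_rendering_style(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15, U_delta=table1.U_delta)
        eq = m.equation()
        assert eq.startswith("+5(")
        assert "*primacy" in eq and "*recency" in eq

    def test_too_many_components(self, table1, explanatory15):
        with pytest.raises(ParameterError):
            fit_cse(table1.delta, explanatory15, n_components=4)

    def test_too_few_items(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 4.0]})
        with pytest.raises(ParameterError):
            fit_cse([0.1, 0.2, 0.3], df)


class TestContributions:
    def test_terms_sum_to_fitted(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15)
        contrib = cse_contributions(m, explanatory15)
        assert contrib["z_R"].to_numpy() == pytest.approx(m.fitted, abs=1e-12)

    def test_zero_regressor_terms(self, table1, explanatory15):
        m = fit_cse(table1.delta, explanatory15)
        contrib = cse_contributions(m, explanatory15)
        assert contrib.loc[0, "primacy"] == 0.0  # item 1: primacy variable 0
        assert contrib.loc[14, "recency"] == 0.0  # item 15: recency variable 0


class TestSubgroupCse:
    def test_identical_groups_identical_models(self, table1, explanatory15):
        models = subgroup_cse(
            {"a": table1.delta, "b": table1.delta.copy()}, explanatory15
        )
        assert models["a"].coefficients == pytest.approx(models["b"].coefficients)
        assert models["a"].intercept == pytest.approx(models["b"].intercept)

    def test_constant_shift_moves_intercept_only(self, table1, explanatory15):
        models = subgroup_cse(
            {"base": table1.delta, "shifted": table1.delta + 2.0}, explanatory15
        )
        assert models["shifted"].intercept - models["base"].intercept == pytest.approx(2.0)
        assert models["shifted"].coefficients == pytest.approx(models["base"].coefficients)

    def test_primacy_benefit_removed_raises_intercept(self, table1, design15):
        # simulate two groups, one with the primacy benefit removed, fit Rasch
        # per group and compare fitted CSE intercepts
        from cse_recall.rasch_core import fit_rasch
        from cse_recall.synthetic_cohort import CohortSpec, GroupSpec, simulate_cohort

        deltas = {}
        for label, shifts in (("healthy", {}), ("impaired", {"Pr": 2.0})):
            spec = CohortSpec.from_design(
                groups=[GroupSpec(label, 800, -0.6, 1.0, region_shifts=shifts)],
                design=design15,
                base_difficulties=table1.delta,
                seed=99,
            )
            matrix, _ = simulate_cohort(spec)
            deltas[label] = fit_rasch(matrix).delta
        X = table1.explanatory()
        models = subgroup_cse(deltas, X)
        # removing the primacy benefit flattens the primacy slope; with the
        # centered-difficulty convention this lifts the intercept contribution
        # of the (negative-mean) primacy column
        healthy_b, impaired_b = models["healthy"], models["impaired"]
        assert impaired_b.coefficients[0] < healthy_b.coefficients[0]

    def test_comparison_table_shape(self, table1, explanatory15):
        models = subgroup_cse({"a": table1.delta, "b": table1.delta + 1}, explanatory15)
        tab = comparison_table(models)
        assert tab.shape == (4, 4)  # 4 terms x (2 groups x value/U)
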