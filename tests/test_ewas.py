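import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from liverewas.ewas import (
    _CHI2_1_MEDIAN,
    benjamini_hochberg,
    empirical_null_correct,
    fit_cpg_model,
    genomic_inflation_lambda,
    run_ewas,
    stratified_ewas,
)


def _bh_oracle(p):
    """Textbook step-up BH: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestFitCpgModel:
    def test_noiseless_construction_recovered_exactly(self, rng):
        n = 200
        x = rng.normal(0.5, 0.05, n)
        C = rng.normal(0, 1, (n, 3))
        y = 2.0 * x + C @ np.array([1.0, -0.5, 0.3]) + 4.0
        fit = fit_cpg_model(y, x, C)
        assert fit["effect"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n, k = 20, 3
        x = rng.normal(0, 1, n)
        C = rng.normal(0, 1, (n, k))
        y = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x, C])
        beta_oracle = np.linalg.pinv(X) @ y
        fit = fit_cpg_model(y, x, C)
        assert fit["effect"] == pytest.approx(beta_oracle[1], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        """p-values under a permuted outcome follow U(0,1)."""
        n, n_cpgs = 500, 2000
        M = pd.DataFrame(
            rng.beta(5, 5, (n_cpgs, n)), columns=[f"s{i}" for i in range(n)]
        )
        y = pd.Series(rng.normal(0, 1, n), index=M.columns)
        res = run_ewas(M, y, covariates=None)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficient_design_names_columns(self, rng):
        n = 50
        x = rng.normal(0, 1, n)
        C = pd.DataFrame({"a": rng.normal(0, 1, n)})
        C["a_copy"] = C["a"]
        with pytest.raises(np.linalg.LinAlgError, match="a_copy"):
            fit_cpg_model(rng.normal(0, 1, n), x, C)

    def test_missing_rows_dropped(self, rng):
        n = 100
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        y[:5] = np.nan
        fit = fit_cpg_model(y, x)
        assert fit["n"] == 95


class TestLambda:
    def test_standard_normal_z_near_one(self, rng):
        lam = genomic_inflation_lambda(z=rng.normal(0, 1, 100_000))
        assert 0.97 <= lam <= 1.03

    def test_scales_with_variance_ratio(self, rng):
        lam = genomic_inflation_lambda(z=rng.normal(0, 1.2, 100_000))
        assert 1.38 <= lam <= 1.50  # 1.2^2 = 1.44

    def test_exactly_one_at_null_median(self):
        z = np.full(500, np.sqrt(_CHI2_1_MEDIAN))
        assert genomic_inflation_lambda(z=z) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_tests_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation_lambda(z=np.ones(10))


class TestEmpiricalNull:
    def test_pure_null_estimates_near_identity(self, rng):
        en = empirical_null_correct(rng.normal(0, 1, 10_000), seed=1)
        assert -0.05 <= en.bias <= 0.05
        assert 0.95 <= en.inflation <= 1.05

    @pytest.mark.parametrize("bias", [0.0, 0.1])
    @pytest.mark.parametrize("inflation", [1.0, 1.3, 1.5])
    def test_parameter_recovery_grid(self, bias, inflation):
        rng = np.random.default_rng(int(100 * bias + 10 * inflation))
        z0 = rng.normal(bias, inflation, 9_500)
        za = np.concatenate([rng.normal(6, 1, 250), rng.normal(-6, 1, 250)])
        en = empirical_null_correct(np.concatenate([z0, za]), seed=1)
        assert en.bias == pytest.approx(bias, abs=0.05)
        assert en.inflation == pytest.approx(inflation, abs=0.1)

    def test_double_correction_is_idempotent(self, rng):
        z = rng.normal(0.1, 1.3, 10_000)
        first = empirical_null_correct(z, seed=1)
        second = empirical_null_correct(first.z_corrected, seed=1)
        assert second.bias == pytest.approx(0.0, abs=0.05)
        assert second.inflation == pytest.approx(1.0, abs=0.05)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    @given(
        st.lists(
            st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=20
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, pvals):
        got = benjamini_hochberg(pvals)
        np.testing.assert_allclose(got, _bh_oracle(pvals), atol=1e-12)

    def test_monotone_in_ranked_p(self, rng):
        p = rng.uniform(1e-8, 1, 500)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])


class TestRunEwas:
    def test_planted_effect_reaches_fdr_significance(self, rng):
        """A 3-residual-SD slope at n=1500 must attain q < 0.05."""
        n, n_cpgs = 1500, 500
        M = pd.DataFrame(
            rng.beta(5, 5, (n_cpgs, n)),
            index=[f"cg{i}" for i in range(n_cpgs)],
            columns=[f"s{i}" for i in range(n)],
        )
        x = M.iloc[0].to_numpy()
        y = pd.Series(
            3.0 * (x - x.mean()) / x.std() + rng.normal(0, 1, n), index=M.columns
        )
        res = run_ewas(M, y)
        assert res.table["q"].iloc[0] < 0.05

    def test_delta_beta_is_crude_group_difference(self, rng):
        n, n_cpgs = 200, 120
        M = pd.DataFrame(
            rng.beta(5, 5, (n_cpgs, n)), columns=[f"s{i}" for i in range(n)]
        )
        y = pd.Series(np.repeat([1, 0], [80, 120]), index=M.columns)
        cov = pd.DataFrame({"c": rng.normal(0, 1, n)}, index=M.columns)
        res_adj = run_ewas(M, y, cov, binary=True)
        res_crude = run_ewas(M, y, binary=True)
        cases = M.columns[:80]
        controls = M.columns[80:]
        expected = M[cases].mean(axis=1) - M[controls].mean(axis=1)
        np.testing.assert_allclose(res_adj.table["delta_beta"], expected, atol=1e-12)
        # delta_beta ignores covariates by construction
        np.testing.assert_allclose(
            res_adj.table["delta_beta"], res_crude.table["delta_beta"], atol=1e-12
        )

    def test_constant_cpg_reported_missing_not_crash(self, rng):
        n, n_cpgs = 150, 120
        M = pd.DataFrame(
            rng.beta(5, 5, (n_cpgs, n)), columns=[f"s{i}" for i in range(n)]
        )
        M.iloc[3] = 0.5
        res = run_ewas(M, pd.Series(rng.normal(0, 1, n), index=M.columns))
        assert np.isnan(res.table["p"].iloc[3])
        assert np.isfinite(res.table["p"].drop(res.table.index[3])).all()

    def test_inflated_scores_trigger_correction(self, rng):
        """Inflated statistics trigger the empirical-null correction and
        the corrected lambda moves toward 1."""
        n, n_cpgs = 300, 1200
        M = pd.DataFrame(
            rng.beta(5, 5, (n_cpgs, n)), columns=[f"s{i}" for i in range(n)]
        )
        # a latent factor shared by outcome and all CpGs inflates lambda
        u = rng.normal(0, 1, n)
        M = M + 0.02 * u
        y = pd.Series(u + rng.normal(0, 1, n), index=M.columns)
        res = run_ewas(M, y, correction_min_tests=1000)
        assert res.lambda_raw > 1.1
        assert res.correction_applied
        assert abs(res.lambda_corrected - 1.0) < abs(res.lambda_raw - 1.0)


class TestStratifiedEwas:
    def _toy(self, rng, n=900):
        M = pd.DataFrame(
            rng.beta(5, 5, (120, n)), columns=[f"s{i}" for i in range(n)]
        )
        y = pd.Series(rng.normal(0, 1, n), index=M.columns)
        return M, y

    def test_constant_stratifier_matches_unstratified(self, rng):
        M, y = self._toy(rng)
        strata = pd.Series("all", index=M.columns)
        res = stratified_ewas(M, y, None, strata)
        base = run_ewas(M, y)
        pd.testing.assert_frame_equal(res["all"].table, base.table)

    def test_effect_planted_in_one_stratum_only(self, rng):
        M, y = self._toy(rng, n=1200)
        strata = pd.Series(
            np.repeat(["excess", "none"], 600), index=M.columns
        )
        x = M.iloc[0]
        mask = strata == "excess"
        y = y.copy()
        y[mask] += 4.0 * (x[mask] - x[mask].mean()) / x[mask].std()
        res = stratified_ewas(M, y, None, strata)
        assert res["excess"].table["q"].iloc[0] < 0.05
        assert res["none"].table["q"].iloc[0] > 0.05

    def test_paper_scale_stratum_sizes_run(self, rng):
        """Stratum sizes like the alcohol-stratified analysis (333/1269/131)."""
        n = 333 + 1269 + 131
        M, y = self._toy(rng, n=n)
        strata = pd.Series(
            np.repeat(["none", "moderate", "excess"], [333, 1269, 131]),
            index=M.columns,
        )
        res = stratified_ewas(M, y, None, strata)
        assert set(res) == {"none", "moderate", "excess"}
        assert res["excess"].notes["stratum_n"] == 131

    def test_tiny_stratum_skipped(self, rng):
        M, y = self._toy(rng, n=300)
        strata = pd.Series(["big"] * 290 + ["tiny"] * 10, index=M.columns)
        res = stratified_ewas(M, y, None, strata, min_n=50)
        assert "tiny" not in res
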