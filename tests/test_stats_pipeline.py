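"""Screening, clustering, OLS identities, power, bootstrap robustness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from exostrength import (
    BootstrapSpec,
    SelectionCriteria,
    bootstrap_validate,
    cluster_metrics,
    correlation_matrix,
    fit_ols,
    normality_test,
    posthoc_power,
    residual_diagnostics,
    select_variables,
)
from exostrength.muscle_parameters import CohortStandardizer
import statsmodels.api as sm


class TestNormality:
    def test_lognormal_rejected_most_seeds(self):
        hits = 0
        for seed in range(40):
            x = np.exp(np.random.default_rng(seed).standard_normal(30))
            _, p = normality_test(x)
            hits += p < 0.05
        assert hits >= 0.8 * 40

    def test_type_one_error_near_alpha(self):
        rejections = 0
        n_trials = 400
        for seed in range(n_trials):
            x = np.random.default_rng(10_000 + seed).standard_normal(30)
            _, p = normality_test(x)
            rejections += p < 0.05
        rate = rejections / n_trials
        assert 0.02 <= rate <= 0.09  # alpha = 0.05 +- Monte-Carlo error

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0] * 10)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "neg_x": -x, "y": rng.standard_normal(50)})
        corr = correlation_matrix(df)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg_x"] == pytest.approx(-1.0)
        assert corr.equals(corr.T)

    def test_pairwise_complete_handling(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, np.nan], "b": [2.0, 4, 6, np.nan, 10]}
        )
        corr = correlation_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)


class TestClustering:
    def test_perfectly_correlated_pair_co_clusters(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]],
            columns=list("abc"), index=list("abc"),
        )
        res = cluster_metrics(corr, SelectionCriteria())
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_block_diagonal_gives_two_clusters(self):
        cols = list("abcd")
        m = np.full((4, 4), 0.0)
        m[:2, :2] = 0.9
        m[2:, 2:] = 0.9
        np.fill_diagonal(m, 1.0)
        corr = pd.DataFrame(m, columns=cols, index=cols)
        res = cluster_metrics(corr, SelectionCriteria())
        assert len(set(res.labels.values())) == 2

    def test_single_metric_singleton(self):
        corr = pd.DataFrame([[1.0]], columns=["a"], index=["a"])
        res = cluster_metrics(corr, SelectionCriteria())
        assert res.labels == {"a": 1}


class TestResidualDiagnostics:
    @staticmethod
    def _fit(x, y):
        X = sm.add_constant(x)
        return sm.OLS(y, X).fit(), X

    def test_homoscedastic_model_passes_most_seeds(self):
        both_pass = 0
        n_trials = 30
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 60)
            y = 1 + 2 * x + rng.standard_normal(60)
            fit, X = self._fit(x, y)
            sh_p, bp_p = residual_diagnostics(fit.resid, X)
            both_pass += (sh_p > 0.05) and (bp_p > 0.05)
        assert both_pass >= 0.6 * n_trials

    def test_variance_growing_with_x_detected(self):
        detected = 0
        n_trials = 30
        for seed in range(n_trials):
            rng = np.random.default_rng(100 + seed)
            x = rng.uniform(0.5, 10, 80)
            y = 1 + 2 * x + (0.5 * x**2) * rng.standard_normal(80)
            fit, X = self._fit(x, y)
            _, bp_p = residual_diagnostics(fit.resid, X)
            detected += bp_p < 0.05
        assert detected >= 0.6 * n_trials

    def test_exact_linear_data_degenerate(self):
        x = np.arange(20.0)
        y = 3 * x + 1
        fit, X = self._fit(x, y)
        with pytest.raises(ValueError, match="degenerate"):
            residual_diagnostics(fit.resid, X)


class TestSelectVariables:
    def _table(self, rng, n=40):
        latent = rng.standard_normal(n)
        return pd.DataFrame(
            {
                "target": latent + 0.3 * rng.standard_normal(n),
                "good": latent + 0.5 * rng.standard_normal(n),
                "lognormal": np.exp(2.0 * rng.standard_normal(n)),
            }
        )

    def test_lognormal_dropped_at_normality_stage(self):
        table = self._table(np.random.default_rng(0))
        kept, audit = select_variables(table, "target")
        assert "lognormal" not in kept
        reasons = {a.column: a.stage for a in audit if a.stage == "normality"}
        assert "lognormal" in reasons

    def test_redundant_pair_keeps_one(self):
        rng = np.random.default_rng(1)
        n = 40
        latent = rng.standard_normal(n)
        a = latent + 0.2 * rng.standard_normal(n)
        table = pd.DataFrame(
            {
                "target": latent + 0.3 * rng.standard_normal(n),
                "a": a,
                "b": a + 0.05 * rng.standard_normal(n),  # |r| ~ 0.99 with a
            }
        )
        kept, _ = select_variables(table, "target")
        assert len([c for c in kept if c in ("a", "b")]) == 1

    def test_planted_three_cluster_design_returns_representatives(self):
        rng = np.random.default_rng(2)
        n = 60
        f1, f2, f3 = (rng.standard_normal(n) for _ in range(3))
        target = f1 + f2 + f3 + 0.5 * rng.standard_normal(n)
        table = pd.DataFrame({"target": target})
        for i, f in enumerate((f1, f2, f3)):
            table[f"m{i}a"] = f + 0.2 * rng.standard_normal(n)
            table[f"m{i}b"] = f + 0.2 * rng.standard_normal(n)
        kept, _ = select_variables(table, "target")
        assert len(kept) == 3
        assert {c[1] for c in kept} == {"0", "1", "2"}

    def test_empty_survivors_is_empty_result(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "target": rng.standard_normal(30),
                "skewed": np.exp(2 * rng.standard_normal(30)),
            }
        )
        kept, audit = select_variables(table, "target")
        assert kept == []
        assert audit


class TestFitOls:
    def test_exact_linear_fit(self):
        x = np.arange(30.0)
        table = pd.DataFrame({"y": 2 * x - 1, "x": x})
        m = fit_ols(table, "y", ["x"])
        assert m.R == pytest.approx(1.0)
        assert m.B[1] == pytest.approx(2.0)

    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        y = 0.8 * x + rng.standard_normal(30)
        table = pd.DataFrame({"y": y, "x": x})
        m = fit_ols(table, "y", ["x"])
        r = st.pearsonr(x, y).statistic
        assert m.beta[0] == pytest.approx(r, abs=1e-12)
        assert abs(m.beta[0]) == pytest.approx(m.R, abs=1e-10)

    def test_f2_identity_round_trip(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("yabc"))
        m = fit_ols(table, "y", ["a", "b", "c"])
        assert m.f2 == pytest.approx(m.r2 / (1 - m.r2), abs=1e-12)
        assert m.R == pytest.approx(math.sqrt(m.f2 / (1 + m.f2)), abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        # independent oracle: solve (X'X) b = X'y directly
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 5))
            y = X @ rng.standard_normal(5) + rng.standard_normal(30)
            cols = [f"x{i}" for i in range(5)]
            table = pd.DataFrame(X, columns=cols)
            table["y"] = y
            m = fit_ols(table, "y", cols)
            Xd = np.column_stack([np.ones(30), X])
            b_oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            assert m.B == pytest.approx(b_oracle, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(30.0)
        table = pd.DataFrame({"y": x + 1, "a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(table, "y", ["a", "b"])

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"y": [1.0, 2], "x": [0.0, 1]})
        with pytest.raises(ValueError):
            fit_ols(table, "y", ["x"])


class TestPower:
    def test_zero_effect_gives_alpha(self):
        assert posthoc_power(0.0, 30, 5, alpha=0.05) == pytest.approx(0.05)

    def test_large_effect_saturates(self):
        assert posthoc_power(3.57, 30, 5) >= 0.999

    def test_nondecreasing_in_n(self):
        powers = [posthoc_power(0.15, n, 3) for n in (10, 20, 40, 80, 160)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_invalid_dof_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power(0.2, 5, 5)


from tests_support_bootstrap import build_bootstrap_table as _make_table


def _bootstrap_table(rng, n=30):
    return _make_table(rng, n)


class TestBootstrap:
    def test_identity_configuration_reproduces_original_fit(self):
        table, std = _bootstrap_table(np.random.default_rng(6))
        base = fit_ols(table, "total_performance", ["Squat_IS_Max"])
        spec = BootstrapSpec(
            n_resamples=len(table), noise_fraction=0.0, n_repeats=3,
            resample=False, seed=1,
        )
        res = bootstrap_validate(
            table, "total_performance", ["Squat_IS_Max"], spec, std
        )
        assert res.mean_R == pytest.approx(base.R, abs=1e-12)
        assert res.sd_R == pytest.approx(0.0, abs=1e-12)

    def test_mean_r_non_increasing_in_noise(self):
        table, std = _bootstrap_table(np.random.default_rng(7))
        results = {}
        for frac in (0.10, 0.30):
            spec = BootstrapSpec(
                n_resamples=100, noise_fraction=frac, n_repeats=200, seed=42
            )
            results[frac] = bootstrap_validate(
                table, "total_performance", ["Squat_IS_Max"], spec, std
            ).mean_R
        assert results[0.30] <= results[0.10]

    def test_attenuation_matches_closed_form(self):
        # closed-form attenuation: SD-proportional noise scales the
        # predictor SD by sqrt(1+q^2); the recomputed composite gains
        # variance 3 q^2 (one q^2 per z-scored component), so
        # r -> r / (sqrt(1+q^2) * sqrt(1 + 3 q^2 / var(TP)))
        rng = np.random.default_rng(8)
        table, std = _bootstrap_table(rng, n=4000)
        r_pop = table["Squat_IS_Max"].corr(table["total_performance"])
        var_tp = table["total_performance"].var(ddof=1)
        q = 0.10
        expected = r_pop / (math.sqrt(1 + q**2) * math.sqrt(1 + 3 * q**2 / var_tp))
        spec = BootstrapSpec(
            n_resamples=4000, noise_fraction=q, n_repeats=30, seed=9
        )
        res = bootstrap_validate(
            table, "total_performance", ["Squat_IS_Max"], spec, std
        )
        assert res.mean_R == pytest.approx(expected, abs=0.02)

    def test_demographics_included_as_predictors(self):
        table, std = _bootstrap_table(np.random.default_rng(10))
        spec = BootstrapSpec(
            n_resamples=60, noise_fraction=0.1, n_repeats=5,
            include_demographics=True, seed=3,
        )
        res = bootstrap_validate(
            table, "total_performance", ["Squat_IS_Max"], spec, std
        )
        assert 0.0 <= res.mean_R <= 1.0

    def test_zero_sd_column_rejected(self):
        table, std = _bootstrap_table(np.random.default_rng(11))
        table["Squat_IS_Max"] = 5.0
        spec = BootstrapSpec(n_resamples=30, noise_fraction=0.1, n_repeats=2, seed=1)
        with pytest.raises(ValueError, match="zero SD"):
            bootstrap_validate(table, "total_performance", ["Squat_IS_Max"], spec, std)

    def test_seed_reproducible(self):
        table, std = _bootstrap_table(np.random.default_rng(12))
        spec = BootstrapSpec(n_resamples=50, noise_fraction=0.2, n_repeats=10, seed=99)
        a = bootstrap_validate(table, "total_performance", ["Squat_IS_Max"], spec, std)
        b = bootstrap_validate(table, "total_performance", ["Squat_IS_Max"], spec, std)
        assert np.array_equal(a.R_values, b.R_values)
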