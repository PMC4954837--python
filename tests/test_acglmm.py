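"""Mixed-model fitting, AC terms, LRT, pruning and diagnostics."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from nigra import acglmm
from nigra.acglmm import (
    ModelSpec,
    RandomTerm,
    build_design,
    compute_ac_term,
    default_random_terms,
    fit_glmm,
    full_test_terms,
    lrt,
    prune_interactions,
    vif,
)
from nigra.errors import DataError
from nigra.studies import _glm_spec


def simulate_logit_table(
    n=2000, seed=0, beta=(0.5, -0.3), group_sd=0.0, n_groups=20, rho_cols=0.0
):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rho_cols * x1 + np.sqrt(1 - rho_cols**2) * rng.normal(size=n)
    g = rng.integers(0, n_groups, n)
    u = rng.normal(0, group_sd, n_groups)
    eta = -0.5 + beta[0] * x1 + beta[1] * x2 + u[g]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(
        {"response": y, "x1": x1, "x2": x2, "g": g, "day": rng.integers(0, 100, n),
         "infant": g % 7, "male": g % 5}
    )


def plain_spec(terms=("x1", "x2"), randoms=()):
    return ModelSpec(
        test_terms=list(terms), control_terms=[], offset=None,
        random_terms=list(randoms),
    )


class TestDesignMatrix:
    def test_interaction_columns_are_products(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        X, names = build_design(tab, ["a", "b", "a:b"])
        assert names == ["intercept", "a", "b", "a:b"]
        assert np.allclose(X[:, 3], [3.0, 8.0])

    def test_missing_column_reported(self):
        with pytest.raises(DataError, match="missing"):
            build_design(pd.DataFrame({"a": [1.0]}), ["a:zzz"])

    def test_canonical_term_counts(self):
        assert len(full_test_terms("infant")) == 13
        assert len(full_test_terms("male")) == 14


class TestPlainLogisticFit:
    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        tab = simulate_logit_table(seed=1)
        fit = fit_glmm(tab, plain_spec())
        X, _ = build_design(tab, ["x1", "x2"])
        oracle = sm.GLM(
            tab["response"].values, X, family=sm.families.Binomial()
        ).fit()
        assert np.abs(fit.params.values - oracle.params).max() < 1e-6
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-8)
        assert np.abs(fit.se.values - oracle.bse).max() < 1e-4

    def test_constant_column_rejected(self):
        tab = simulate_logit_table(seed=2)
        tab["flat"] = 1.0
        with pytest.raises(DataError, match="constant"):
            fit_glmm(tab, plain_spec(terms=("x1", "flat")))


class TestMixedFit:
    def test_zero_variance_reduces_to_plain_fit(self):
        tab = simulate_logit_table(seed=3, group_sd=0.0, n=1500)
        plain = fit_glmm(tab, plain_spec())
        mixed = fit_glmm(tab, plain_spec(randoms=[RandomTerm("g")]))
        assert np.abs(mixed.params.values - plain.params.values).max() < 1e-2
        assert max(mixed.vc.values()) < 0.05

    def test_variance_recovered_when_present(self):
        tab = simulate_logit_table(seed=4, group_sd=1.0, n=4000, n_groups=40)
        mixed = fit_glmm(tab, plain_spec(randoms=[RandomTerm("g")]))
        assert 0.3 < mixed.vc["g"] < 2.5
        assert mixed.loglik > fit_glmm(tab, plain_spec()).loglik

    def test_deterministic(self):
        tab = simulate_logit_table(seed=5, group_sd=0.5)
        f1 = fit_glmm(tab, plain_spec(randoms=[RandomTerm("g")]))
        f2 = fit_glmm(tab, plain_spec(randoms=[RandomTerm("g")]))
        assert f1.loglik == f2.loglik
        assert (f1.params == f2.params).all()

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lme4_laplace(self, tmp_path):
        tab = simulate_logit_table(seed=6, group_sd=0.8, n=1500, n_groups=25)
        csv = tmp_path / "d.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            d <- read.csv(commandArgs(TRUE)[1])
            suppressMessages(library(lme4))
            m <- glmer(response ~ x1 + x2 + (1 | g), data = d, family = binomial)
            cat(jsonlite <- sprintf('{"ll": %.6f, "b0": %.6f, "b1": %.6f, "b2": %.6f, "sd": %.6f}',
                as.numeric(logLik(m)), fixef(m)[1], fixef(m)[2], fixef(m)[3],
                sqrt(unlist(VarCorr(m))[1])))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True,
            timeout=300,
        )
        ref = json.loads(out.stdout.strip())
        fit = fit_glmm(tab, plain_spec(randoms=[RandomTerm("g")]))
        assert fit.loglik == pytest.approx(ref["ll"], abs=0.5)
        assert fit.params["intercept"] == pytest.approx(ref["b0"], abs=0.05)
        assert fit.params["x1"] == pytest.approx(ref["b1"], abs=0.05)
        assert fit.params["x2"] == pytest.approx(ref["b2"], abs=0.05)
        assert np.sqrt(fit.vc["g"]) == pytest.approx(ref["sd"], abs=0.1)


class TestACTerm:
    def test_constant_residuals_return_constant(self):
        days = np.array([0, 3, 9, 20])
        keys = np.array(["a"] * 4)
        out = compute_ac_term(days, keys, np.full(4, 0.7), sigma=5.0)
        assert np.allclose(out, 0.7)

    def test_single_partner_returns_its_residual(self):
        out = compute_ac_term(
            np.array([0, 10]), np.array(["a", "a"]), np.array([0.3, -0.2]), 4.0
        )
        assert out[0] == pytest.approx(-0.2)
        assert out[1] == pytest.approx(0.3)

    def test_symmetric_lags_average(self):
        out = compute_ac_term(
            np.array([0, 5, 10]), np.array(["a"] * 3),
            np.array([0.4, 0.0, -0.2]), 3.0,
        )
        assert out[1] == pytest.approx(0.1)  # equidistant partners average

    def test_isolated_rows_get_zero(self):
        out = compute_ac_term(
            np.array([0, 5]), np.array(["a", "b"]), np.array([1.0, 2.0]), 3.0
        )
        assert np.allclose(out, 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        n = 400
        days = rng.integers(0, 120, n)
        keys = rng.choice(list("abcdefg"), n)
        resid = rng.normal(size=n)
        for sigma in (1.0, 7.5, 40.0):
            fast = compute_ac_term(days, keys, resid, sigma)
            slow = np.zeros(n)
            for i in range(n):
                num = den = 0.0
                for j in range(n):
                    if i != j and keys[i] == keys[j]:
                        w = np.exp(-((days[i] - days[j]) ** 2) / (2 * sigma**2))
                        num += w * resid[j]
                        den += w
                slow[i] = num / den if den > 0 else 0.0
            assert np.abs(fast - slow).max() < 1e-12

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_ac_term(np.array([0]), np.array(["a"]), np.array([0.0]), 0.0)


class TestBandwidthAndWorkflow:
    def test_bandwidth_deterministic(self, infant_table):
        spec = _glm_spec(infant_table)
        base = fit_glmm(infant_table, spec)
        resid = acglmm.response_residuals(infant_table, base)
        b1 = acglmm.optimize_bandwidth(infant_table, spec, resid, "infant")
        b2 = acglmm.optimize_bandwidth(infant_table, spec, resid, "infant")
        assert b1.sigma == b2.sigma and b1.loglik == b2.loglik

    def test_ac_model_improves_likelihood_on_ar1_data(self, infant_table):
        spec = _glm_spec(infant_table)
        base = fit_glmm(infant_table, spec)
        fit, work = acglmm.fit_with_ac(infant_table, spec)
        assert set(fit.ac_sigmas) == {"infant", "male"}
        assert fit.loglik > base.loglik
        assert {"ac_infant", "ac_male"} <= set(work.columns)


class TestInference:
    def test_identical_models_give_null_lrt(self):
        tab = simulate_logit_table(seed=8)
        f = fit_glmm(tab, plain_spec())
        chi2, df, p = lrt(f, f)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_lrt_invariant_to_term_order(self):
        tab = simulate_logit_table(seed=9)
        fit_a = fit_glmm(tab, plain_spec(terms=("x1", "x2")))
        fit_b = fit_glmm(tab, plain_spec(terms=("x2", "x1")))
        null = fit_glmm(tab, plain_spec(terms=()))
        assert lrt(fit_a, null)[0] == pytest.approx(lrt(fit_b, null)[0], abs=1e-6)

    def test_full_vs_null_df_counts_test_terms(self, infant_table, male_table):
        # the canonical structures give 13 (infant) / 14 (male) df
        for tab, direction, expected in (
            (infant_table, "infant", 13),
            (male_table, "male", 14),
        ):
            spec = ModelSpec(
                test_terms=full_test_terms(direction),
                control_terms=[],
                offset="log_obs",
                random_terms=[],
            )
            if direction == "infant":
                assert len(spec.test_terms) == expected
            null = spec.null_spec()
            assert len(spec.test_terms) - len(null.test_terms) == expected

    def test_type1_rate_of_full_vs_null(self):
        # under a null generator the LRT p-values should be roughly uniform
        rejections = 0
        n_rep = 60
        for k in range(n_rep):
            tab = simulate_logit_table(n=600, seed=100 + k, beta=(0.0, 0.0))
            full = fit_glmm(tab, plain_spec())
            null = fit_glmm(tab, plain_spec(terms=()))
            _, _, p = lrt(full, null)
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.15


class TestPruning:
    def test_null_interactions_removed_and_hierarchy_kept(self):
        rng = np.random.default_rng(11)
        n = 3000
        tab = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        eta = -0.3 + 0.4 * tab["a"]
        tab["response"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        spec = ModelSpec(
            test_terms=["a", "b", "c", "a:b", "a:c", "a:b:c"],
            control_terms=[], offset=None, random_terms=[],
        )
        final, log = prune_interactions(tab, spec)
        # mains never removed; every retained interaction keeps its mains
        assert {"a", "b", "c"} <= set(final.test_terms)
        for t in final.test_terms:
            for part in t.split(":"):
                assert part in final.test_terms
        assert set(log.columns) == {"term", "chi2", "df", "p", "action"}

    def test_real_interaction_retained(self):
        rng = np.random.default_rng(12)
        n = 4000
        a, b = rng.normal(size=n), rng.normal(size=n)
        eta = -0.3 + 0.3 * a + 0.2 * b + 0.6 * a * b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        tab = pd.DataFrame({"a": a, "b": b, "response": y})
        spec = ModelSpec(
            test_terms=["a", "b", "a:b"], control_terms=[], offset=None,
            random_terms=[],
        )
        final, _ = prune_interactions(tab, spec)
        assert "a:b" in final.test_terms


class TestVIF:
    def test_orthogonal_predictors_near_one(self):
        rng = np.random.default_rng(13)
        tab = pd.DataFrame(rng.normal(size=(5000, 3)), columns=["a", "b", "c"])
        out = vif(tab, ["a", "b", "c"])
        assert (out < 1.05).all()

    def test_correlated_pair_closed_form(self):
        tab = simulate_logit_table(seed=14, n=200_00 // 2, rho_cols=0.8)
        out = vif(tab, ["x1", "x2"])
        assert out["x1"] == pytest.approx(1 / (1 - 0.8**2), abs=0.15)

    def test_duplicate_column_is_perfect_collinearity(self):
        tab = pd.DataFrame({"a": np.arange(10.0)})
        tab["b"] = tab["a"]
        with pytest.raises(DataError, match="collinearity"):
            vif(tab, ["a", "b"])


class TestStability:
    def test_one_row_per_level_and_extreme_level_found(self):
        rng = np.random.default_rng(15)
        n = 1200
        g = rng.integers(0, 6, n)
        x = rng.normal(size=n)
        eta = -0.5 + 0.3 * x + np.where(g == 3, 2.5, 0.0)  # planted outlier group
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        tab = pd.DataFrame({"response": y, "x": x, "infant": g.astype(str)})
        spec = ModelSpec(
            test_terms=["x"], control_terms=[], offset=None, random_terms=[]
        )
        out = acglmm.stability_check(tab, spec, group_cols=("infant",))
        assert len(out) == 6
        worst = out.sort_values("max_abs_delta").iloc[-1]
        assert worst["level"] == "3"
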