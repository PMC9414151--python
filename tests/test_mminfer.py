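"""GLMM fitting, AICc model sets, averaging and back-transformations."""

from __future__ import annotations

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ravenrange import mminfer
from ravenrange.mminfer import AveragedEstimate, FitResult, ModelSpec


def poisson_dataset(beta_origin=0.48, tau=0.4, n_groups=40, per_group=5, seed=0, intercept=0.3):
    rng = np.random.default_rng(seed)
    ids = np.repeat([f"b{i:03d}" for i in range(n_groups)], per_group)
    origin = np.repeat(rng.random(n_groups) < 0.5, per_group)
    u = np.repeat(rng.normal(0, tau, n_groups), per_group)
    y = rng.poisson(np.exp(intercept + beta_origin * origin + u))
    return pd.DataFrame(
        {
            "individual_id": ids,
            "origin": np.where(origin, "wild-caught", "captive-released"),
            "n_visits": y,
        }
    )


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"Intercept": 1.0, "a": x1, "b": x2})
        v = mminfer.vif(X)
        assert v["a"] == pytest.approx(1.0, abs=1e-9)
        assert v["b"] == pytest.approx(1.0, abs=1e-9)

    def test_near_collinear_pair_explodes(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        x2 = x1 + rng.normal(scale=1e-3, size=200)
        X = pd.DataFrame({"Intercept": 1.0, "a": x1, "b": x2})
        v = mminfer.vif(X)
        assert v["a"] > 10 and v["b"] > 10

    def test_matches_regression_oracle_on_random_design(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(300, 4)) @ np.array(
            [[1, 0.4, 0, 0.2], [0, 1, 0.3, 0], [0, 0, 1, 0.5], [0, 0, 0, 1]]
        )
        X = pd.DataFrame(Z, columns=["a", "b", "c", "d"])
        X.insert(0, "Intercept", 1.0)
        v = mminfer.vif(X)
        for j, col in enumerate(["a", "b", "c", "d"]):
            others = [c for c in ["a", "b", "c", "d"] if c != col]
            A = np.column_stack([np.ones(300), X[others].to_numpy()])
            resid = X[col] - A @ np.linalg.lstsq(A, X[col].to_numpy(), rcond=None)[0]
            r2 = 1 - resid.var() / X[col].var()
            assert v[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_constant_column_raises_singularity(self):
        X = pd.DataFrame({"Intercept": 1.0, "a": np.arange(10.0), "b": 2.0})
        with pytest.raises(mminfer.SingularDesignError, match="b"):
            mminfer.vif(X)


class TestAicc:
    def _fit(self, loglik, k, n):
        return FitResult(
            spec=ModelSpec("y", "poisson", ()), params=pd.Series(dtype=float),
            se=pd.Series(dtype=float), vc={}, loglik=loglik, k=k, n=n, converged=True,
        )

    def test_textbook_value(self):
        assert mminfer.aicc(self._fit(-10.0, 3, 20)) == pytest.approx(27.5)

    def test_converges_to_aic_for_large_n(self):
        f = self._fit(-100.0, 3, 10**6)
        aic = -2 * -100.0 + 2 * 3
        assert abs(mminfer.aicc(f) - aic) < 1e-3

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            mminfer.aicc(self._fit(-10.0, 5, 6))

    def test_matches_direct_formula_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ll = float(rng.normal(-50, 20))
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 200))
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert mminfer.aicc(self._fit(ll, k, n)) == pytest.approx(expected)


class TestEnumerateSubsets:
    def test_six_terms_give_sixty_four_models(self):
        spec = ModelSpec(
            "occurrence_km2", "lognormal",
            ("age_class", "origin", "season", "year", "sex", "fixes_per_day"),
        )
        assert len(mminfer.enumerate_subsets(spec)) == 64

    def test_zero_terms_give_intercept_only(self):
        subsets = mminfer.enumerate_subsets(ModelSpec("y", "poisson", ()))
        assert len(subsets) == 1 and subsets[0].fixed_terms == ()

    def test_three_terms_match_power_set_oracle(self):
        import itertools

        terms = ("age_class", "origin", "sex")
        got = {s.fixed_terms for s in mminfer.enumerate_subsets(ModelSpec("y", "poisson", terms))}
        want = set()
        for r in range(4):
            want |= set(itertools.combinations(terms, r))
        assert got == want


def _fit_with(terms, params, ses, loglik, k=3, n=100):
    idx = list(params)
    return FitResult(
        spec=ModelSpec("y", "poisson", terms),
        params=pd.Series(params, index=idx) if isinstance(params, dict) else params,
        se=pd.Series(ses, index=idx) if isinstance(ses, dict) else ses,
        vc={}, loglik=loglik, k=k, n=n, converged=True,
    )


class TestModelAverage:
    def make_pair(self):
        # delta AICc exactly [0, 2] via logLik offset
        f1 = _fit_with(("origin",), {"Intercept": 1.0, "origin[wild-caught]": 0.5},
                       {"Intercept": 0.1, "origin[wild-caught]": 0.2}, loglik=-10.0, k=3)
        f2 = _fit_with((), {"Intercept": 1.2}, {"Intercept": 0.15}, loglik=-11.0, k=2)
        a1, a2 = mminfer.aicc(f1), mminfer.aicc(f2)
        # shift the second model's loglik so that delta = 2 exactly
        f2.loglik += (a2 - a1 - 2.0) / 2.0
        return f1, f2

    def test_weights_follow_akaike_formula(self):
        f1, f2 = self.make_pair()
        table = mminfer.model_set_table([f1, f2])
        np.testing.assert_allclose(table["weight"], [0.73106, 0.26894], atol=1e-4)

    def test_rvi_is_candidate_weight_of_containing_models(self):
        f1, f2 = self.make_pair()
        est = {e.level: e for e in mminfer.model_average([f1, f2])}
        assert est["wild-caught"].rvi == pytest.approx(0.73106, abs=1e-4)

    def test_identical_models_average_to_themselves(self):
        f1 = _fit_with(("origin",), {"Intercept": 1.0, "origin[wild-caught]": 0.5},
                       {"Intercept": 0.1, "origin[wild-caught]": 0.2}, loglik=-10.0)
        f2 = _fit_with(("origin",), {"Intercept": 1.0, "origin[wild-caught]": 0.5},
                       {"Intercept": 0.1, "origin[wild-caught]": 0.2}, loglik=-10.0)
        est = {e.level: e for e in mminfer.model_average([f1, f2])}
        assert est["wild-caught"].estimate == pytest.approx(0.5)
        assert est["wild-caught"].unc_se == pytest.approx(0.2)
        assert est["wild-caught"].ci_low == pytest.approx(0.5 - 1.96 * 0.2)

    def test_candidate_weights_sum_to_one_and_rvi_monotone(self):
        f1, f2 = self.make_pair()
        t = mminfer.model_set_table([f1, f2])
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        rvi_before = {e.level: e.rvi for e in mminfer.model_average([f1, f2])}["wild-caught"]
        f3 = _fit_with(("origin", "sex"),
                       {"Intercept": 1.0, "origin[wild-caught]": 0.4, "sex[male]": 0.1},
                       {"Intercept": 0.1, "origin[wild-caught]": 0.2, "sex[male]": 0.1},
                       loglik=-10.5, k=4)
        rvi_after = {e.level: e.rvi for e in mminfer.model_average([f1, f2, f3])}["wild-caught"]
        assert rvi_after >= rvi_before - 1e-12 or rvi_after > 0.73

    def test_delta_cutoff_excludes_weak_models(self):
        f1, f2 = self.make_pair()
        f2.loglik -= 10  # push delta far beyond 6
        est = mminfer.model_average([f1, f2], delta_max=6.0)
        # only model 1 remains; averaging over a single model is exact
        by = {e.level: e for e in est}
        assert by["wild-caught"].estimate == pytest.approx(0.5)
        assert by["wild-caught"].rvi == pytest.approx(1.0)


class TestBackTransforms:
    @pytest.mark.parametrize(
        "beta,printed",
        [(-0.84, -56.82), (-2.73, -93.50), (-1.78, -83.15), (2.20, 800.34),
         (-0.21, -18.55), (0.48, 61.67), (0.35, 42.50)],
    )
    def test_percent_change_matches_printed_tables(self, beta, printed):
        # the printed coefficient is rounded to 2 dp, so the printed percent
        # can wander by ~0.5% of exp(beta) around the recomputed value
        got = mminfer.backtransform_percent(beta)
        tol = 100.0 * math.exp(beta) * 0.0055 + 0.005
        assert got == pytest.approx(printed, abs=tol)

    def test_zero_maps_to_zero(self):
        assert mminfer.backtransform_percent(0.0) == 0.0

    @pytest.mark.parametrize(
        "eta,printed",
        [(-2.42 + 1.16, 0.22), (-2.42 + 0.60, 0.14), (-2.42 + 0.67, 0.15), (-2.42, 0.08), (0.0, 0.5)],
    )
    def test_probability_matches_printed_tables(self, eta, printed):
        assert mminfer.backtransform_prob(eta) == pytest.approx(printed, abs=0.01)

    def test_prob_inverts_logit_exactly(self):
        for p in [1e-6, 0.01, 0.3, 0.5, 0.9, 1 - 1e-6]:
            eta = math.log(p / (1 - p))
            assert mminfer.backtransform_prob(eta) == pytest.approx(p, abs=1e-12)


class TestFitGlmm:
    def test_intercept_only_poisson_matches_closed_form(self):
        # zero between-individual variance: the MLE intercept is log(mean)
        rng = np.random.default_rng(2)
        y = rng.poisson(3.0, 200)
        df = pd.DataFrame(
            {"individual_id": [f"b{i}" for i in range(200)], "n_visits": y}
        )
        fit = mminfer.fit_glmm(ModelSpec("n_visits", "poisson", ()), df)
        assert fit.params["Intercept"] == pytest.approx(math.log(y.mean()), abs=1e-3)

    def test_zero_variance_data_match_plain_glm(self):
        import statsmodels.api as sm

        df = poisson_dataset(beta_origin=0.5, tau=0.0, n_groups=60, per_group=4, seed=5)
        fit = mminfer.fit_glmm(ModelSpec("n_visits", "poisson", ("origin",)), df)
        X = mminfer.build_design(df, ("origin",)).to_numpy()
        glm = sm.GLM(df["n_visits"].to_numpy(), X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), glm.params, atol=1e-3)

    def test_lognormal_zero_variance_matches_ols_on_log_response(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 240
        origin = rng.random(n) < 0.5
        y = np.exp(1.0 + 0.7 * origin + rng.normal(0, 0.3, n))
        df = pd.DataFrame(
            {
                "individual_id": [f"b{i}" for i in range(n)],
                "origin": np.where(origin, "wild-caught", "captive-released"),
                "occ": y,
            }
        )
        fit = mminfer.fit_glmm(ModelSpec("occ", "lognormal", ("origin",)), df)
        X = mminfer.build_design(df, ("origin",)).to_numpy()
        ols = sm.OLS(np.log(y), X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-3)

    def test_binomial_response_validation(self):
        df = pd.DataFrame(
            {"individual_id": ["a", "b"], "n_fixes_inside": [5, 2], "n_fixes_total": [4, 10]}
        )
        with pytest.raises(ValueError, match="exceed"):
            mminfer.fit_glmm(ModelSpec("prop", "binomial", (), olre=True), df)

    def test_binomial_spec_requires_olre_and_bans_sampling_covariate(self):
        with pytest.raises(ValueError, match="observation-level"):
            ModelSpec("prop", "binomial", ())
        with pytest.raises(ValueError, match="fixes_per_day"):
            ModelSpec("prop", "binomial", ("fixes_per_day",), olre=True)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLme4:
    def test_poisson_glmm_matches_lme4_agq(self, tmp_path):
        df = poisson_dataset(beta_origin=0.48, tau=0.4, n_groups=40, per_group=5, seed=7)
        fit = mminfer.fit_glmm(ModelSpec("n_visits", "poisson", ("origin",)), df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(n_visits ~ origin + (1|individual_id), data=d, family=poisson, nAGQ=15)\n"
            "co <- summary(m)$coefficients\n"
            "cat(co[,1], co[,2], as.numeric(VarCorr(m)$individual_id), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        b0, b1, se0, se1, tau2 = vals
        assert fit.params["Intercept"] == pytest.approx(b0, abs=2e-3)
        assert fit.params["origin[wild-caught]"] == pytest.approx(b1, abs=2e-3)
        assert fit.se["Intercept"] == pytest.approx(se0, abs=5e-3)
        assert fit.se["origin[wild-caught]"] == pytest.approx(se1, abs=5e-3)
        assert fit.vc["individual"] == pytest.approx(tau2, rel=0.02, abs=1e-3)
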