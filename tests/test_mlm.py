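"""Multilevel logit fitter and latent-scale ICC."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from hsequity import (
    ICC_THRESHOLD,
    MLMSpec,
    SimulationSpec,
    fit_multilevel,
    icc,
    icc_from_variances,
    needs_multilevel,
    simulate_cohort,
)
from hsequity._design import build_design, sigmoid


class TestICC:
    @pytest.mark.parametrize(
        "s2_city, s2_comm, level, expected",
        [
            (0.396, 0.109, "city", 0.104),
            (0.396, 0.109, "community_cumulative", 0.133),
            (0.294, 0.0, "city", 0.082),
            (0.294, 0.0, "community_cumulative", 0.082),
            (0.0, 0.0, "city", 0.0),
            (0.0, 0.0, "community_cumulative", 0.0),
        ],
    )
    def test_worked_examples(self, s2_city, s2_comm, level, expected):
        """Latent-scale ICC with level-1 variance fixed at pi^2/3."""
        assert round(icc_from_variances(s2_city, s2_comm, level), 3) == expected

    @given(
        s2c=st.floats(0.0, 5.0),
        s2m=st.floats(0.0, 5.0),
        bump=st.floats(0.01, 2.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_ordered(self, s2c, s2m, bump):
        city = icc_from_variances(s2c, s2m, "city")
        cum = icc_from_variances(s2c, s2m, "community_cumulative")
        assert 0.0 <= city <= cum < 1.0
        assert icc_from_variances(s2c + bump, s2m, "city") > city

    def test_gaussian_uses_residual_variance(self):
        assert icc_from_variances(1.0, 1.0, "city", sigma2_residual=2.0) == 0.25

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            icc_from_variances(-0.1, 0.0, "city")
        with pytest.raises(ValueError):
            icc_from_variances(0.1, 0.0, "nowhere")


class TestDecisionRule:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.104, True), (0.059, False), (8.53e-36, False), (0.0591, True)],
    )
    def test_against_0059_threshold(self, value, expected):
        assert needs_multilevel(value) is expected
        assert ICC_THRESHOLD == 0.059

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            needs_multilevel(1.0)


@pytest.fixture(scope="module")
def flat_cohort():
    """No clustering at all: both variance components truly zero."""
    spec = SimulationSpec(
        n_cities=25,
        communities_per_city=3,
        workers_per_community=12,
        sigma2_city=0.0,
        sigma2_community=0.0,
        seed=11,
    )
    return simulate_cohort(spec)


class TestLogitFits:
    def test_fixed_zero_variance_matches_weighted_glm(self, flat_cohort):
        """Pinning both components at 0 reproduces the plain weighted logit."""
        cohort = flat_cohort.cohort
        rng = np.random.default_rng(4)
        w = rng.integers(1, 4, size=len(cohort)).astype(float)
        spec = MLMSpec(outcome="outpatient_2w", person_terms=("age_group", "sah"))
        fit = fit_multilevel(
            cohort, spec, weights=w, fix_sigma=(0.0, 0.0),
            categories=flat_cohort.spec.categories,
        )
        X, names = build_design(
            cohort, ["age_group", "sah"], flat_cohort.spec.categories
        )
        ref = sm.GLM(
            cohort["outpatient_2w"].to_numpy(float),
            X,
            family=sm.families.Binomial(),
            freq_weights=w,
        ).fit()
        got = fit.coef.reindex(names).to_numpy()
        np.testing.assert_allclose(got, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_null_model_intercept_is_logit_prevalence(self, flat_cohort):
        """Intercept-only fit with ~zero variances: logit of the prevalence."""
        cohort = flat_cohort.cohort
        fit = fit_multilevel(cohort, MLMSpec(outcome="outpatient_2w"))
        prevalence = cohort["outpatient_2w"].mean()
        assert fit.sigma2_city <= 0.01 and fit.sigma2_community <= 0.01
        assert fit.coef["(Intercept)"] == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=0.05
        )

    def test_three_level_loglik_dominates_two_level(self, small_cohort):
        spec3 = MLMSpec(outcome="outpatient_2w", person_terms=("sah",))
        spec2 = MLMSpec(
            outcome="outpatient_2w", person_terms=("sah",),
            random_levels=("community",),
        )
        ll3 = fit_multilevel(small_cohort, spec3).loglik
        ll2 = fit_multilevel(small_cohort, spec2).loglik
        assert ll3 >= ll2 - 1e-4

    def test_separation_is_reported_not_silent(self):
        n = 40
        cohort = pd.DataFrame(
            {
                "person_id": range(n),
                "city_id": [0, 1] * (n // 2),
                "community_id": [0, 1] * (n // 2),
                "group": ["in_county"] * n,
                "x": ["a"] * (n // 2) + ["b"] * (n // 2),
                "outpatient_2w": [1] * (n // 2) + [0] * (n // 2),
                "inpatient_12m": [0] * n,
                "weight": [1.0] * n,
            }
        )
        spec = MLMSpec(outcome="outpatient_2w", person_terms=("x",))
        with pytest.warns(UserWarning, match="converge|separation"):
            fit = fit_multilevel(cohort, spec, fix_sigma=(0.0, 0.0))
        assert not fit.converged

    def test_non_nested_ids_rejected(self, small_cohort):
        broken = small_cohort.copy()
        broken.loc[broken.index[0], "city_id"] = 19  # community straddles cities
        with pytest.raises(ValueError, match="nested"):
            fit_multilevel(broken, MLMSpec(outcome="outpatient_2w"))

    def test_odds_ratios_exponentiate_coefficients(self, small_cohort):
        fit = fit_multilevel(
            small_cohort, MLMSpec(outcome="outpatient_2w", person_terms=("sah",))
        )
        np.testing.assert_allclose(fit.odds_ratio, np.exp(fit.coef))


class TestAgainstLme4:
    """Independent oracle: R lme4::glmer (Laplace) on the same data."""

    def test_three_level_fit_matches_glmer(self, tmp_path):
        spec = SimulationSpec(
            n_cities=30, communities_per_city=3, workers_per_community=15,
            sigma2_city=0.4, sigma2_community=0.15, seed=21,
        )
        cohort = simulate_cohort(spec).cohort
        cohort = cohort[cohort["group"] == "in_county"]
        csv = tmp_path / "cohort.csv"
        cohort.to_csv(csv, index=False)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$sah <- relevel(factor(d$sah), ref="good")
            m <- glmer(outpatient_2w ~ sah + (1|city_id) + (1|community_id),
                       data=d, family=binomial, nAGQ=1)
            v <- VarCorr(m)
            cat(jsonlite::toJSON(list(
                loglik=as.numeric(logLik(m)),
                s2_city=as.numeric(v$city_id[1,1]),
                s2_comm=as.numeric(v$community_id[1,1]),
                beta=as.numeric(fixef(m))), digits=10))
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        raw = json.loads(out.stdout)
        ref = {k: (v[0] if k != "beta" else v) for k, v in raw.items()}
        fit = fit_multilevel(
            cohort,
            MLMSpec(outcome="outpatient_2w", person_terms=("sah",)),
            categories={"sah": ["good", "fair", "poor"]},
        )
        assert fit.loglik == pytest.approx(ref["loglik"], abs=0.5)
        assert fit.sigma2_city == pytest.approx(ref["s2_city"], abs=0.02)
        assert fit.sigma2_community == pytest.approx(ref["s2_comm"], abs=0.02)
        np.testing.assert_allclose(fit.coef.to_numpy(), ref["beta"], atol=0.02)


class TestGaussianSpecialCase:
    def test_variance_recovery(self):
        """Identity-link special case via MixedLM: components near truth."""
        rng = np.random.default_rng(17)
        K, J, n = 60, 4, 10
        city = np.repeat(np.arange(K), J * n)
        comm = np.repeat(np.arange(K * J), n)
        y = (
            2.0
            + rng.normal(0, np.sqrt(0.5), K)[city]
            + rng.normal(0, np.sqrt(0.3), K * J)[comm]
            + rng.normal(0, 1.0, K * J * n)
        )
        cohort = pd.DataFrame(
            {
                "person_id": np.arange(K * J * n),
                "city_id": city,
                "community_id": comm,
                "group": "in_county",
                "score": y,
                "outpatient_2w": 0,
                "inpatient_12m": 0,
                "weight": 1.0,
            }
        )
        fit = fit_multilevel(cohort, MLMSpec(outcome="score", family="gaussian"))
        assert fit.sigma2_city == pytest.approx(0.5, abs=0.25)
        assert fit.sigma2_community == pytest.approx(0.3, abs=0.15)
        assert fit.sigma2_residual == pytest.approx(1.0, abs=0.1)
        total = fit.sigma2_city + fit.sigma2_community + fit.sigma2_residual
        assert icc(fit, "city") == pytest.approx(fit.sigma2_city / total)
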