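"""Fairlie decomposition: closed forms, brute-force pairing oracle, identities."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from hsequity import (
    PooledLogit,
    SimulationSpec,
    fairlie_decompose,
    fit_pooled_logit,
    simulate_cohort,
    total_gap,
)
from hsequity._design import sigmoid
from hsequity.simulate import GROUP_ACROSS, GROUP_IN


def make_cohort(x_u, x_r, y_u=None, y_r=None):
    """Two-group cohort over one numeric covariate x."""
    x_u, x_r = np.asarray(x_u, float), np.asarray(x_r, float)
    y_u = np.zeros_like(x_u) if y_u is None else np.asarray(y_u, float)
    y_r = np.zeros_like(x_r) if y_r is None else np.asarray(y_r, float)
    return pd.DataFrame(
        {
            "group": [GROUP_ACROSS] * len(x_u) + [GROUP_IN] * len(x_r),
            "x": np.concatenate([x_u, x_r]),
            "y": np.concatenate([y_u, y_r]).astype(int),
        }
    )


def pooled(b0, b1):
    return PooledLogit(
        coef=pd.Series({"(Intercept)": b0, "x": b1}),
        covariates=["x"],
        categories={},
        loglik=np.nan,
        n_obs=0,
    )


class TestTotalGap:
    def test_defining_arithmetic(self):
        """u prevalence 0.046 vs r prevalence 0.050 -> gap -0.004."""
        y_u = np.zeros(1000)
        y_u[:46] = 1
        y_r = np.zeros(1000)
        y_r[:50] = 1
        cohort = make_cohort(np.zeros(1000), np.zeros(1000), y_u, y_r)
        assert total_gap(cohort, "y") == pytest.approx(-0.004, abs=1e-12)

    def test_identical_groups_zero(self):
        cohort = make_cohort([0, 1], [1, 0], [1, 0], [0, 1])
        assert total_gap(cohort, "y") == 0.0

    def test_empty_group_rejected(self):
        cohort = make_cohort([0.0], [])
        with pytest.raises(ValueError, match="empty"):
            total_gap(cohort, "y")

    def test_null_design_gap_shrinks(self):
        """Same DGP in both groups: the gap vanishes with n."""
        gaps = []
        for n_cities, seed in [(20, 1), (180, 1)]:
            spec = SimulationSpec(
                n_cities=n_cities, communities_per_city=3,
                workers_per_community=10, seed=seed,
            )
            spec.beta_across = {k: dict(v) for k, v in spec.beta_in.items()}
            spec.selection_coefs = {}
            cohort = simulate_cohort(spec).cohort
            gaps.append(abs(total_gap(cohort, "outpatient_2w")))
            n = len(cohort)
        assert gaps[1] < 4 * np.sqrt(0.25 * 4 / n)  # 4 MC SDs at ~50/50 split


class TestPooledLogit:
    def test_closed_form_two_by_two(self):
        """y=1: 30/50 at x=1, 10/50 at x=0 -> slope log 6, intercept log 1/4."""
        x = np.concatenate([np.ones(50), np.zeros(50)])
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)])
        groups = np.where(np.arange(100) % 2 == 0, GROUP_ACROSS, GROUP_IN)
        cohort = pd.DataFrame({"group": groups, "x": x, "y": y.astype(int)})
        fit = fit_pooled_logit(cohort, "y", ["x"])
        assert fit.coef["x"] == pytest.approx(np.log(6.0), abs=1e-6)
        assert fit.coef["(Intercept)"] == pytest.approx(np.log(0.25), abs=1e-6)

    def test_independent_outcome_gives_null_slopes(self, small_cohort):
        rng = np.random.default_rng(0)
        cohort = small_cohort.copy()
        cohort["coin"] = rng.integers(0, 2, len(cohort))
        fit = fit_pooled_logit(cohort, "coin", ["age_group", "sah"])
        prevalence = cohort["coin"].mean()
        slopes = fit.coef.drop("(Intercept)")
        assert np.abs(slopes).max() < 0.5
        assert fit.coef["(Intercept)"] == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=0.3
        )

    def test_separation_raises(self):
        cohort = make_cohort([0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 1, 1])
        with pytest.raises(RuntimeError, match="separation|converge"):
            fit_pooled_logit(cohort, "y", ["x"])

    def test_missing_group_rejected(self):
        cohort = make_cohort([0.0, 1.0], [])
        with pytest.raises(ValueError, match="both groups"):
            fit_pooled_logit(cohort, "y", ["x"])


class TestDecomposition:
    def test_identical_groups_record_for_record(self):
        """Same covariates in both groups: contributions 0, gap all unexplained."""
        x = np.array([0, 0, 1, 1, 0, 1.0])
        y_u = np.array([1, 0, 0, 0, 0, 0])
        y_r = np.array([1, 1, 0, 1, 0, 0])
        cohort = make_cohort(x, x, y_u, y_r)
        dec = fairlie_decompose(cohort, "y", ["x"], pooled(-0.3, 0.7), seed=5)
        assert dec.contributions["x"] == pytest.approx(0.0, abs=1e-14)
        gap = total_gap(cohort, "y")
        assert dec.total_gap == pytest.approx(gap)
        assert dec.unexplained == pytest.approx(gap, abs=1e-14)

    def test_brute_force_pairing_oracle(self):
        """Average contribution over every possible pairing of the two samples."""
        b0, b1 = -0.4, 1.1
        x_u = np.array([1, 1, 1, 0, 1, 0.0])
        x_r = np.array([0, 1, 0, 0, 1, 0.0])
        cohort = make_cohort(x_u, x_r)
        f_u, f_r = sigmoid(b0 + b1 * x_u), sigmoid(b0 + b1 * x_r)
        oracle = np.mean(
            [np.mean(f_u - f_r[list(p)]) for p in permutations(range(len(x_r)))]
        )
        dec = fairlie_decompose(
            cohort, "y", ["x"], pooled(b0, b1), n_orderings=1, seed=9
        )
        assert dec.contributions["x"] == pytest.approx(oracle, abs=1e-10)

    def test_closed_form_at_n20(self):
        """P(x=1)=0.8 vs 0.2, equal sizes: contribution = mean F_u - mean F_r."""
        b0, b1 = -1.0, 0.8
        x_u = np.array([1.0] * 16 + [0.0] * 4)
        x_r = np.array([1.0] * 4 + [0.0] * 16)
        cohort = make_cohort(x_u, x_r)
        expected = sigmoid(b0 + b1 * x_u).mean() - sigmoid(b0 + b1 * x_r).mean()
        dec = fairlie_decompose(
            cohort, "y", ["x"], pooled(b0, b1), n_orderings=3, seed=2
        )
        assert dec.contributions["x"] == pytest.approx(expected, abs=1e-10)

    def test_equal_sizes_invariant_to_subsample_draws(self, small_cohort):
        covs = ["age_group", "sah"]
        fit = fit_pooled_logit(small_cohort, "outpatient_2w", covs)
        u = small_cohort[small_cohort["group"] == GROUP_ACROSS]
        r = small_cohort[small_cohort["group"] == GROUP_IN].head(len(u))
        balanced = pd.concat([u, r], ignore_index=True)
        runs = [
            fairlie_decompose(
                balanced, "outpatient_2w", covs, fit,
                n_orderings=10, n_subsample_draws=draws, seed=3,
            )
            for draws in (1, 7)
        ]
        pd.testing.assert_series_equal(runs[0].contributions, runs[1].contributions)

    def test_identity_and_blocksum_are_algebraic(self, small_cohort, matched_small):
        covs = ["age_group", "gender", "income_quintile", "sah"]
        w = matched_small.cem_weight.to_numpy()
        fit = fit_pooled_logit(small_cohort, "outpatient_2w", covs, weights=w)
        dec = fairlie_decompose(
            small_cohort, "outpatient_2w", covs, fit, weights=w,
            n_orderings=10, n_subsample_draws=5, seed=0,
        )
        assert dec.explained + dec.unexplained == pytest.approx(
            dec.total_gap, abs=1e-12
        )
        assert dec.contributions.sum() == pytest.approx(dec.explained, abs=1e-12)
        assert dec.contribution_percent.sum() == pytest.approx(
            dec.explained_percent, abs=1e-6
        )

    def test_doubling_orderings_stays_within_mc_error(self, small_cohort,
                                                      matched_small):
        covs = ["age_group", "gender", "income_quintile", "sah"]
        w = matched_small.cem_weight.to_numpy()
        fit = fit_pooled_logit(small_cohort, "outpatient_2w", covs, weights=w)
        runs = {
            n: fairlie_decompose(
                small_cohort, "outpatient_2w", covs, fit, weights=w,
                n_orderings=n, n_subsample_draws=10, seed=8,
            )
            for n in (40, 80)
        }
        for block in covs:
            se = max(runs[40].contribution_se[block], 1e-12)
            diff = abs(
                runs[40].contributions[block] - runs[80].contributions[block]
            )
            assert diff < 4 * se

    def test_mislabeled_groups_rejected(self):
        cohort = make_cohort(np.zeros(5), np.zeros(2))
        with pytest.raises(ValueError, match="smaller"):
            fairlie_decompose(cohort, "y", ["x"], pooled(0.0, 0.0))

    def test_unknown_block_rejected(self, small_cohort):
        fit = fit_pooled_logit(small_cohort, "outpatient_2w", ["sah"])
        with pytest.raises(KeyError, match="nope"):
            fairlie_decompose(small_cohort, "outpatient_2w", ["nope"], fit)
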