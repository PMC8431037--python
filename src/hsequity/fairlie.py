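"""Fairlie nonlinear decomposition of a binary-outcome gap.

The gap in a binary outcome between the across-county group (u, the smaller
group) and the in-county group (r) is

    Ȳu − Ȳr = [Σ F(X_u'β)/N_u − Σ F(X_r'β)/N_r]  +  (remainder),

with F the logistic CDF. The first bracket is the *characteristic*
(explained, endowment) effect — the part of the gap attributable to group
differences in covariate composition evaluated at common coefficients β
(here: a weighted logit on the pooled sample) — and the remainder is the
*discrimination* (unexplained) effect.

Because F is nonlinear the characteristic effect must be built
record-by-record: a random subsample of the larger group of the smaller
group's size is drawn, both samples are ranked by predicted probability and
paired by rank, and each covariate block is switched from the u-values to
the paired r-values one block at a time, recording the induced change in
the mean predicted probability as that block's contribution. Contributions
depend on the switching order, so they are averaged over random orderings
(the conventional 100) and over subsample draws.

By construction the block contributions of one ordering telescope, so
``explained`` equals the characteristic bracket computed on the paired
samples and ``explained + unexplained == total_gap`` holds algebraically.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import build_design, infer_categories, sigmoid
from .simulate import GROUP_ACROSS, GROUP_IN

__all__ = [
    "PooledLogit",
    "DecompositionResult",
    "fit_pooled_logit",
    "fairlie_decompose",
    "total_gap",
]


def _weights_of(cohort, weights):
    if weights is None:
        w = (
            cohort["weight"].to_numpy(dtype=float)
            if "weight" in cohort.columns
            else np.ones(len(cohort))
        )
    else:
        w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return w


def total_gap(
    cohort: pd.DataFrame,
    outcome: str,
    weights: Sequence[float] | None = None,
    group_col: str = "group",
) -> float:
    """Weighted mean(outcome | across-county) − weighted mean(outcome | in-county)."""
    w = _weights_of(cohort, weights)
    y = cohort[outcome].to_numpy(dtype=float)
    means = {}
    for g in (GROUP_ACROSS, GROUP_IN):
        mask = (cohort[group_col] == g).to_numpy()
        if w[mask].sum() <= 0:
            raise ValueError(f"group {g!r} is empty (or has zero total weight)")
        means[g] = float(np.average(y[mask], weights=w[mask]))
    return means[GROUP_ACROSS] - means[GROUP_IN]


@dataclass
class PooledLogit:
    """Pooled-sample logit coefficients used as the common β of Eq.-style decomposition."""

    coef: pd.Series
    covariates: list[str]
    categories: dict[str, list[str]]
    loglik: float
    n_obs: int

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X, names = build_design(data, self.covariates, self.categories)
        return X @ self.coef.reindex(names).to_numpy()


def fit_pooled_logit(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    weights: Sequence[float] | None = None,
    include_group_indicator: bool = False,
    group_col: str = "group",
) -> PooledLogit:
    """Weighted ML logit on the pooled (both-group) sample.

    The plain pooled model (no group-membership indicator) is the default
    convention; ``include_group_indicator=True`` adds the indicator, whose
    coefficient is then excluded from the stored decomposition coefficients.
    """
    covariates = list(covariates)
    for g in (GROUP_IN, GROUP_ACROSS):
        if (cohort[group_col] == g).sum() == 0:
            raise ValueError(f"pooled fit requires both groups; {g!r} is absent")
    w = _weights_of(cohort, weights)
    keep = w > 0
    data = cohort.loc[keep]
    w = w[keep]
    categories = infer_categories(data, covariates)
    X, names = build_design(data, covariates, categories)
    if include_group_indicator:
        X = np.column_stack([X, (data[group_col] == GROUP_ACROSS).astype(float)])
        names = names + ["__group__"]
    y = data[outcome].to_numpy(dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = model.fit(maxiter=200)
    except Exception as err:  # statsmodels raises on some separation paths
        raise RuntimeError(
            f"pooled logit for {outcome!r} failed: possible separation ({err})"
        ) from err
    if any(issubclass(c.category, PerfectSeparationWarning) for c in caught):
        raise RuntimeError(
            f"pooled logit for {outcome!r}: perfect separation detected"
        )
    if not res.converged:
        raise RuntimeError(
            f"pooled logit for {outcome!r} did not converge "
            "(possible separation)"
        )
    if np.abs(res.params).max() > 50:
        raise RuntimeError(
            f"pooled logit for {outcome!r}: coefficient diverged "
            "(perfect separation in some covariate cell)"
        )
    coef = pd.Series(res.params, index=names, name="coef")
    if include_group_indicator:
        coef = coef.drop("__group__")
    return PooledLogit(
        coef=coef,
        covariates=covariates,
        categories=categories,
        loglik=float(res.llf),
        n_obs=int(keep.sum()),
    )


@dataclass
class DecompositionResult:
    """Gap decomposition into per-block characteristic contributions."""

    outcome: str
    total_gap: float
    explained: float
    unexplained: float
    contributions: pd.Series  # coefficient (probability) scale, one per block
    contribution_se: pd.Series  # Monte-Carlo SE over orderings × draws
    n_orderings: int
    n_subsample_draws: int
    seed: int
    n_u: int
    n_r: int

    @property
    def explained_percent(self) -> float:
        return self._pct(self.explained)

    @property
    def contribution_percent(self) -> pd.Series:
        return self.contributions.map(self._pct).rename("contribution_pct")

    def _pct(self, value: float) -> float:
        if self.total_gap == 0:
            return float("nan")
        return 100.0 * value / self.total_gap

    def to_frame(self) -> pd.DataFrame:
        """Decomposition table: per-block probability-scale value and % of gap."""
        return pd.DataFrame(
            {
                "contribution": self.contributions,
                "contribution_pct": self.contribution_percent,
                "mc_se": self.contribution_se,
            }
        ).rename_axis("block")


def _paired_block_parts(pooled, data, blocks):
    """Per-record linear-predictor pieces: base (intercept + unswitched) and
    one column per block."""
    coef = pooled.coef
    names = coef.index
    X, xnames = build_design(data, pooled.covariates, pooled.categories)
    X = pd.DataFrame(X, columns=xnames)
    parts = np.zeros((len(data), len(blocks)))
    base = np.zeros(len(data))
    for name in names:
        col = X[name].to_numpy() * coef[name]
        cov = name.split("=", 1)[0] if "=" in name else name
        if name == "(Intercept)" or cov not in blocks:
            base += col
        else:
            parts[:, blocks.index(cov)] += col
    return base, parts


def fairlie_decompose(
    cohort: pd.DataFrame,
    outcome: str,
    covariate_blocks: Sequence[str],
    coefs: PooledLogit,
    weights: Sequence[float] | None = None,
    n_orderings: int = 100,
    n_subsample_draws: int = 100,
    seed: int = 0,
    group_col: str = "group",
) -> DecompositionResult:
    """Decompose the outcome gap into per-block characteristic contributions.

    All dummies of a categorical covariate are switched together and reported
    as one block. The larger (in-county) group is subsampled with probability
    proportional to weight; with equal group sizes the subsample step is the
    identity and a single draw is used. Ties in predicted probability are
    broken by a seeded shuffle, so results are deterministic given ``seed``.
    """
    blocks = list(covariate_blocks)
    unknown = [b for b in blocks if b not in coefs.covariates]
    if unknown:
        raise KeyError(f"blocks {unknown} are not covariates of the pooled model")
    w = _weights_of(cohort, weights)
    matched = w > 0
    data = cohort.loc[matched]
    w = w[matched]
    u_mask = (data[group_col] == GROUP_ACROSS).to_numpy()
    r_mask = (data[group_col] == GROUP_IN).to_numpy()
    n_u, n_r = int(u_mask.sum()), int(r_mask.sum())
    if n_u == 0 or n_r == 0:
        raise ValueError("both groups must be present (with positive weight)")
    if n_u > n_r:
        raise ValueError(
            f"the across-county group must be the smaller group "
            f"(got N_u={n_u} > N_r={n_r}); check the group labels"
        )

    gap = total_gap(data, outcome, weights=w, group_col=group_col)

    base_all, parts_all = _paired_block_parts(coefs, data, blocks)
    base_u, parts_u = base_all[u_mask], parts_all[u_mask]
    base_r, parts_r = base_all[r_mask], parts_all[r_mask]
    w_r = w[r_mask]
    lp_u = base_u + parts_u.sum(axis=1)
    lp_r_all = base_r + parts_r.sum(axis=1)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    equal_sizes = n_u == n_r
    draws = 1 if equal_sizes else n_subsample_draws
    B = len(blocks)
    samples = np.zeros((draws * n_orderings, B))
    row = 0
    # rank the u-sample once per draw (its tie-break shuffle is redrawn with
    # the subsample to keep the pairing exchangeable)
    for _ in range(draws):
        if equal_sizes:
            idx = np.arange(n_r)
        else:
            idx = rng.choice(n_r, size=n_u, replace=False, p=w_r / w_r.sum())
        order_u = _rank_order(lp_u, rng)
        order_r = _rank_order(lp_r_all[idx], rng)
        pu = parts_u[order_u]
        pr = parts_r[idx][order_r]
        bu = base_u[order_u]
        # switching covariates does not touch the base (intercept + any
        # unswitched terms), which stays at the u-records' values
        for _ in range(n_orderings):
            perm = rng.permutation(B)
            lp = bu + pu.sum(axis=1)
            mean_prev = float(np.mean(sigmoid(lp)))
            for b in perm:
                lp = lp + pr[:, b] - pu[:, b]
                mean_next = float(np.mean(sigmoid(lp)))
                samples[row, b] = mean_prev - mean_next
                mean_prev = mean_next
            row += 1

    contributions = pd.Series(samples.mean(axis=0), index=blocks, name="contribution")
    # Monte-Carlo SE: orderings within one subsample draw share the pairing,
    # so cluster at the draw level when several draws were taken
    by_draw = samples.reshape(draws, n_orderings, B)
    if draws > 1:
        draw_means = by_draw.mean(axis=1)
        se = draw_means.std(axis=0, ddof=1) / np.sqrt(draws)
    elif n_orderings > 1:
        se = by_draw[0].std(axis=0, ddof=1) / np.sqrt(n_orderings)
    else:
        se = np.zeros(B)
    explained = float(contributions.sum())
    return DecompositionResult(
        outcome=outcome,
        total_gap=gap,
        explained=explained,
        unexplained=gap - explained,
        contributions=contributions,
        contribution_se=pd.Series(se, index=blocks, name="mc_se"),
        n_orderings=n_orderings,
        n_subsample_draws=draws,
        seed=seed,
        n_u=n_u,
        n_r=n_r,
    )


def _rank_order(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending order with ties broken by a seeded shuffle."""
    perm = rng.permutation(len(values))
    return perm[np.argsort(values[perm], kind="stable")]
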