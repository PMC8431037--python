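"""Random-intercept multilevel models and latent-scale ICC.

The workhorse is a maximum-likelihood fitter for up-to-three-level
random-intercept logistic regression,

    logit P(y_ijk = 1) = x_ijk'β + ω_jk'γ + z_k'η + μ_jk + ν_k,

with worker i nested in community j nested in city k, μ ~ N(0, σ²_community)
and ν ~ N(0, σ²_city). Estimation uses the Laplace approximation in the
spherical (lme4-style) parametrization: the latent effects are scaled
standard-normal vectors, the fixed effects and effect modes are found
jointly by penalized iteratively reweighted least squares exploiting the
nested sparsity (one small block per city), and the profiled Laplace
log-likelihood is maximized over the two standard deviations with a
bounded derivative-free search. The boundary σ = 0 is an ordinary point of
the parametrization, so degenerate variance components pose no problem.

Intraclass correlations use the latent-threshold convention for the logit
family: the worker-level variance is fixed at π²/3, so

    ICC_city = σ²_city / (σ²_city + σ²_community + π²/3)

and the community-level ICC is cumulative, (σ²_city + σ²_community) over the
same total. A fitted ICC above 0.059 is the conventional signal that a
multilevel model is required.

The gaussian family (the identity-link special case of the same three-level
structure) is delegated to :class:`statsmodels` MixedLM.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._design import build_design, infer_categories, sigmoid

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3
ICC_THRESHOLD = 0.059
#: variance estimates below this are reported as exactly zero
VARIANCE_FLOOR = 1e-8

__all__ = [
    "MLMSpec",
    "MLMFit",
    "fit_multilevel",
    "icc",
    "icc_from_variances",
    "needs_multilevel",
    "LOGIT_RESIDUAL_VARIANCE",
    "ICC_THRESHOLD",
]


@dataclass
class MLMSpec:
    """What to fit: outcome, fixed effects per level, random levels, family."""

    outcome: str
    person_terms: tuple[str, ...] = ()
    community_terms: tuple[str, ...] = ()
    city_terms: tuple[str, ...] = ()
    random_levels: tuple[str, ...] = ("city", "community")
    family: str = "binomial"
    use_weights: bool = True

    @property
    def fixed_terms(self) -> list[str]:
        return list(self.person_terms) + list(self.community_terms) + list(
            self.city_terms
        )

    def validate(self) -> None:
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        unknown = set(self.random_levels) - {"city", "community"}
        if unknown:
            raise ValueError(f"unknown random-intercept levels {sorted(unknown)}")


@dataclass
class MLMFit:
    """Coefficients, variance components and diagnostics of a fitted model."""

    spec: MLMSpec
    coef: pd.Series
    se: pd.Series
    sigma2_city: float
    sigma2_community: float
    sigma2_residual: float  # π²/3 for the logit family, σ²_e0 for gaussian
    loglik: float
    converged: bool
    message: str
    n_obs: int
    n_communities: int
    n_cities: int

    @property
    def odds_ratio(self) -> pd.Series | None:
        if self.spec.family != "binomial":
            return None
        return np.exp(self.coef).rename("OR")

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def pvalues(self) -> pd.Series:
        from scipy import stats

        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self.coef.index
        )

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.coef, "se": self.se, "p": self.pvalues})
        if self.spec.family == "binomial":
            out.insert(0, "OR", self.odds_ratio)
        return out


# ----------------------------------------------------------------------
# Laplace fitter for the binomial family
# ----------------------------------------------------------------------


def _agg(idx: np.ndarray, values: np.ndarray, size: int) -> np.ndarray:
    """Group-sum of ``values`` (1-D or 2-D) by integer codes ``idx``."""
    if values.ndim == 1:
        return np.bincount(idx, weights=values, minlength=size)
    return np.column_stack(
        [np.bincount(idx, weights=values[:, j], minlength=size)
         for j in range(values.shape[1])]
    )


class _LaplaceLogit:
    """Inner machinery: joint (β, z) mode and profiled Laplace deviance."""

    def __init__(self, y, X, w, comm_idx, city_idx, city_of_comm):
        self.y, self.X, self.w = y, X, w
        self.comm_idx, self.city_idx = comm_idx, city_idx
        self.city_of_comm = city_of_comm
        self.n, self.p = X.shape
        self.J = len(city_of_comm)
        self.K = int(city_of_comm.max()) + 1 if self.J else int(city_idx.max()) + 1
        self.wy = w * y
        # warm-start state shared across outer evaluations
        self.beta = np.zeros(self.p)
        self.zc = np.zeros(self.K)
        self.zm = np.zeros(self.J)
        self.converged_inner = True

    def _eta(self, beta, zc, zm, sc, sm):
        eta = self.X @ beta
        if sc:
            eta = eta + sc * zc[self.city_idx]
        if sm:
            eta = eta + sm * zm[self.comm_idx]
        return eta

    def _penalized_loglik(self, eta, zc, zm):
        ll = float(np.sum(self.wy * eta - self.w * np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(zc @ zc + zm @ zm)

    def mode(self, sc: float, sm: float, gtol: float = 1e-9, max_iter: int = 100):
        """Newton iterations for the joint penalized mode; returns state dict."""
        beta, zc, zm = self.beta.copy(), self.zc.copy(), self.zm.copy()
        X, w, y = self.X, self.w, self.y
        comm_idx, city_idx, coc = self.comm_idx, self.city_idx, self.city_of_comm
        eta = self._eta(beta, zc, zm, sc, sm)
        obj = self._penalized_loglik(eta, zc, zm)
        gscale = gtol * max(1.0, float(np.sum(w)))
        converged = False
        a = atil = d = None
        for _ in range(max_iter):
            p_hat = sigmoid(eta)
            W = w * p_hat * (1.0 - p_hat)
            r = w * (y - p_hat)
            gb = X.T @ r
            gc = sc * _agg(city_idx, r, self.K) - zc
            gm = sm * _agg(comm_idx, r, self.J) - zm
            gnorm = max(
                np.abs(gb).max(initial=0.0),
                np.abs(gc).max(initial=0.0),
                np.abs(gm).max(initial=0.0),
            )
            # aggregates for the Hessian
            t = _agg(comm_idx, W, self.J)
            S = _agg(city_idx, W, self.K)
            a = sc * sc * S + 1.0
            d = sm * sm * t + 1.0
            b = sc * sm * t
            atil = a - _agg(coc, b * b / d, self.K)

            if gnorm < gscale:
                converged = True
                break

            WX = X * W[:, None]
            P = X.T @ WX
            Cc = sc * _agg(city_idx, WX, self.K)
            Cm = sm * _agg(comm_idx, WX, self.J)

            def msolve(vc, vm):
                vc2 = vc.reshape(self.K, -1)
                vm2 = vm.reshape(self.J, -1)
                bd = (b / d)[:, None] * vm2
                xc = (vc2 - _agg(coc, bd, self.K)) / atil[:, None]
                xm = (vm2 - b[:, None] * xc[coc]) / d[:, None]
                return xc, xm

            uc, um = msolve(gc, gm)
            Yc, Ym = msolve(Cc, Cm)
            A = P - (Cc.T @ Yc + Cm.T @ Ym)
            A[np.diag_indices_from(A)] += 1e-10
            rhs = gb - (Cc.T @ uc + Cm.T @ um).ravel()
            try:
                db = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                break
            dzc = uc.ravel() - Yc @ db
            dzm = um.ravel() - Ym @ db

            step = 1.0
            for _ in range(40):
                nb, nc, nm = beta + step * db, zc + step * dzc, zm + step * dzm
                neta = self._eta(nb, nc, nm, sc, sm)
                nobj = self._penalized_loglik(neta, nc, nm)
                if nobj >= obj - 1e-12:
                    break
                step *= 0.5
            if nobj < obj - 1e-10:
                break  # no ascent possible; stop with converged=False
            beta, zc, zm, eta = nb, nc, nm, neta
            if nobj - obj < 1e-12 * max(1.0, abs(obj)) and gnorm < 1e3 * gscale:
                obj = nobj
                converged = True
                # refresh a/d for logdet at the final point
                p_hat = sigmoid(eta)
                W = w * p_hat * (1.0 - p_hat)
                t = _agg(comm_idx, W, self.J)
                S = _agg(city_idx, W, self.K)
                a = sc * sc * S + 1.0
                d = sm * sm * t + 1.0
                b = sc * sm * t
                atil = a - _agg(coc, b * b / d, self.K)
                break
            obj = nobj

        self.beta, self.zc, self.zm = beta, zc, zm
        self.converged_inner = converged
        logdet = float(np.sum(np.log(atil)) + np.sum(np.log(d)))
        # conditional covariance of beta at the mode (for Wald SEs)
        p_hat = sigmoid(eta)
        W = w * p_hat * (1.0 - p_hat)
        WX = X * W[:, None]
        P = X.T @ WX
        if sc or sm:
            Cc = sc * _agg(city_idx, WX, self.K)
            Cm = sm * _agg(comm_idx, WX, self.J)
            b = sc * sm * t
            bd = (b / d)[:, None] * Cm
            Yc = (Cc - _agg(coc, bd, self.K)) / atil[:, None]
            Ym = (Cm - b[:, None] * Yc[coc]) / d[:, None]
            A = P - (Cc.T @ Yc + Cm.T @ Ym)
        else:
            A = P
        return {
            "beta": beta,
            "zc": zc,
            "zm": zm,
            "obj": obj,
            "logdet": logdet,
            "beta_info": A,
            "converged": converged,
        }

    def laplace_loglik(self, sc: float, sm: float) -> tuple[float, dict]:
        state = self.mode(sc, sm)
        return state["obj"] - 0.5 * state["logdet"], state

    def z_mode(self, beta, sc, sm, gtol: float = 1e-11, max_iter: int = 60):
        """Mode over the latent effects only, β held fixed (full Laplace).

        Returns the Laplace log-likelihood contribution and the aggregates
        needed for the log-determinant and Wald information.
        """
        zc, zm = self.zc.copy(), self.zm.copy()
        w, y = self.w, self.y
        comm_idx, city_idx, coc = self.comm_idx, self.city_idx, self.city_of_comm
        Xb = self.X @ beta
        gscale = gtol * max(1.0, float(np.sum(w)))
        eta = Xb + sc * zc[city_idx] + sm * zm[comm_idx]
        obj = self._penalized_loglik(eta, zc, zm)
        converged = False
        for _ in range(max_iter):
            p_hat = sigmoid(eta)
            W = w * p_hat * (1.0 - p_hat)
            r = w * (y - p_hat)
            gc = sc * _agg(city_idx, r, self.K) - zc
            gm = sm * _agg(comm_idx, r, self.J) - zm
            t = _agg(comm_idx, W, self.J)
            S = _agg(city_idx, W, self.K)
            a = sc * sc * S + 1.0
            d = sm * sm * t + 1.0
            b = sc * sm * t
            atil = a - _agg(coc, b * b / d, self.K)
            if max(np.abs(gc).max(initial=0.0), np.abs(gm).max(initial=0.0)) < gscale:
                converged = True
                break
            bd = (b / d) * gm
            dzc = (gc - _agg(coc, bd, self.K)) / atil
            dzm = (gm - b * dzc[coc]) / d
            step = 1.0
            for _ in range(40):
                nc, nm = zc + step * dzc, zm + step * dzm
                neta = Xb + sc * nc[city_idx] + sm * nm[comm_idx]
                nobj = self._penalized_loglik(neta, nc, nm)
                if nobj >= obj - 1e-12:
                    break
                step *= 0.5
            if nobj < obj - 1e-10:
                break
            zc, zm, eta, obj = nc, nm, neta, nobj
        self.zc, self.zm = zc, zm
        logdet = float(np.sum(np.log(atil)) + np.sum(np.log(d)))
        return {
            "obj": obj,
            "logdet": logdet,
            "loglik": obj - 0.5 * logdet,
            "converged": converged,
            "W_aggs": (t, S, a, d, b, atil),
            "eta": eta,
        }

    def beta_information(self, beta, sc, sm):
        """Conditional information of β at the current latent mode (Wald SEs)."""
        state = self.z_mode(beta, sc, sm)
        eta = state["eta"]
        p_hat = sigmoid(eta)
        W = self.w * p_hat * (1.0 - p_hat)
        WX = self.X * W[:, None]
        P = self.X.T @ WX
        t, S, a, d, b, atil = state["W_aggs"]
        if sc or sm:
            Cc = sc * _agg(self.city_idx, WX, self.K)
            Cm = sm * _agg(self.comm_idx, WX, self.J)
            bd = (b / d)[:, None] * Cm
            Yc = (Cc - _agg(self.city_of_comm, bd, self.K)) / atil[:, None]
            Ym = (Cm - b[:, None] * Yc[self.city_of_comm]) / d[:, None]
            P = P - (Cc.T @ Yc + Cm.T @ Ym)
        return P, state


def _wald_se(engine, beta, s_city, s_comm, free, cond_info):
    """Wald standard errors of the fixed effects.

    Primary route: invert the numerical observed information of the Laplace
    log-likelihood over (β, free σ) jointly, so variance-parameter
    uncertainty propagates into the fixed-effect SEs. Variance components at
    (or numerically near) the σ=0 boundary are excluded — the objective is
    flat to first order there. Falls back to the conditional-on-σ
    information if the joint Hessian is not positive definite.
    """
    p = len(beta)
    sig = [s_city, s_comm]
    keep = [j for j in range(2) if free[j] and sig[j] > 0.05]

    def f(x):
        vals = list(sig)
        for i, j in enumerate(keep):
            vals[j] = x[p + i]
        return -engine.z_mode(x[:p], vals[0], vals[1])["loglik"]

    x0 = np.concatenate([beta, [sig[j] for j in keep]])
    m = len(x0)
    h = 1e-3 * np.maximum(1.0, np.abs(x0))
    try:
        H = np.empty((m, m))
        f0 = f(x0)
        for i in range(m):
            ei = np.zeros(m)
            ei[i] = h[i]
            H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            for j in range(i):
                ej = np.zeros(m)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej)
                    + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:p]
        if (var <= 0).any():
            raise np.linalg.LinAlgError("non-PD joint Hessian")
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        try:
            return np.sqrt(np.clip(np.diag(np.linalg.inv(cond_info)), 0.0, None))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)


def _fit_binomial(y, X, names, w, comm_idx, city_idx, city_of_comm, spec, fix_sigma):
    engine = _LaplaceLogit(y, X, w, comm_idx, city_idx, city_of_comm)
    p = X.shape[1]
    free_city = "city" in spec.random_levels
    free_comm = "community" in spec.random_levels
    if fix_sigma is not None:
        s_city, s_comm = (float(np.sqrt(max(v, 0.0))) for v in fix_sigma)
        free_city = free_comm = False
    else:
        s_city = 0.3 if free_city else 0.0
        s_comm = 0.3 if free_comm else 0.0
    free = [free_city, free_comm]

    message = "ok"
    # Stage 1: cheap profiled search (β solved jointly with the latent mode)
    # to land near the optimum of the variance parameters.
    if any(free):

        def unpack(x):
            vals, i = [s_city, s_comm], 0
            for j in range(2):
                if free[j]:
                    vals[j] = abs(x[i])
                    i += 1
            return vals

        def profiled(x):
            sc, sm = unpack(x)
            ll, _ = engine.laplace_loglik(sc, sm)
            return -ll

        x0 = np.array([v for v, f in zip((s_city, s_comm), free) if f])
        res = optimize.minimize(
            profiled,
            x0,
            method="Nelder-Mead",
            bounds=[(0.0, 5.0)] * len(x0),
            options={"xatol": 5e-3, "fatol": 1e-5, "maxiter": 200},
        )
        s_city, s_comm = unpack(res.x)
    engine.laplace_loglik(s_city, s_comm)  # refresh joint-mode warm start

    # Stage 2: full Laplace — maximize over β and the free standard
    # deviations with the latent effects profiled out by the inner mode.
    def pack_full():
        return np.concatenate(
            [engine.beta, [v for v, f in zip((s_city, s_comm), free) if f]]
        )

    def unpack_full(x):
        beta = x[:p]
        vals, i = [s_city, s_comm], p
        for j in range(2):
            if free[j]:
                vals[j] = x[i]
                i += 1
        return beta, vals[0], vals[1]

    def objective(x):
        beta, sc, sm = unpack_full(x)
        return -engine.z_mode(beta, sc, sm)["loglik"]

    if any(free) or s_city > 0 or s_comm > 0:
        bounds = [(None, None)] * p + [(0.0, 5.0)] * sum(free)
        res2 = optimize.minimize(
            objective,
            pack_full(),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-6, "eps": 1e-6},
        )
        if not res2.success:
            # line searches can fail on finite-difference gradient noise;
            # restart once from the current point with a fresh memory
            res2b = optimize.minimize(
                objective,
                res2.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-6, "eps": 1e-5},
            )
            if res2b.fun <= res2.fun:
                res2 = res2b
        beta, s_city, s_comm = unpack_full(res2.x)
        if not res2.success:
            message = f"Laplace optimization did not converge: {res2.message}"
    else:
        # both variances pinned at zero: the joint Newton fit above *is* the
        # exact ML logit, no Laplace correction exists
        beta = engine.beta.copy()

    info, state = engine.beta_information(beta, s_city, s_comm)
    loglik = state["loglik"]
    converged = state["converged"] and message == "ok"
    if np.abs(beta).max(initial=0.0) > 15.0:
        converged = False
        message = (
            "possible separation: a fixed-effect estimate diverged "
            f"(max |beta| = {np.abs(beta).max():.1f})"
        )
    elif not state["converged"]:
        message = "inner Newton iterations did not converge"
    if not converged:
        warnings.warn(f"multilevel logit did not converge cleanly: {message}")
    se = _wald_se(engine, beta, s_city, s_comm, free, info)

    def floored(v):
        return 0.0 if v < VARIANCE_FLOOR else float(v)

    return MLMFit(
        spec=spec,
        coef=pd.Series(beta, index=names, name="coef"),
        se=pd.Series(se, index=names, name="se"),
        sigma2_city=floored(s_city**2),
        sigma2_community=floored(s_comm**2),
        sigma2_residual=LOGIT_RESIDUAL_VARIANCE,
        loglik=float(loglik),
        converged=converged,
        message=message,
        n_obs=len(y),
        n_communities=len(city_of_comm),
        n_cities=engine.K,
    )


# ----------------------------------------------------------------------
# gaussian special case (delegated to statsmodels MixedLM)
# ----------------------------------------------------------------------


def _fit_gaussian(data, spec, categories):
    import statsmodels.formula.api as smf

    terms = []
    for t in spec.fixed_terms:
        terms.append(f"C({t})" if t in categories else t)
    formula = f"{spec.outcome} ~ " + (" + ".join(terms) if terms else "1")
    levels = set(spec.random_levels)
    kwargs: dict = {}
    if levels == {"city", "community"}:
        kwargs = {
            "groups": "city_id",
            "re_formula": "1",
            "vc_formula": {"community": "0 + C(community_id)"},
        }
    elif levels == {"city"}:
        kwargs = {"groups": "city_id", "re_formula": "1"}
    elif levels == {"community"}:
        kwargs = {"groups": "community_id", "re_formula": "1"}
    else:
        raise ValueError("gaussian family requires at least one random level")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, **kwargs)
        res = model.fit(reml=False)

    def rename(name: str) -> str:
        if name == "Intercept":
            return "(Intercept)"
        if name.startswith("C(") and "[T." in name:
            cov = name[2 : name.index(")")]
            lev = name[name.index("[T.") + 3 : -1]
            return f"{cov}={lev}"
        return name

    fe = res.fe_params.rename(rename)
    se = res.bse.loc[res.fe_params.index].rename(rename)
    if levels == {"city", "community"}:
        s2_city = float(res.cov_re.iloc[0, 0])
        s2_comm = float(res.vcomp[0])
    elif levels == {"city"}:
        s2_city, s2_comm = float(res.cov_re.iloc[0, 0]), 0.0
    else:
        s2_city, s2_comm = 0.0, float(res.cov_re.iloc[0, 0])
    return MLMFit(
        spec=spec,
        coef=fe,
        se=se,
        sigma2_city=s2_city,
        sigma2_community=s2_comm,
        sigma2_residual=float(res.scale),
        loglik=float(res.llf),
        converged=bool(res.converged),
        message="ok" if res.converged else "MixedLM did not converge",
        n_obs=int(res.nobs),
        n_communities=int(data["community_id"].nunique()),
        n_cities=int(data["city_id"].nunique()),
    )


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------


def fit_multilevel(
    cohort: pd.DataFrame,
    spec: MLMSpec,
    weights: Sequence[float] | pd.Series | None = None,
    fix_sigma: tuple[float, float] | None = None,
    categories: Mapping[str, Sequence[str]] | None = None,
) -> MLMFit:
    """Fit a random-intercept model for ``spec`` on ``cohort``.

    ``weights`` (defaulting to the cohort's ``weight`` column when
    ``spec.use_weights``) multiply each observation's log-likelihood
    contribution; zero-weight records are dropped. ``fix_sigma`` pins the
    (city, community) variance components instead of estimating them — with
    ``(0, 0)`` the fit is an ordinary weighted logit.
    """
    spec.validate()
    if spec.outcome not in cohort.columns:
        raise KeyError(f"outcome {spec.outcome!r} not in cohort")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    elif spec.use_weights and "weight" in cohort.columns:
        w = cohort["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(len(cohort))
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    keep = w > 0
    data = cohort.loc[keep].reset_index(drop=True)
    w = w[keep]

    nunique = data.groupby("community_id")["city_id"].nunique()
    if (nunique > 1).any():
        raise ValueError(
            "ids are not nested: some community_id maps to multiple city_id"
        )

    if categories is None:
        categories = infer_categories(data, spec.fixed_terms)
    if spec.family == "gaussian":
        if not np.allclose(w, w[0]):
            raise NotImplementedError(
                "the gaussian special case does not support unequal weights"
            )
        return _fit_gaussian(data, spec, categories)

    y = data[spec.outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {spec.outcome!r} must be binary for the logit family")
    X, names = build_design(data, spec.fixed_terms, categories)
    comm_codes, comm_levels = pd.factorize(data["community_id"], sort=True)
    city_codes, _ = pd.factorize(data["city_id"], sort=True)
    city_of_comm = (
        data.groupby(pd.Series(comm_codes, name="comm"))["city_id"]
        .first()
        .pipe(lambda s: pd.factorize(s, sort=True)[0])
    )
    return _fit_binomial(
        y, X, names, w, comm_codes, city_codes, np.asarray(city_of_comm), spec,
        fix_sigma,
    )


def icc_from_variances(
    sigma2_city: float,
    sigma2_community: float,
    level: str,
    sigma2_residual: float | None = None,
) -> float:
    """Latent-scale intraclass correlation from variance components.

    ``level`` is ``"city"`` (share of the city component) or
    ``"community_cumulative"`` (share of city + community). The level-1
    variance defaults to the logistic latent-scale constant π²/3.
    """
    if sigma2_city < 0 or sigma2_community < 0:
        raise ValueError("variance components must be nonnegative")
    resid = LOGIT_RESIDUAL_VARIANCE if sigma2_residual is None else sigma2_residual
    if resid <= 0:
        raise ValueError("residual variance must be positive")
    total = sigma2_city + sigma2_community + resid
    if level == "city":
        return sigma2_city / total
    if level == "community_cumulative":
        return (sigma2_city + sigma2_community) / total
    raise ValueError(f"unknown ICC level {level!r}")


def icc(fit: MLMFit, level: str) -> float:
    """Latent-scale ICC of a fitted model (π²/3 for logit, σ²_e for gaussian)."""
    return icc_from_variances(
        fit.sigma2_city, fit.sigma2_community, level, fit.sigma2_residual
    )


def needs_multilevel(icc_value: float, threshold: float = ICC_THRESHOLD) -> bool:
    """True iff the ICC strictly exceeds the conventional 0.059 threshold."""
    if not 0.0 <= icc_value < 1.0:
        raise ValueError(f"ICC must be in [0, 1), got {icc_value}")
    return icc_value > threshold
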