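"""Synthetic hierarchical survey cohorts with known ground truth.

Emulates a three-level "city → community → worker" survey of rural migrant
workers enrolled in a county-pooled health-insurance scheme: categorical
person-level covariates, covariate-dependent assignment to the *in-county*
vs *across-county* migration group (selection bias), group-specific logit
coefficients for two binary utilization outcomes (two-week outpatient visit,
12-month inpatient admission), and independent normal random intercepts for
community and city on the latent logit scale.

Every random draw (city/community effects, selection propensities) is
returned alongside the cohort so downstream estimators can be tested against
the true data-generating process. A single master seed drives one
``numpy.random.SeedSequence`` split per stage, so each table is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._design import INTERCEPT, build_design, coef_vector, sigmoid

GROUP_IN = "in_county"
GROUP_ACROSS = "across_county"
GROUP_LABELS = (GROUP_IN, GROUP_ACROSS)

OUTPATIENT = "outpatient_2w"
INPATIENT = "inpatient_12m"
OUTCOMES = (OUTPATIENT, INPATIENT)

ID_COLUMNS = ("person_id", "city_id", "community_id")
MANDATORY_COLUMNS = ID_COLUMNS + ("group",) + OUTCOMES


@dataclass(frozen=True)
class Covariate:
    """A categorical person-level covariate with marginal category shares."""

    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...]

    def validate(self) -> None:
        if len(self.categories) != len(self.probs) or len(self.categories) < 1:
            raise ValueError(
                f"covariate {self.name!r}: categories and probs must align"
            )
        if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-8:
            raise ValueError(
                f"covariate {self.name!r}: marginal probabilities must be "
                f"nonnegative and sum to 1 (got {self.probs})"
            )


# Defaults emulate the composition of a ~3300-person rural-migrant-worker
# cohort: age-group and income shares close to the published survey margins,
# self-assessed health (SAH) skewed toward "good".
DEFAULT_COVARIATES: tuple[Covariate, ...] = (
    Covariate("age_group", ("15~36", "36~50", "50~64"), (0.39, 0.36, 0.25)),
    Covariate("gender", ("men", "women"), (0.575, 0.425)),
    Covariate(
        "income_quintile",
        ("poorest", "poorer", "middle", "richer", "richest"),
        (0.2, 0.2, 0.2, 0.2, 0.2),
    ),
    Covariate("sah", ("good", "fair", "poor"), (0.688, 0.252, 0.060)),
)

# Group-assignment logit P(across-county | x): younger, richer and slightly
# more female workers migrate farther, reproducing the selection bias the
# matching stage is there to remove. Overall across-county share ≈ 0.17.
DEFAULT_SELECTION_COEFS: dict[str, float] = {
    INTERCEPT: -1.55,
    "age_group=36~50": -0.18,
    "age_group=50~64": -0.83,
    "gender=women": 0.23,
    "income_quintile=poorer": -0.38,
    "income_quintile=middle": 0.05,
    "income_quintile=richer": 0.59,
    "income_quintile=richest": 0.68,
    "sah=fair": -0.02,
    "sah=poor": -0.33,
}

# Outcome coefficients per group, loosely calibrated to the published
# odds-ratio tables (poor self-assessed health strongly raises outpatient
# use; extreme published ORs are damped to keep prevalences realistic).
# The across-county intercepts are tuned so the CEM-matched weighted gaps
# come out slightly negative (≈ −0.004 outpatient, ≈ −0.007 inpatient),
# the regime the comparison emulates: marginally lower utilization for
# workers insured outside the county pool.
DEFAULT_BETA_IN: dict[str, dict[str, float]] = {
    OUTPATIENT: {
        INTERCEPT: -3.0,
        "age_group=36~50": -0.14,
        "age_group=50~64": -0.33,
        "gender=women": -0.16,
        "income_quintile=poorer": -0.03,
        "income_quintile=middle": -0.33,
        "income_quintile=richer": 0.11,
        "income_quintile=richest": -0.75,
        "sah=fair": 1.24,
        "sah=poor": 2.17,
    },
    INPATIENT: {
        INTERCEPT: -2.77,
        "age_group=36~50": -0.22,
        "age_group=50~64": 0.25,
        "gender=women": 0.35,
        "income_quintile=poorer": 0.05,
        "income_quintile=middle": 0.02,
        "income_quintile=richer": -0.03,
        "income_quintile=richest": 0.46,
        "sah=fair": -0.05,
        "sah=poor": 0.43,
    },
}
DEFAULT_BETA_ACROSS: dict[str, dict[str, float]] = {
    OUTPATIENT: {
        INTERCEPT: -3.42,
        "age_group=36~50": -0.64,
        "age_group=50~64": -0.13,
        "gender=women": 0.40,
        "income_quintile=poorer": -0.50,
        "income_quintile=middle": -0.60,
        "income_quintile=richer": -0.40,
        "income_quintile=richest": -0.30,
        "sah=fair": 1.73,
        "sah=poor": 2.87,
    },
    INPATIENT: {
        INTERCEPT: -2.42,
        "age_group=36~50": -0.80,
        "age_group=50~64": -0.68,
        "gender=women": 1.20,
        "income_quintile=poorer": -0.60,
        "income_quintile=middle": -0.11,
        "income_quintile=richer": -0.90,
        "income_quintile=richest": -1.06,
        "sah=fair": 0.27,
        "sah=poor": -0.40,
    },
}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions this generator emulates: a cohort
    of 55 cities × 4 communities × 15 workers ≈ 3300 persons, latent-scale
    variance components ``sigma2_city=0.396`` and ``sigma2_community=0.109``
    (the published null-model estimates for the in-county outpatient model),
    and covariate-dependent group assignment.
    """

    n_cities: int = 55
    communities_per_city: int = 4
    workers_per_community: int = 15
    sigma2_city: float = 0.396
    sigma2_community: float = 0.109
    beta_in: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETA_IN.items()}
    )
    beta_across: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETA_ACROSS.items()}
    )
    selection_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SELECTION_COEFS)
    )
    covariates: tuple[Covariate, ...] = DEFAULT_COVARIATES
    seed: int = 0
    #: optional joint sampler ``f(rng, n) -> DataFrame`` replacing independent
    #: marginal draws; lets tests create covariate-dependent scenarios.
    joint_sampler: Callable[[np.random.Generator, int], pd.DataFrame] | None = None

    @property
    def n_workers(self) -> int:
        return self.n_cities * self.communities_per_city * self.workers_per_community

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def categories(self) -> dict[str, list[str]]:
        return {c.name: list(c.categories) for c in self.covariates}

    def validate(self) -> None:
        for name, value in (
            ("n_cities", self.n_cities),
            ("communities_per_city", self.communities_per_city),
            ("workers_per_community", self.workers_per_community),
        ):
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if self.sigma2_city < 0 or self.sigma2_community < 0:
            raise ValueError("variance components must be nonnegative")
        for cov in self.covariates:
            cov.validate()
        from ._design import design_columns

        names = set(design_columns(self.covariate_names, self.categories))
        for label, coefs in [("selection_coefs", self.selection_coefs)] + [
            (f"beta_in[{o}]", b) for o, b in self.beta_in.items()
        ] + [(f"beta_across[{o}]", b) for o, b in self.beta_across.items()]:
            unknown = set(coefs) - names
            if unknown:
                raise ValueError(
                    f"{label}: coefficients {sorted(unknown)} do not match the "
                    "covariate schema"
                )
        if set(self.beta_in) != set(self.beta_across):
            raise ValueError("beta_in and beta_across must cover the same outcomes")
        for outcome in self.beta_in:
            if set(self.beta_in[outcome]) != set(self.beta_across[outcome]):
                raise ValueError(
                    f"beta_in and beta_across for {outcome!r} must have "
                    "identical coefficient names"
                )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("joint_sampler")
        d["covariates"] = [
            {"name": c.name, "categories": list(c.categories), "probs": list(c.probs)}
            for c in self.covariates
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationSpec":
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = tuple(
                Covariate(c["name"], tuple(c["categories"]), tuple(c["probs"]))
                for c in d["covariates"]
            )
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedCohort:
    """A simulated cohort plus the ground-truth draws that generated it."""

    cohort: pd.DataFrame
    city_effects: pd.DataFrame  # index city_id, one column per outcome
    community_effects: pd.DataFrame  # index community_id, one column per outcome
    selection_propensity: np.ndarray  # P(across-county | x) per person
    spec: SimulationSpec


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Draw a cohort from the three-level logit data-generating process.

    Outcomes follow Bernoulli(logit⁻¹(x'β_group + ν_city + μ_community)) with
    ν ~ N(0, sigma2_city) and μ ~ N(0, sigma2_community) drawn independently
    per outcome; group membership follows Bernoulli(logit⁻¹(x'selection_coefs)).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    s_cov, s_sel, s_city, s_comm, s_out = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    n = spec.n_workers
    n_comm = spec.n_cities * spec.communities_per_city
    city_id = np.repeat(
        np.arange(spec.n_cities),
        spec.communities_per_city * spec.workers_per_community,
    )
    community_id = np.repeat(np.arange(n_comm), spec.workers_per_community)

    if spec.joint_sampler is not None:
        covs = spec.joint_sampler(s_cov, n)
        missing = [c for c in spec.covariate_names if c not in covs.columns]
        if missing:
            raise ValueError(f"joint_sampler did not produce covariates {missing}")
        covs = covs[spec.covariate_names].reset_index(drop=True)
    else:
        covs = pd.DataFrame(
            {
                c.name: s_cov.choice(list(c.categories), size=n, p=list(c.probs))
                for c in spec.covariates
            }
        )

    X, names = build_design(covs, spec.covariate_names, spec.categories)
    propensity = sigmoid(X @ coef_vector(names, spec.selection_coefs))
    across = s_sel.random(n) < propensity
    group = np.where(across, GROUP_ACROSS, GROUP_IN)

    outcomes = sorted(spec.beta_in)
    nu = pd.DataFrame(
        {
            o: s_city.normal(0.0, np.sqrt(spec.sigma2_city), spec.n_cities)
            for o in outcomes
        }
    )
    nu.index.name = "city_id"
    mu = pd.DataFrame(
        {
            o: s_comm.normal(0.0, np.sqrt(spec.sigma2_community), n_comm)
            for o in outcomes
        }
    )
    mu.index.name = "community_id"

    data = {
        "person_id": np.arange(n),
        "city_id": city_id,
        "community_id": community_id,
        "group": group,
    }
    data.update({c: covs[c].to_numpy() for c in spec.covariate_names})
    for outcome in outcomes:
        lp = np.where(
            across,
            X @ coef_vector(names, spec.beta_across[outcome]),
            X @ coef_vector(names, spec.beta_in[outcome]),
        )
        lp = lp + nu[outcome].to_numpy()[city_id] + mu[outcome].to_numpy()[community_id]
        data[outcome] = (s_out.random(n) < sigmoid(lp)).astype(np.int64)
    data["weight"] = np.ones(n)

    return SimulatedCohort(
        cohort=pd.DataFrame(data),
        city_effects=nu,
        community_effects=mu,
        selection_propensity=propensity,
        spec=spec,
    )


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort contract: columns, binary outcomes, strict nesting."""
    for col in MANDATORY_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing mandatory column {col!r}")
    for outcome in OUTCOMES:
        values = set(pd.unique(cohort[outcome]))
        if not values <= {0, 1}:
            raise ValueError(
                f"outcome {outcome!r} must be binary 0/1, found values "
                f"{sorted(values - {0, 1})!r}"
            )
    groups = set(cohort["group"].unique())
    if not groups <= set(GROUP_LABELS):
        raise ValueError(
            f"group labels must be among {GROUP_LABELS}, found {sorted(groups)}"
        )
    parents = cohort.groupby("community_id")["city_id"].nunique()
    if (parents > 1).any():
        bad = parents[parents > 1].index.tolist()
        raise ValueError(f"communities nested in more than one city: {bad}")
    if "weight" in cohort.columns and (cohort["weight"] < 0).any():
        raise ValueError("weights must be nonnegative")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to UTF-8 CSV (header row, outcomes as 0/1 integers)."""
    validate_cohort(cohort)
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; a missing weight column defaults to 1."""
    cohort = pd.read_csv(path)
    if "weight" not in cohort.columns:
        cohort["weight"] = 1.0
    cohort["weight"] = cohort["weight"].astype(float)
    validate_cohort(cohort)
    for outcome in OUTCOMES:
        cohort[outcome] = cohort[outcome].astype(np.int64)
    return cohort
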