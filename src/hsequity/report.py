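"""End-to-end pipeline: simulate/load → match → fit → decompose → report.

Runs the full comparative analysis on a cohort (synthetic or user-supplied)
and writes the table set of a matched two-group utilization study:

* ``l1_summary.json`` + ``balance.csv`` — multivariate/univariate L1 and the
  per-covariate weighted balance table before and after matching;
* ``null_models.csv`` — variance components of the intercept-only
  three-level logits per outcome × group, latent-scale ICCs and the 0.059
  decision;
* ``model_fits.csv`` — covariate-adjusted multilevel fits per
  outcome × group (odds ratios, SEs, significance stars);
* ``decomposition_<outcome>.csv`` — Fairlie decomposition with per-block
  contributions plus the need/inequity partition rows;
* ``manifest.json`` — seeds, package version and all settings, so a rerun
  with the same config reproduces every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cem import cem_match
from .fairlie import fairlie_decompose, fit_pooled_logit
from .inequity import DEFAULT_NEED_BLOCKS, NeedPartition, inequity_from_decomposition
from .mlm import MLMSpec, fit_multilevel, icc, needs_multilevel
from .simulate import (
    GROUP_ACROSS,
    GROUP_IN,
    OUTCOMES,
    SimulationSpec,
    read_cohort,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger("hsequity")

GROUPS = (GROUP_IN, GROUP_ACROSS)


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class PipelineConfig:
    """Settings of one pipeline run; exactly one input source must be set."""

    simulation: SimulationSpec | None = None
    input_path: str | None = None
    out_dir: str = "hsequity_output"
    matching_covariates: tuple[str, ...] = (
        "age_group",
        "gender",
        "income_quintile",
        "sah",
    )
    #: None → exact matching on the observed categories
    coarsening: dict | None = None
    model_covariates: tuple[str, ...] = (
        "age_group",
        "gender",
        "income_quintile",
        "sah",
    )
    outcomes: tuple[str, ...] = OUTCOMES
    random_levels: tuple[str, ...] = ("city", "community")
    decomposition_blocks: tuple[str, ...] | None = None  # None → model_covariates
    n_orderings: int = 100
    n_subsample_draws: int = 100
    need_blocks: tuple[str, ...] = DEFAULT_NEED_BLOCKS
    seed: int = 0

    def validate(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ValueError(
                "exactly one of `simulation` and `input_path` must be provided"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationSpec.from_dict(d["simulation"])
        for key in (
            "matching_covariates",
            "model_covariates",
            "outcomes",
            "random_levels",
            "need_blocks",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("decomposition_blocks") is not None:
            d["decomposition_blocks"] = tuple(d["decomposition_blocks"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame
    match: object
    null_fits: dict
    model_fits: dict
    decompositions: dict
    inequity: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _configure_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    logger.addHandler(fh)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage; a failure aborts with the stage name, keeping
    whatever outputs earlier stages already wrote."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _configure_logging(out)
    paths: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "input"
        if config.simulation is not None:
            logger.info("simulating cohort (seed=%d)", config.simulation.seed)
            sim = simulate_cohort(config.simulation)
            cohort = sim.cohort
            paths["cohort"] = out / "cohort.csv"
            write_cohort(cohort, paths["cohort"])
        else:
            logger.info("reading cohort from %s", config.input_path)
            cohort = read_cohort(config.input_path)

        stage = "match"
        match = cem_match(cohort, config.matching_covariates, config.coarsening)
        logger.info(
            "CEM: L1 %.4f -> %.3g; matched %s",
            match.l1_before,
            match.l1_after,
            match.n_matched,
        )
        paths.update(match.to_files(out))
        weights = match.cem_weight.to_numpy()

        stage = "null models"
        null_fits, null_rows = {}, []
        for outcome in config.outcomes:
            for group in GROUPS:
                mask = (cohort["group"] == group).to_numpy()
                fit = fit_multilevel(
                    cohort.loc[mask],
                    MLMSpec(outcome=outcome, random_levels=config.random_levels),
                    weights=weights[mask],
                )
                null_fits[(outcome, group)] = fit
                icc_city = icc(fit, "city")
                icc_cum = icc(fit, "community_cumulative")
                null_rows.append(
                    {
                        "outcome": outcome,
                        "group": group,
                        "intercept": fit.coef["(Intercept)"],
                        "intercept_se": fit.se["(Intercept)"],
                        "sigma2_city": fit.sigma2_city,
                        "sigma2_community": fit.sigma2_community,
                        "icc_city": icc_city,
                        "icc_community_cumulative": icc_cum,
                        "needs_multilevel": needs_multilevel(icc_cum),
                        "loglik": fit.loglik,
                        "converged": fit.converged,
                    }
                )
                logger.info(
                    "null model %s/%s: s2_city=%.3g s2_comm=%.3g ICC=%.3f/%.3f",
                    outcome,
                    group,
                    fit.sigma2_city,
                    fit.sigma2_community,
                    icc_city,
                    icc_cum,
                )
        paths["null_models"] = out / "null_models.csv"
        pd.DataFrame(null_rows).to_csv(paths["null_models"], index=False)

        stage = "multilevel fits"
        model_fits, fit_rows = {}, []
        for outcome in config.outcomes:
            for group in GROUPS:
                mask = (cohort["group"] == group).to_numpy()
                fit = fit_multilevel(
                    cohort.loc[mask],
                    MLMSpec(
                        outcome=outcome,
                        person_terms=config.model_covariates,
                        random_levels=config.random_levels,
                    ),
                    weights=weights[mask],
                )
                model_fits[(outcome, group)] = fit
                frame = fit.summary_frame().reset_index(names="term")
                frame.insert(0, "group", group)
                frame.insert(0, "outcome", outcome)
                frame["sig"] = frame["p"].map(stars)
                fit_rows.append(frame)
                logger.info(
                    "fit %s/%s: converged=%s loglik=%.2f", outcome, group,
                    fit.converged, fit.loglik,
                )
        paths["model_fits"] = out / "model_fits.csv"
        pd.concat(fit_rows, ignore_index=True).to_csv(
            paths["model_fits"], index=False
        )

        stage = "decomposition"
        blocks = config.decomposition_blocks or config.model_covariates
        seed_seq = np.random.SeedSequence(config.seed).spawn(len(config.outcomes))
        decompositions, inequities = {}, {}
        for outcome, child in zip(config.outcomes, seed_seq):
            pooled = fit_pooled_logit(
                cohort, outcome, list(blocks), weights=weights
            )
            dec = fairlie_decompose(
                cohort,
                outcome,
                list(blocks),
                pooled,
                weights=weights,
                n_orderings=config.n_orderings,
                n_subsample_draws=config.n_subsample_draws,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            partition = NeedPartition(
                tuple(b for b in config.need_blocks if b in blocks)
            )
            ineq = inequity_from_decomposition(dec, partition)
            decompositions[outcome] = dec
            inequities[outcome] = ineq
            table = dec.to_frame().reset_index()
            header = pd.DataFrame(
                {
                    "block": ["total_gap", "explained_pct"],
                    "contribution": [dec.total_gap, np.nan],
                    "contribution_pct": [np.nan, dec.explained_percent],
                    "mc_se": [np.nan, np.nan],
                }
            )
            footer = pd.DataFrame(
                {
                    "block": ["difference_caused_by_need", "inequity_index"],
                    "contribution": [ineq.need_difference, ineq.inequity_index],
                    "contribution_pct": [ineq.need_percent, ineq.inequity_percent],
                    "mc_se": [np.nan, np.nan],
                }
            )
            full = pd.concat([header, table, footer], ignore_index=True)
            paths[f"decomposition_{outcome}"] = out / f"decomposition_{outcome}.csv"
            full.to_csv(paths[f"decomposition_{outcome}"], index=False)
            logger.info(
                "decomposition %s: gap=%.4f explained=%.1f%% inequity=%.4f",
                outcome,
                dec.total_gap,
                dec.explained_percent,
                ineq.inequity_index,
            )

        stage = "manifest"
        manifest = {
            "hsequity_version": __version__,
            "config": config.to_dict(),
            "n_records": int(len(cohort)),
            "n_matched": match.n_matched,
            "L1_before": match.l1_before,
            "L1_after": match.l1_after,
        }
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    except Exception as err:
        logger.error("pipeline failed at stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return PipelineResult(
        config=config,
        cohort=cohort,
        match=match,
        null_fits=null_fits,
        model_fits=model_fits,
        decompositions=decompositions,
        inequity=inequities,
        paths=paths,
    )
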