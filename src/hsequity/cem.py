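"""Coarsened exact matching (CEM) with L1 imbalance diagnostics.

Records are matched by exact agreement on coarsened covariates: each record
is assigned to the stratum defined by the tuple of its coarsened values, and
strata containing both migration groups are kept. The across-county group
(the smaller, "treated" group) keeps weight 1; in-county records in stratum
``s`` receive weight ``(m_s^across / m_s^in) × (M^in / M^across)`` where
``m`` are stratum counts among matched records and ``M`` matched totals —
the convention of the Stata ``cem`` command. These weights make the two
groups' coarsened covariate distributions identical, so the multivariate L1
imbalance on the matching covariates is zero (up to floating point) after
matching.

L1 imbalance between groups is half the sum of absolute differences of their
(weighted) relative frequencies over the coarsened cross-classification:
0 means balanced, 1 maximal (disjoint) imbalance.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GROUP_ACROSS, GROUP_IN

#: Per-covariate rule: an explicit category list (used as-is) or strictly
#: increasing numeric cut-points producing bins.
CoarseningScheme = Mapping[str, Sequence]


def _is_numeric_rule(rule: Sequence) -> bool:
    return all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in rule)


def _bin_labels(cuts: Sequence[float]) -> list[str]:
    labels = [f"<{cuts[0]:g}"]
    labels += [f"{lo:g}~{hi:g}" for lo, hi in zip(cuts[:-1], cuts[1:])]
    labels.append(f">={cuts[-1]:g}")
    return labels


def coarsen(cohort: pd.DataFrame, scheme: CoarseningScheme) -> pd.DataFrame:
    """Apply a coarsening scheme, returning one string column per covariate.

    Numeric cut-points ``(c1, …, ck)`` create the k+1 half-open bins
    ``(-inf, c1), [c1, c2), …, [ck, inf)``; an explicit category list keeps
    values as-is but raises on values outside the list.
    """
    out = {}
    for cov, rule in scheme.items():
        if cov not in cohort.columns:
            raise KeyError(f"matching covariate {cov!r} not in cohort")
        rule = list(rule)
        if not rule:
            raise ValueError(f"empty coarsening rule for {cov!r}")
        if _is_numeric_rule(rule):
            cuts = [float(c) for c in rule]
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(
                    f"cut-points for {cov!r} must be strictly increasing: {cuts}"
                )
            values = pd.to_numeric(cohort[cov]).to_numpy(dtype=float)
            labels = np.array(_bin_labels(cuts))
            out[cov] = labels[np.digitize(values, cuts)]
        else:
            allowed = [str(v) for v in rule]
            values = cohort[cov].astype(str).to_numpy()
            bad = ~np.isin(values, allowed)
            if bad.any():
                raise ValueError(
                    f"value {values[bad][0]!r} of {cov!r} outside coarsening "
                    f"categories {allowed}"
                )
            out[cov] = values
    return pd.DataFrame(out, index=cohort.index)


def identity_scheme(cohort: pd.DataFrame, covariates: Sequence[str]) -> dict:
    """Scheme that keeps each (categorical) covariate's observed levels as-is."""
    return {c: sorted(cohort[c].astype(str).unique()) for c in covariates}


def stratum_ids(coarsened: pd.DataFrame) -> pd.Series:
    """Stratum label per record: the tuple of coarsened covariate values."""
    return pd.Series(
        list(map(tuple, coarsened.to_numpy())), index=coarsened.index, name="stratum_id"
    )


def l1_imbalance(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    scheme: CoarseningScheme | None = None,
    weights: np.ndarray | pd.Series | None = None,
    group_col: str = "group",
) -> float:
    """Multivariate (or univariate) L1 imbalance between the two groups.

    ``L1 = ½ Σ_cells |f_cell − g_cell|`` over the coarsened
    cross-classification of ``covariates``, where ``f`` and ``g`` are the
    weighted relative frequencies of the two groups. Passing one covariate
    gives the univariate L1.
    """
    if scheme is None:
        scheme = identity_scheme(cohort, covariates)
    scheme = {c: scheme[c] for c in covariates}
    cells = stratum_ids(coarsen(cohort, scheme))
    w = (
        np.ones(len(cohort))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    groups = cohort[group_col].to_numpy()
    table = pd.DataFrame({"cell": cells.to_numpy(), "group": groups, "w": w})
    sums = table.pivot_table(
        index="cell", columns="group", values="w", aggfunc="sum", fill_value=0.0
    )
    for g in (GROUP_IN, GROUP_ACROSS):
        if g not in sums.columns or sums[g].sum() <= 0:
            raise ValueError(f"group {g!r} is empty after weighting")
    f = sums[GROUP_IN] / sums[GROUP_IN].sum()
    g = sums[GROUP_ACROSS] / sums[GROUP_ACROSS].sum()
    return 0.5 * float(np.abs(f - g).sum())


def balance_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    weights: np.ndarray | pd.Series | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Weighted counts, column percentages and chi-square p-value per covariate.

    The test is Pearson's chi-square applied to weight-scaled (effective)
    counts. A covariate with a single observed level gets a NaN p-value
    rather than an exception.
    """
    w = (
        np.ones(len(cohort))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    rows = []
    for cov in covariates:
        counts = pd.DataFrame(
            {"level": cohort[cov].astype(str), "group": cohort[group_col], "w": w}
        ).pivot_table(
            index="level", columns="group", values="w", aggfunc="sum", fill_value=0.0
        )
        counts = counts.reindex(columns=[GROUP_IN, GROUP_ACROSS], fill_value=0.0)
        observed = counts.to_numpy()
        keep = observed.sum(axis=1) > 0
        if keep.sum() < 2 or (observed[keep].sum(axis=0) <= 0).any():
            pvalue = np.nan
        else:
            pvalue = stats.chi2_contingency(observed[keep], correction=False)[1]
        shares = counts / counts.sum(axis=0).replace(0.0, np.nan)
        for level in counts.index:
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "n_in_county": counts.loc[level, GROUP_IN],
                    "n_across_county": counts.loc[level, GROUP_ACROSS],
                    "pct_in_county": 100 * shares.loc[level, GROUP_IN],
                    "pct_across_county": 100 * shares.loc[level, GROUP_ACROSS],
                    "p_value": pvalue,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MatchResult:
    """Output of :func:`cem_match`.

    ``cem_weight`` follows the Stata ``cem`` convention (treated = across-county
    records weight 1; unmatched records weight 0); ``equalized_weights`` rescales
    the comparison group so both groups' weighted totals equal the matched
    treated-group size — the "equalize the number of two groups" reading.
    """

    stratum_id: pd.Series
    cem_weight: pd.Series
    n_matched: dict[str, int]
    l1_before: float
    l1_after: float
    univariate_l1: pd.DataFrame  # index covariate, columns before/after
    balance_before: pd.DataFrame
    balance_after: pd.DataFrame
    matching_covariates: list[str]
    treated_group: str = GROUP_ACROSS

    @property
    def matched(self) -> pd.Series:
        return self.cem_weight > 0

    def equalized_weights(self, cohort: pd.DataFrame) -> pd.Series:
        """CEM weights rescaled so each group's weighted total is M^treated."""
        w = self.cem_weight.copy()
        comparison = cohort["group"] != self.treated_group
        total_c = w[comparison].sum()
        if total_c > 0:
            w.loc[comparison] *= self.n_matched[self.treated_group] / total_c
        return w

    def to_files(self, out_dir) -> dict[str, Path]:
        """Serialize: record-level weights CSV, balance CSV, JSON L1 summary."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        weights = pd.DataFrame(
            {
                "stratum_id": self.stratum_id.map(lambda t: "|".join(t)),
                "cem_weight": self.cem_weight,
            }
        )
        paths["weights"] = out_dir / "cem_weights.csv"
        weights.to_csv(paths["weights"], index_label="row")
        balance = pd.concat(
            {"before": self.balance_before, "after": self.balance_after},
            names=["stage"],
        ).reset_index(level="stage")
        paths["balance"] = out_dir / "balance.csv"
        balance.to_csv(paths["balance"], index=False)
        summary = {
            "matching_covariates": self.matching_covariates,
            "n_matched": self.n_matched,
            "L1_before": self.l1_before,
            "L1_after": self.l1_after,
            "univariate_L1": {
                cov: {
                    "before": float(self.univariate_l1.loc[cov, "before"]),
                    "after": float(self.univariate_l1.loc[cov, "after"]),
                }
                for cov in self.univariate_l1.index
            },
        }
        paths["summary"] = out_dir / "cem_summary.json"
        paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
        return paths


def cem_match(
    cohort: pd.DataFrame,
    matching_covariates: Sequence[str],
    scheme: CoarseningScheme | None = None,
) -> MatchResult:
    """Match the two groups by coarsened exact matching.

    Raises a "no common support" error if no stratum contains both groups.
    """
    matching_covariates = list(matching_covariates)
    if scheme is None:
        scheme = identity_scheme(cohort, matching_covariates)
    scheme = {c: scheme[c] for c in matching_covariates}
    for g in (GROUP_IN, GROUP_ACROSS):
        if (cohort["group"] == g).sum() == 0:
            raise ValueError(f"cohort has no records in group {g!r}")

    strata = stratum_ids(coarsen(cohort, scheme))
    is_treated = (cohort["group"] == GROUP_ACROSS).to_numpy()
    counts = pd.DataFrame(
        {"stratum": strata.to_numpy(), "treated": is_treated}
    ).pivot_table(index="stratum", columns="treated", aggfunc="size", fill_value=0)
    counts = counts.reindex(columns=[False, True], fill_value=0)
    both = (counts[True] > 0) & (counts[False] > 0)
    if not both.any():
        raise ValueError(
            "no common support: no stratum contains both migration groups"
        )
    matched_strata = counts.index[both]
    m_treat = counts.loc[matched_strata, True]
    m_comp = counts.loc[matched_strata, False]
    M_treat, M_comp = int(m_treat.sum()), int(m_comp.sum())
    comp_weight = (m_treat / m_comp) * (M_comp / M_treat)

    in_matched = strata.isin(matched_strata).to_numpy()
    weight = np.zeros(len(cohort))
    weight[in_matched & is_treated] = 1.0
    comp_mask = in_matched & ~is_treated
    weight[comp_mask] = comp_weight.reindex(strata.to_numpy()[comp_mask]).to_numpy()
    weight = pd.Series(weight, index=cohort.index, name="cem_weight")

    l1_before = l1_imbalance(cohort, matching_covariates, scheme)
    l1_after = l1_imbalance(cohort, matching_covariates, scheme, weights=weight)
    uni = pd.DataFrame(
        {
            "before": [
                l1_imbalance(cohort, [c], scheme) for c in matching_covariates
            ],
            "after": [
                l1_imbalance(cohort, [c], scheme, weights=weight)
                for c in matching_covariates
            ],
        },
        index=pd.Index(matching_covariates, name="covariate"),
    )
    return MatchResult(
        stratum_id=strata,
        cem_weight=weight,
        n_matched={GROUP_ACROSS: M_treat, GROUP_IN: M_comp},
        l1_before=l1_before,
        l1_after=l1_after,
        univariate_l1=uni,
        balance_before=balance_table(cohort, matching_covariates),
        balance_after=balance_table(cohort, matching_covariates, weights=weight),
        matching_covariates=matching_covariates,
    )
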