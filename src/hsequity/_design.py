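"""Dummy-coded design matrices shared by the simulator, fitters and decomposition.

All model components in this package agree on one coefficient naming scheme:
``(Intercept)`` for the constant, ``<covariate>=<category>`` for a treatment-coded
(first-category-reference) dummy, and the bare column name for a numeric covariate.
Keeping one builder guarantees that coefficients simulated, estimated and switched
during decomposition always line up.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

INTERCEPT = "(Intercept)"


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable inverse-logit."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def infer_categories(
    data: pd.DataFrame, covariates: Sequence[str]
) -> dict[str, list[str]]:
    """Category levels per categorical covariate, reference level first.

    Non-numeric columns are treated as categorical with levels in sorted order
    (deterministic); numeric columns are omitted (they enter designs as-is).
    """
    categories: dict[str, list[str]] = {}
    for name in covariates:
        if name not in data.columns:
            raise KeyError(f"covariate {name!r} not found in data")
        col = data[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            continue
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [str(c) for c in col.cat.categories]
        else:
            levels = sorted(str(v) for v in col.dropna().unique())
        categories[name] = levels
    return categories


def design_columns(
    covariates: Sequence[str], categories: Mapping[str, Sequence[str]]
) -> list[str]:
    """Column names of the design matrix (intercept first)."""
    names = [INTERCEPT]
    for cov in covariates:
        if cov in categories:
            names.extend(f"{cov}={lev}" for lev in categories[cov][1:])
        else:
            names.append(cov)
    return names


def build_design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    categories: Mapping[str, Sequence[str]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies + numeric passthrough.

    Returns the dense design matrix and its column names. A categorical value
    outside the declared levels raises ``ValueError``.
    """
    if categories is None:
        categories = infer_categories(data, covariates)
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    for cov in covariates:
        if cov in categories:
            levels = list(categories[cov])
            values = data[cov].astype(str).to_numpy()
            known = np.isin(values, levels)
            if not known.all():
                bad = values[~known][0]
                raise ValueError(
                    f"value {bad!r} of covariate {cov!r} outside declared "
                    f"categories {levels}"
                )
            for lev in levels[1:]:
                cols.append((values == lev).astype(float))
        else:
            cols.append(pd.to_numeric(data[cov]).to_numpy(dtype=float))
    return np.column_stack(cols), design_columns(covariates, categories)


def coef_vector(names: Sequence[str], coefs: Mapping[str, float]) -> np.ndarray:
    """Align a ``{column name: value}`` mapping to design columns.

    Columns absent from the mapping get coefficient 0; keys matching no
    design column raise, so a misspelled category never silently drops a
    coefficient.
    """
    extra = [k for k in coefs if k not in names]
    if extra:
        raise KeyError(f"coefficients do not match any design column: {extra}")
    return np.array([float(coefs.get(n, 0.0)) for n in names])
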