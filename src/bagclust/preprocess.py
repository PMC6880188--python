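"""Covariate residualization of the brain view.

Region-wise brain features (cortical thickness) are regressed against
age, sex and scanner, and the z-scored residuals feed the clustering.
Two modes are provided:

* ``"sequential"`` (default): regress each feature on age, take
  residuals, regress those on sex, then on scanner, then z-score.
* ``"joint"``: one multi-covariate least-squares fit per feature.

The two agree exactly when the covariates are mutually orthogonal and
differ otherwise; sequential residualization attributes shared variance
to the earlier covariate in the order.  Phenotype scores are never
residualized.  Categorical covariates are one-hot encoded with the
first level as reference; z-scoring uses the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CohortTable

logger = logging.getLogger("bagclust")

__all__ = ["ResidualizedView", "residualize", "residualize_cohort"]


@dataclass
class ResidualizedView:
    """z-scored residuals plus the covariates actually regressed out, in order."""

    values: pd.DataFrame
    covariate_order: tuple[str, ...]


def _encode(col: pd.Series, name: str) -> np.ndarray | None:
    """Encode one covariate as regression columns (no intercept).

    Numeric covariates pass through; categoricals become one-hot dummies
    with the first (sorted) level dropped.  A single-level categorical
    carries no information and is skipped with a warning.
    """
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float).reshape(-1, 1)
    levels = pd.unique(col)
    if len(levels) < 2:
        logger.warning("covariate %r has a single level; skipped", name)
        return None
    dummies = pd.get_dummies(col.astype("category"), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(Y)), X])
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


def _zscore(Y: np.ndarray, feature_names: list[str]) -> np.ndarray:
    sd = Y.std(axis=0, ddof=1)
    const = np.isclose(sd, 0.0, atol=1e-12)
    if const.any():
        bad = [feature_names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant feature column(s) after residualization: {bad}")
    return (Y - Y.mean(axis=0)) / sd


def residualize(
    view: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "sequential",
    covariate_order: tuple[str, ...] = ("age", "sex", "scanner"),
) -> ResidualizedView:
    """Regress covariates out of every feature column and z-score the residuals."""
    if mode not in ("sequential", "joint"):
        raise ValueError("mode must be 'sequential' or 'joint'")
    if not view.index.equals(covariates.index):
        raise ValueError("view and covariates must share the participant index")
    order = [c for c in covariate_order if c in covariates.columns]
    encoded = [(name, _encode(covariates[name], name)) for name in order]
    encoded = [(name, X) for name, X in encoded if X is not None]

    Y = view.to_numpy(dtype=float)
    names = list(view.columns)
    if mode == "sequential":
        for _, X in encoded:
            Y = _residuals(Y, X)
    else:
        if encoded:
            Y = _residuals(Y, np.column_stack([X for _, X in encoded]))
    Z = _zscore(Y, names)
    used = tuple(name for name, _ in encoded)
    return ResidualizedView(pd.DataFrame(Z, index=view.index, columns=view.columns), used)


def residualize_cohort(cohort: CohortTable, mode: str = "sequential") -> CohortTable:
    """Return the cohort with its brain view replaced by z-scored residuals."""
    res = residualize(cohort.brain, cohort.covariates, mode=mode)
    return CohortTable(res.values, cohort.phenotype, cohort.covariates, cohort.labels)
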