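"""Rank-based group comparisons across clusters with multiplicity control.

Phenotype scores and brain features are compared across the final
clusters (or across diagnostic groups) with Kruskal-Wallis tests;
per-feature batches are Bonferroni-corrected, and Dunn's z-tests on
mean ranks provide post-hoc pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import scipy.stats as stats

from .io_model import ClusterSolution, CohortTable

logger = logging.getLogger("bagclust")

__all__ = [
    "kruskal_wallis",
    "bonferroni",
    "per_feature_cluster_tests",
    "posthoc_pairwise",
]


def _group_values(values, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have the same length")
    uniq = pd.unique(groups)
    out = [values[groups == g] for g in uniq]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, degrees of freedom, and chi-squared p."""
    samples = _group_values(values, groups)
    df = len(samples) - 1
    flat = np.concatenate(samples)
    if np.ptp(flat) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def bonferroni(p_raw: float | np.ndarray, m: int) -> np.ndarray | float:
    """Bonferroni-adjusted p-value(s): min(1, p * m)."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m)


def per_feature_cluster_tests(
    cohort: CohortTable,
    solution: ClusterSolution,
    features: list[str] | str = "brain",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis per feature across clusters, Bonferroni over the batch.

    ``features`` may be "brain", "phenotype", "all" or an explicit list
    of column names; the Bonferroni multiplier is the number of features
    in the tested batch.
    """
    if not np.array_equal(solution.index, cohort.participant_ids):
        raise ValueError("solution index does not match cohort")
    if features == "brain":
        cols = cohort.brain_features
    elif features == "phenotype":
        cols = cohort.pheno_features
    elif features == "all":
        cols = cohort.brain_features + cohort.pheno_features
    else:
        cols = list(features)
    data = pd.concat([cohort.brain, cohort.phenotype], axis=1)
    m = len(cols)
    rows = []
    for col in cols:
        h, df, p = kruskal_wallis(data[col].to_numpy(), solution.labels)
        p_bonf = float(bonferroni(p, m))
        rows.append((col, h, df, p, p_bonf, p_bonf < alpha))
    return pd.DataFrame(
        rows, columns=["feature", "H", "df", "p_raw", "p_bonferroni", "significant"]
    ).set_index("feature")


def posthoc_pairwise(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise mean-rank z-tests, Bonferroni-adjusted over pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = _group_values(values, groups)
    uniq = list(pd.unique(groups))
    n_total = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int((groups == g).sum()) for g in uniq}

    # tie correction to the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var_coeff = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(uniq, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_coeff * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = float(bonferroni(p, m))
        rows.append((g1, g2, z, p, p_adj, p_adj < alpha))
    return pd.DataFrame(
        rows, columns=["group_1", "group_2", "z", "p_raw", "p_bonferroni", "significant"]
    )
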