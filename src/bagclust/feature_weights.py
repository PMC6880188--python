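"""Permutation-accuracy feature weights for the bagged clustering.

A feature's weight measures how much the final partition depends on
its values.  For feature f:

1. *baseline accuracy*: over the bagging iterations in which f was
   selected, the mean agreement between the iteration's labels and the
   final labels restricted to that iteration's subsample;
2. *permuted accuracy*: f's column is permuted across participants
   (once, seeded) and those same iterations are replayed with all other
   random draws fixed (same participants, same sampled features, same
   k, same k-means seed); the agreement is recomputed;
3. weight = baseline - permuted.

Agreement defaults to the adjusted Rand index rescaled to [0, 1] via
(ARI + 1) / 2, which is invariant to cluster relabeling; a
Hungarian-matched classification accuracy is available as an
alternative (``metric="matched"``).  Brain features count as selected
when forward selection kept them; phenotype scores count as selected
whenever they were sampled (both sampled scores always enter the
fusion).  Features selected in no iteration get an undefined (NaN)
weight, never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .bagging import IterationRecord, iteration_labels
from .io_model import ClusterSolution, CohortTable, PipelineConfig

logger = logging.getLogger("bagclust")

__all__ = ["FeatureWeightReport", "compute_feature_weights", "rank_features"]


def _ari01(a: np.ndarray, b: np.ndarray) -> float:
    return (adjusted_rand_score(a, b) + 1.0) / 2.0


def _matched_accuracy(a: np.ndarray, b: np.ndarray) -> float:
    """Classification accuracy after optimally matching cluster labels."""
    cont = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    rows, cols = linear_sum_assignment(cont, maximize=True)
    return float(cont[rows, cols].sum() / cont.sum())


_METRICS = {"ari": _ari01, "matched": _matched_accuracy}


@dataclass
class FeatureWeightReport:
    """Per-feature baseline/permuted accuracy and weight.

    ``table`` columns: feature, view, baseline, permuted, weight,
    n_iterations_used.  Never-selected features carry NaN weights.
    """

    table: pd.DataFrame
    metric: str


def _mean_agreement(
    records: list[IterationRecord],
    final_labels: np.ndarray,
    metric,
    labels_for=None,
) -> float:
    scores = []
    for rec in records:
        labels = rec.labels if labels_for is None else labels_for(rec)
        scores.append(metric(labels, final_labels[rec.sampled_participants]))
    return float(np.mean(scores))


def compute_feature_weights(
    cohort: CohortTable,
    final: ClusterSolution,
    records: list[IterationRecord],
    config: PipelineConfig,
    rng: np.random.Generator,
    *,
    metric: str = "ari",
) -> FeatureWeightReport:
    """Permutation importance of every brain and phenotype feature."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    score = _METRICS[metric]
    logger.info("feature weights: agreement metric = %s", metric)
    if not np.array_equal(final.index, cohort.participant_ids):
        raise ValueError("final solution index does not match cohort")
    final_labels = final.labels
    brain = cohort.brain.to_numpy(dtype=float)
    pheno = cohort.phenotype.to_numpy(dtype=float)

    rows = []
    specs = [("brain", j, name) for j, name in enumerate(cohort.brain_features)]
    specs += [("phenotype", j, name) for j, name in enumerate(cohort.pheno_features)]
    for view, j, name in specs:
        if view == "brain":
            used = [r for r in records if j in r.selected_brain]
        else:
            used = [r for r in records if j in r.sampled_pheno]
        if not used:
            logger.warning("feature %r selected in no iteration; weight undefined", name)
            rows.append((name, view, np.nan, np.nan, np.nan, 0))
            continue
        baseline = _mean_agreement(used, final_labels, score)

        perm = rng.permutation(cohort.n_participants)
        if view == "brain":
            brain_mod, pheno_mod = brain.copy(), pheno
            brain_mod[:, j] = brain[perm, j]
        else:
            brain_mod, pheno_mod = brain, pheno.copy()
            pheno_mod[:, j] = pheno[perm, j]

        def replay(rec: IterationRecord) -> np.ndarray:
            labels, _ = iteration_labels(
                brain_mod, pheno_mod,
                rec.sampled_participants, rec.sampled_brain, rec.sampled_pheno,
                rec.k, rec.cluster_seed, config,
            )
            return labels

        permuted = _mean_agreement(used, final_labels, score, labels_for=replay)
        rows.append((name, view, baseline, permuted, baseline - permuted, len(used)))

    table = pd.DataFrame(
        rows,
        columns=["feature", "view", "baseline", "permuted", "weight", "n_iterations_used"],
    ).set_index("feature")
    return FeatureWeightReport(table, metric)


def rank_features(report: FeatureWeightReport) -> list[str]:
    """Features by descending weight; undefined weights last; ties keep canonical order."""
    t = report.table
    defined = t[t["weight"].notna()]
    undefined = t[t["weight"].isna()]
    ordered = defined.sort_values("weight", ascending=False, kind="stable")
    return list(ordered.index) + list(undefined.index)
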