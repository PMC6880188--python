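"""Cluster-quality scoring and sequential forward feature selection.

The quality score is a size-weighted within-to-between similarity
ratio.  For each cluster c:

* within_c  = median over members i of the median affinity between i
  and the other members of c (self-pairs excluded);
* between_c = median over members i of the 99th-percentile affinity
  between i and all participants outside c (a high percentile copes
  with sparse affinity matrices);
* ratio_c   = within_c / between_c.

The overall score is the mean of the per-cluster ratios weighted by
cluster size.  Singleton clusters have no within-similarity and are
skipped with weight 0 (warned).

Sequential forward selection greedily grows the brain-feature subset:
at each step every unselected candidate is trialled by fusing it with
the already-selected brain affinities (arithmetic mean), fusing that
with the phenotype affinity (geometric mean), clustering, and scoring.
The best candidate is added while it strictly improves the score; the
first step always accepts the best single candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .affinity import fuse_across_types, fuse_within_type
from .io_model import AffinityMatrix, ClusterSolution

logger = logging.getLogger("bagclust")

__all__ = ["QualityRatio", "within_between_ratio", "sequential_forward_select"]

#: ratio reported when a cluster's between-similarity is exactly zero
RATIO_SENTINEL = 1e12


@dataclass
class QualityRatio:
    """Overall size-weighted ratio plus per-cluster (within, between, ratio, size)."""

    overall: float
    per_cluster: list[tuple[int, float, float, float, int]]


def within_between_ratio(
    affinity: AffinityMatrix,
    solution: ClusterSolution,
    *,
    between_percentile: float = 99.0,
) -> QualityRatio:
    """Size-weighted within-to-between similarity ratio of a partition."""
    A = affinity.values
    labels = solution.labels
    if len(labels) != affinity.n:
        raise ValueError("solution does not match affinity size")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")

    per_cluster: list[tuple[int, float, float, float, int]] = []
    weighted_sum = 0.0
    total_weight = 0
    for c in clusters:
        members = np.flatnonzero(labels == c)
        outside = np.flatnonzero(labels != c)
        size = len(members)
        if size == 1:
            logger.warning("cluster %d is a singleton; excluded from the ratio (weight 0)", c)
            continue
        # within: per-member median over same-cluster partners, self-pairs dropped
        M = A[np.ix_(members, members)]
        partners = M[~np.eye(size, dtype=bool)].reshape(size, size - 1)
        within = float(np.median(np.median(partners, axis=1)))
        B = A[np.ix_(members, outside)]
        between = float(np.median(np.percentile(B, between_percentile, axis=1)))
        if between == 0.0:
            logger.warning("cluster %d has zero between-similarity; ratio set to sentinel", c)
            ratio = RATIO_SENTINEL
        else:
            ratio = within / between
        per_cluster.append((int(c), within, between, ratio, size))
        weighted_sum += size * ratio
        total_weight += size
    if total_weight == 0:
        raise ValueError("all clusters are singletons; ratio undefined")
    return QualityRatio(weighted_sum / total_weight, per_cluster)


def sequential_forward_select(
    candidate_affinities: Sequence[AffinityMatrix],
    pheno_affinity: AffinityMatrix,
    cluster_fn: Callable[[AffinityMatrix], ClusterSolution],
    *,
    tol: float = 1e-12,
) -> tuple[list[int], AffinityMatrix, float]:
    """Greedy forward selection of brain affinities against the phenotype view.

    Returns ``(selected_indices, fused_affinity, best_score)`` where the
    fused matrix is the cross-view fusion of the selected brain features
    with the phenotype affinity.  Candidates whose trial clustering
    fails are skipped with a warning.  Ties break toward the lowest
    candidate index, so selection is deterministic for a seeded
    ``cluster_fn``.
    """
    if not candidate_affinities:
        raise ValueError("empty candidate list")
    selected: list[int] = []
    best_score = -np.inf
    best_fused: AffinityMatrix | None = None
    remaining = list(range(len(candidate_affinities)))

    while remaining:
        step_best_score = -np.inf
        step_best_idx: int | None = None
        step_best_fused: AffinityMatrix | None = None
        for idx in remaining:
            trial = [candidate_affinities[i] for i in selected] + [candidate_affinities[idx]]
            fused = fuse_across_types(fuse_within_type(trial), pheno_affinity)
            try:
                sol = cluster_fn(fused)
                score = within_between_ratio(fused, sol).overall
            except Exception as exc:  # noqa: BLE001 - candidate-level robustness
                logger.warning("candidate %d skipped: %s", idx, exc)
                continue
            if score > step_best_score + tol:
                step_best_score = score
                step_best_idx = idx
                step_best_fused = fused
        if step_best_idx is None:
            break
        improves = step_best_score > best_score + tol
        if not selected or improves:
            selected.append(step_best_idx)
            remaining.remove(step_best_idx)
            best_score = step_best_score
            best_fused = step_best_fused
            if not improves:
                break  # forced first pick that did not improve -inf base (unreachable)
        else:
            break
    if best_fused is None:
        raise ValueError("no candidate could be clustered")
    return selected, best_fused, best_score
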