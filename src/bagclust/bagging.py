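"""The bagged multi-view clustering loop.

A full run draws many random subsamples of the cohort (participants,
phenotype scores, brain regions, and the cluster count k), clusters
each subsample, and accumulates how often each participant pair lands
in the same cluster.  Pairs are normalized by how often they were
jointly sampled, several independent runs are aggregated by an
element-wise median, and the final partition is obtained by spectral
clustering of the median co-assignment matrix.

Reproducibility contract: every iteration's random stream is derived
counter-style from the master seed via ``SeedSequence(seed,
spawn_key=(run, iteration))``, so results are bitwise identical
regardless of execution order or the number of worker processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from joblib import Parallel, delayed

from .affinity import fuse_across_types, fuse_within_type, gaussian_affinity
from .cluster_quality import QualityRatio, sequential_forward_select, within_between_ratio
from .io_model import (
    AffinityMatrix,
    ClusterSolution,
    CohortTable,
    ConsensusMatrix,
    PipelineConfig,
)

logger = logging.getLogger("bagclust")

__all__ = [
    "IterationRecord",
    "PipelineResult",
    "spectral_cluster",
    "run_iteration",
    "accumulate",
    "run_pipeline",
    "final_clusters",
    "sweep_k",
]


# ---------------------------------------------------------------------------
# Spectral clustering
# ---------------------------------------------------------------------------


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D^2 sampling)."""
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c] = X[rng.integers(n)]
            continue
        centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    return centers


def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 10, max_iter: int = 300) -> np.ndarray:
    """Seeded Lloyd's k-means, best of ``n_init`` k-means++ restarts.

    Ties in inertia break toward the earlier restart.  Emptied clusters
    are reseeded at the point farthest from its assigned center, so
    exactly k nonempty clusters are returned whenever X has >= k
    distinct rows.
    """
    rng = np.random.default_rng(seed)
    n = len(X)
    x2 = (X**2).sum(axis=1)
    arange_n = np.arange(n)

    def dist2(centers: np.ndarray) -> np.ndarray:
        return np.maximum(x2[:, None] - 2.0 * X @ centers.T + (centers**2).sum(axis=1)[None, :], 0.0)

    best_labels: np.ndarray | None = None
    best_inertia = np.inf
    for _ in range(n_init):
        centers = _kmeanspp_init(X, k, rng)
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d2 = dist2(centers)
            new_labels = d2.argmin(axis=1)
            empty = np.flatnonzero(np.bincount(new_labels, minlength=k) == 0)
            for c in empty:  # reseed an emptied cluster at the worst-fit point
                far = d2[arange_n, new_labels].argmax()
                new_labels[far] = c
                d2[far] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            onehot = (labels == np.arange(k)[:, None]).astype(float)
            centers = (onehot @ X) / onehot.sum(axis=1)[:, None]
        inertia = dist2(centers)[arange_n, labels].sum()
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            best_labels = labels
    assert best_labels is not None
    return best_labels


def spectral_cluster(affinity: AffinityMatrix, k: int, seed: int = 0) -> ClusterSolution:
    """Normalized spectral clustering of an affinity matrix.

    Embeds participants in the k eigenvectors of the symmetric
    normalized Laplacian with smallest eigenvalues, row-normalizes the
    embedding, and partitions it with seeded k-means (10 restarts, best
    inertia kept).  Participants with no off-diagonal affinity are
    detached from the graph and each becomes its own singleton cluster
    (warned).  If the embedding collapses onto fewer than k distinct
    points, only that many clusters are returned.
    """
    A = affinity.values
    n = affinity.n
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n - 1:
        raise ValueError(f"k={k} too large for n={n} participants")

    off_degree = A.sum(axis=1) - np.diag(A)
    isolated = np.flatnonzero(off_degree <= 0)
    connected = np.flatnonzero(off_degree > 0)
    if len(isolated):
        logger.warning("%d zero-degree participant(s) assigned to singleton clusters", len(isolated))

    labels = np.zeros(n, dtype=int)
    next_label = 1
    if len(connected):
        sub = A[np.ix_(connected, connected)]
        k_eff = min(k, len(connected))
        if k_eff >= 2 and len(connected) > k_eff:
            d = sub.sum(axis=1)
            inv_sqrt = 1.0 / np.sqrt(d)
            L = np.eye(len(connected)) - inv_sqrt[:, None] * sub * inv_sqrt[None, :]
            L = (L + L.T) / 2.0
            _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, k_eff - 1])
            norms = np.linalg.norm(vecs, axis=1)
            norms[norms == 0] = 1.0
            emb = vecs / norms[:, None]
            n_distinct = len(np.unique(np.round(emb, 10), axis=0))
            k_eff = min(k_eff, n_distinct)
        else:
            emb = sub  # tiny subgraph: cluster the raw affinity rows
            k_eff = min(k_eff, len(connected))
        if k_eff >= 2:
            sub_labels = _kmeans(emb, k_eff, int(seed))
        else:
            sub_labels = np.zeros(len(connected), dtype=int)
        labels[connected] = sub_labels + 1
        next_label = int(labels[connected].max()) + 1
    for i in isolated:
        labels[i] = next_label
        next_label += 1
    return ClusterSolution(labels, affinity.index, k=k, source="iteration")


# ---------------------------------------------------------------------------
# One bagging iteration
# ---------------------------------------------------------------------------


@dataclass
class IterationRecord:
    """Everything needed to replay one bagging iteration.

    Indices are positions in the cohort's canonical (sorted-ID) order;
    ``cluster_seed`` seeds the k-means inside spectral clustering so a
    replay with modified data (feature-weight permutation) keeps every
    other random draw fixed.
    """

    sampled_participants: np.ndarray
    sampled_pheno: np.ndarray
    sampled_brain: np.ndarray
    selected_brain: np.ndarray
    k: int
    cluster_seed: int
    labels: np.ndarray


def _subsample_size(n: int, fraction: float) -> int:
    return max(int(round(fraction * n)), 3)


def iteration_labels(
    brain_values: np.ndarray,
    pheno_values: np.ndarray,
    part_idx: np.ndarray,
    brain_idx: np.ndarray,
    pheno_idx: np.ndarray,
    k: int,
    cluster_seed: int,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster one subsample; returns (labels over part_idx, selected brain features).

    Builds per-measure Gaussian affinities on the subsample only (the
    bandwidth is recomputed on the subsample), fuses the sampled
    phenotype scores arithmetically, selects brain regions by forward
    selection against the phenotype view, and clusters the cross-view
    fusion at the drawn k.
    """
    pheno_affs = [
        gaussian_affinity(pheno_values[part_idx, j], part_idx, config.kernel_percentile)
        for j in pheno_idx
    ]
    pheno_fused = fuse_within_type(pheno_affs)
    candidates = [
        gaussian_affinity(brain_values[part_idx, j], part_idx, config.kernel_percentile)
        for j in brain_idx
    ]
    cluster_fn = lambda aff: spectral_cluster(aff, k, cluster_seed)  # noqa: E731
    selected_local, fused, _ = sequential_forward_select(candidates, pheno_fused, cluster_fn)
    solution = spectral_cluster(fused, k, cluster_seed)
    return solution.labels, np.asarray(brain_idx)[selected_local]


def run_iteration(
    cohort: CohortTable, config: PipelineConfig, rng: np.random.Generator
) -> IterationRecord:
    """Draw one subsample (participants, features, k) and cluster it."""
    n = cohort.n_participants
    n_brain = len(cohort.brain_features)
    n_pheno = len(cohort.pheno_features)

    m = min(_subsample_size(n, config.participant_fraction), n)
    part_idx = np.sort(rng.choice(n, size=m, replace=False))
    pheno_idx = np.sort(
        rng.choice(n_pheno, size=min(config.n_pheno_views_sampled, n_pheno), replace=False)
    )
    brain_idx = np.sort(
        rng.choice(n_brain, size=min(config.n_brain_features_sampled, n_brain), replace=False)
    )
    if config.k_min >= m:
        raise ValueError(f"subsample of {m} cannot host k >= {config.k_min}")
    k = int(rng.integers(config.k_min, config.k_max + 1))
    while k >= m:
        k = int(rng.integers(config.k_min, config.k_max + 1))
    cluster_seed = int(rng.integers(2**31 - 1))

    labels, selected = iteration_labels(
        cohort.brain.to_numpy(dtype=float),
        cohort.phenotype.to_numpy(dtype=float),
        part_idx,
        brain_idx,
        pheno_idx,
        k,
        cluster_seed,
        config,
    )
    return IterationRecord(part_idx, pheno_idx, brain_idx, selected, k, cluster_seed, labels)


def accumulate(consensus: ConsensusMatrix, record: IterationRecord) -> ConsensusMatrix:
    """Add one iteration's co-sampling/co-assignment counts (in place)."""
    ii = record.sampled_participants
    if ii.max() >= consensus.co_sample.shape[0]:
        raise ValueError("record participants outside the consensus index")
    block = np.ix_(ii, ii)
    consensus.co_sample[block] += 1
    same = (record.labels[:, None] == record.labels[None, :]).astype(np.int64)
    consensus.co_assign[block] += same
    return consensus


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Aggregated consensus plus per-run diagnostics and the iteration log."""

    median_frequency: np.ndarray
    run_frequencies: list[np.ndarray]
    run_consensus: list[ConsensusMatrix]
    records: list[list[IterationRecord]]
    index: np.ndarray
    config: PipelineConfig

    @property
    def all_records(self) -> list[IterationRecord]:
        return [r for run in self.records for r in run]

    def consensus_affinity(self) -> AffinityMatrix:
        return AffinityMatrix(self.median_frequency, self.index)


def _iteration_rng(master_seed: int, run: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(run, iteration)))


def run_pipeline(cohort: CohortTable, config: PipelineConfig) -> PipelineResult:
    """Run ``n_runs`` independent bagging runs and aggregate by element-wise median.

    Iterations may execute in parallel (``config.n_jobs``); the
    counter-derived per-iteration seeds make the result identical to
    serial execution.  Pairs never co-sampled within a run are excluded
    from that run's median; pairs undefined in every run are treated as
    0 similarity with a warning.
    """
    config.validate(len(cohort.brain_features), len(cohort.pheno_features))
    n = cohort.n_participants
    index = cohort.participant_ids

    run_freqs: list[np.ndarray] = []
    run_cons: list[ConsensusMatrix] = []
    all_records: list[list[IterationRecord]] = []
    for run in range(config.n_runs):
        if config.n_jobs == 1:
            records = [
                run_iteration(cohort, config, _iteration_rng(config.rng_seed, run, it))
                for it in range(config.n_iterations)
            ]
        else:
            records = Parallel(n_jobs=config.n_jobs)(
                delayed(run_iteration)(cohort, config, _iteration_rng(config.rng_seed, run, it))
                for it in range(config.n_iterations)
            )
        consensus = ConsensusMatrix.empty(index)
        for rec in records:
            accumulate(consensus, rec)
        run_freqs.append(consensus.frequency())
        run_cons.append(consensus)
        all_records.append(records)
        logger.info("run %d/%d complete", run + 1, config.n_runs)

    stacked = np.ma.masked_invalid(np.stack(run_freqs))
    median = np.ma.median(stacked, axis=0)
    never_defined = np.asarray(median.mask) if median.mask is not np.ma.nomask else np.zeros((n, n), bool)
    if never_defined.any():
        logger.warning(
            "%d pair(s) never co-sampled in any run; treated as 0 similarity",
            int(never_defined.sum()) // 2,
        )
    median = np.asarray(median.filled(0.0))
    median = (median + median.T) / 2.0
    np.fill_diagonal(median, 1.0)
    return PipelineResult(median, run_freqs, run_cons, all_records, index, config)


def final_clusters(result: PipelineResult | AffinityMatrix, k: int, seed: int = 0) -> ClusterSolution:
    """Spectral clustering of the median consensus matrix at the requested k."""
    aff = result.consensus_affinity() if isinstance(result, PipelineResult) else result
    solution = spectral_cluster(aff, k, seed)
    solution.source = "final"
    return solution


def sweep_k(
    result: PipelineResult | AffinityMatrix,
    k_range: range | list[int],
    seed: int = 0,
) -> list[tuple[int, ClusterSolution, QualityRatio]]:
    """Final clustering and within-to-between ratio for each k (model selection)."""
    aff = result.consensus_affinity() if isinstance(result, PipelineResult) else result
    out = []
    for k in k_range:
        sol = final_clusters(aff, k, seed)
        out.append((k, sol, within_between_ratio(aff, sol)))
    return out
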