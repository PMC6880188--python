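import dataclasses

import numpy as np
import pytest

from bagclust import (
    AffinityMatrix,
    ClusterSolution,
    ConsensusMatrix,
    IterationRecord,
    PipelineConfig,
    accumulate,
    adjusted_rand,
    final_clusters,
    gaussian_affinity,
    nmi,
    run_iteration,
    run_pipeline,
    spectral_cluster,
    sweep_k,
)
from bagclust.bagging import _iteration_rng

from _oracles import best_ncut_partition
from conftest import two_block_affinity


SMALL_CFG = PipelineConfig(
    n_iterations=150,
    n_runs=1,
    n_brain_features_sampled=3,
    n_pheno_views_sampled=2,
    k_min=2,
    k_max=5,
    rng_seed=0,
)


def _block_affinity(sizes):
    labels = np.concatenate([[c + 1] * s for c, s in enumerate(sizes)])
    A = (labels[:, None] == labels[None, :]).astype(float)
    return AffinityMatrix(A, np.arange(len(labels))), labels


# -- spectral clustering -----------------------------------------------------


def test_disconnected_blocks_recovered_exactly():
    aff, labels = _block_affinity([6, 5])
    sol = spectral_cluster(aff, 2, seed=0)
    assert adjusted_rand(sol.labels, labels) == 1.0


def test_identity_affinity_isolates_every_participant(caplog):
    aff = AffinityMatrix(np.eye(4), np.arange(4))
    with caplog.at_level("WARNING", logger="bagclust"):
        sol = spectral_cluster(aff, 2, seed=0)
    assert len(np.unique(sol.labels)) == 4
    assert any("zero-degree" in r.message for r in caplog.records)


def test_k_out_of_range_is_rejected():
    aff, _ = _block_affinity([3, 3])
    with pytest.raises(ValueError):
        spectral_cluster(aff, 6, seed=0)
    with pytest.raises(ValueError):
        spectral_cluster(aff, 1, seed=0)


@pytest.mark.parametrize("seed", range(3))
def test_three_group_solution_matches_exhaustive_ncut_oracle(seed):
    """9 one-dimensional points in 3 tight groups: compare with brute force."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 0.05, 3), rng.normal(5, 0.05, 3), rng.normal(10, 0.05, 3)])
    aff = gaussian_affinity(x)
    sol = spectral_cluster(aff, 3, seed=seed)
    oracle = best_ncut_partition(aff.values, 3)
    assert adjusted_rand(sol.labels, oracle) == 1.0


# -- iterations and accumulation ---------------------------------------------


def test_iteration_is_deterministic_given_seed(small_cohort_residualized):
    cohort, _ = small_cohort_residualized
    a = run_iteration(cohort, SMALL_CFG, _iteration_rng(42, 0, 0))
    b = run_iteration(cohort, SMALL_CFG, _iteration_rng(42, 0, 0))
    assert np.array_equal(a.sampled_participants, b.sampled_participants)
    assert np.array_equal(a.selected_brain, b.selected_brain)
    assert np.array_equal(a.labels, b.labels)
    assert a.k == b.k


def test_subsample_size_rounds_fraction(small_cohort_residualized):
    cohort, _ = small_cohort_residualized
    sub = cohort.__class__(
        cohort.brain.iloc[:20], cohort.phenotype.iloc[:20],
        cohort.covariates.iloc[:20], None,
    )
    rec = run_iteration(sub, SMALL_CFG, _iteration_rng(0, 0, 0))
    assert len(rec.sampled_participants) == 13  # round(0.632 * 20) = round(12.64)
    assert rec.selected_brain.size and set(rec.selected_brain) <= set(rec.sampled_brain)


def test_accumulate_matches_hand_tally():
    index = np.array(list("abcd"))
    consensus = ConsensusMatrix.empty(index)
    records = [
        IterationRecord(np.array([0, 1, 2]), None, None, None, 2, 0, np.array([1, 1, 2])),
        IterationRecord(np.array([0, 1, 3]), None, None, None, 2, 0, np.array([1, 2, 2])),
        IterationRecord(np.array([1, 2, 3]), None, None, None, 2, 0, np.array([1, 1, 1])),
    ]
    for rec in records:
        accumulate(consensus, rec)
    # hand tally over the three records
    assert consensus.co_sample[0, 1] == 2 and consensus.co_assign[0, 1] == 1
    assert consensus.co_sample[1, 2] == 2 and consensus.co_assign[1, 2] == 1
    assert consensus.co_sample[0, 3] == 1 and consensus.co_assign[0, 3] == 0
    assert consensus.co_sample[1, 3] == 2 and consensus.co_assign[1, 3] == 2
    assert consensus.co_sample[0, 2] == 1 and consensus.co_assign[0, 2] == 0
    freq = consensus.frequency()
    assert freq[0, 1] == 0.5 and not np.isnan(freq[2, 3])
    assert (freq.diagonal() == 1.0).all()


def test_never_cosampled_pair_is_flagged_undefined():
    index = np.array(list("abc"))
    consensus = ConsensusMatrix.empty(index)
    accumulate(consensus, IterationRecord(np.array([0, 1]), None, None, None, 2, 0, np.array([1, 1])))
    freq = consensus.frequency()
    assert freq[0, 1] == 1.0
    assert np.isnan(freq[0, 2]) and np.isnan(freq[1, 2])


# -- full pipeline ------------------------------------------------------------


@pytest.fixture(scope="module")
def small_result(small_cohort_residualized):
    cohort, _ = small_cohort_residualized
    return run_pipeline(cohort, SMALL_CFG)


def test_single_run_median_equals_run_frequency(small_cohort_residualized):
    cohort, _ = small_cohort_residualized
    cfg = dataclasses.replace(SMALL_CFG, n_iterations=40)
    res = run_pipeline(cohort, cfg)
    expected = res.run_frequencies[0].copy()
    expected[np.isnan(expected)] = 0.0
    np.testing.assert_array_equal(res.median_frequency, expected)


def test_consensus_is_symmetric_with_unit_diagonal(small_result):
    f = small_result.median_frequency
    assert np.array_equal(f, f.T)
    assert (np.diag(f) == 1.0).all()
    assert f.min() >= 0.0 and f.max() <= 1.0


def test_planted_structure_dominates_consensus(small_result, small_cohort_residualized):
    _, planted = small_cohort_residualized
    lab = planted.to_numpy()
    f = small_result.median_frequency
    iu = np.triu_indices(len(lab), 1)
    same = lab[iu[0]] == lab[iu[1]]
    assert f[iu][same].mean() > f[iu][~same].mean()


def test_final_clusters_recover_planted_partition(small_result, small_cohort_residualized):
    _, planted = small_cohort_residualized
    sol = final_clusters(small_result, 3, seed=0)
    assert nmi(sol.to_series(), planted) >= 0.9


def test_stability_across_master_seeds(small_cohort_residualized, small_result):
    cohort, _ = small_cohort_residualized
    other = run_pipeline(cohort, dataclasses.replace(SMALL_CFG, rng_seed=99))
    a = final_clusters(small_result, 3, seed=0)
    b = final_clusters(other, 3, seed=0)
    assert nmi(a.labels, b.labels) >= 0.8


def test_block_diagonal_consensus_recovered_and_delegates(small_result):
    aff, labels = _block_affinity([4, 4, 4, 4])
    sol = final_clusters(aff, 4, seed=1)
    assert adjusted_rand(sol.labels, labels) == 1.0
    assert np.array_equal(sol.labels, spectral_cluster(aff, 4, seed=1).labels)
    assert sol.source == "final"


def test_sweep_reports_ratio_per_k(small_result):
    out = sweep_k(small_result, range(2, 5), seed=0)
    assert [k for k, _, _ in out] == [2, 3, 4]
    assert all(q.overall > 0 for _, _, q in out)
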