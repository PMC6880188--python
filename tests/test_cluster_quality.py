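import numpy as np
import pytest

from bagclust import (
    AffinityMatrix,
    ClusterSolution,
    sequential_forward_select,
    spectral_cluster,
    within_between_ratio,
)

from _oracles import within_between_oracle
from conftest import random_affinity


def _block_affinity(sizes, within, between):
    labels = np.concatenate([[c + 1] * s for c, s in enumerate(sizes)])
    A = np.full((len(labels), len(labels)), between, dtype=float)
    same = labels[:, None] == labels[None, :]
    A[same] = within
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(A, np.arange(len(labels))), labels


def test_two_block_affinity_gives_ratio_of_block_values():
    aff, labels = _block_affinity([4, 4], within=1.0, between=0.1)
    q = within_between_ratio(aff, ClusterSolution(labels, aff.index, k=2))
    for _, w, b, r, _ in q.per_cluster:
        assert (w, b) == (1.0, 0.1)
    assert q.overall == pytest.approx(10.0)


def test_uniform_affinity_gives_ratio_one():
    aff, labels = _block_affinity([3, 5], within=0.4, between=0.4)
    q = within_between_ratio(aff, ClusterSolution(labels, aff.index, k=2))
    assert q.overall == pytest.approx(1.0)


def test_block_constant_overall_is_exactly_w_over_b_and_scale_invariant():
    aff, labels = _block_affinity([3, 4, 5], within=0.8, between=0.2)
    sol = ClusterSolution(labels, aff.index, k=3)
    q = within_between_ratio(aff, sol)
    assert q.overall == pytest.approx(0.8 / 0.2)
    # scale invariance: halving all off-diagonal similarities leaves ratios alone
    v = aff.values * 0.5
    np.fill_diagonal(v, 1.0)
    q2 = within_between_ratio(AffinityMatrix(v, aff.index), sol)
    assert q2.overall == pytest.approx(q.overall)


@pytest.mark.parametrize("seed", range(5))
def test_random_partitions_match_exhaustive_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(6, 12)
    aff = random_affinity(rng, n)
    labels = rng.integers(1, 3, size=n)
    while len(np.unique(labels)) < 2 or min(np.bincount(labels)[1:]) < 2:
        labels = rng.integers(1, 3, size=n)
    q = within_between_ratio(aff, ClusterSolution(labels, aff.index, k=2))
    overall, per = within_between_oracle(aff.values, labels)
    assert q.overall == pytest.approx(overall, abs=1e-12)
    for c, w, b, r, s in q.per_cluster:
        ow, ob, orat, osz = per[c]
        assert (w, b, s) == (pytest.approx(ow), pytest.approx(ob), osz)


def test_singleton_cluster_excluded_with_warning(caplog):
    aff, _ = _block_affinity([4, 4], within=0.9, between=0.1)
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 3])  # cluster 3 is a singleton
    with caplog.at_level("WARNING", logger="bagclust"):
        q = within_between_ratio(aff, ClusterSolution(labels, aff.index, k=3))
    assert {c for c, *_ in q.per_cluster} == {1, 2}
    assert any("singleton" in r.message for r in caplog.records)


def test_single_cluster_is_rejected():
    aff, _ = _block_affinity([4], within=1.0, between=0.5)
    with pytest.raises(ValueError, match="2 clusters"):
        within_between_ratio(aff, ClusterSolution(np.ones(4, dtype=int), aff.index, k=2))


# -- sequential forward selection -------------------------------------------


def _cluster_fn(k=2, seed=0):
    return lambda aff: spectral_cluster(aff, k, seed)


def test_single_candidate_is_always_selected():
    rng = np.random.default_rng(0)
    pheno, _ = _block_affinity([5, 5], within=0.9, between=0.1)
    cand = random_affinity(rng, 10)
    selected, fused, _ = sequential_forward_select([cand], pheno, _cluster_fn())
    assert selected == [0]


def test_planted_candidate_selected_first_over_noise():
    rng = np.random.default_rng(1)
    planted, _ = _block_affinity([5, 5], within=0.95, between=0.05)
    noise = [random_affinity(rng, 10) for _ in range(2)]
    pheno, _ = _block_affinity([5, 5], within=0.9, between=0.1)
    candidates = [noise[0], planted, noise[1]]
    selected, _, best = sequential_forward_select(candidates, pheno, _cluster_fn())
    assert selected[0] == 1
    # cross-check: the planted candidate wins an exhaustive single-candidate scan
    from bagclust import fuse_across_types, within_between_ratio as wbr

    scores = []
    for cand in candidates:
        fused = fuse_across_types(cand, pheno)
        scores.append(wbr(fused, _cluster_fn()(fused)).overall)
    assert int(np.argmax(scores)) == 1


def test_identical_candidates_select_exactly_one():
    aff, _ = _block_affinity([5, 5], within=0.9, between=0.1)
    pheno, _ = _block_affinity([5, 5], within=0.9, between=0.1)
    selected, _, _ = sequential_forward_select([aff, aff, aff], pheno, _cluster_fn())
    assert selected == [0]  # duplicates cannot improve the mean; ties keep lowest index


def test_selection_deterministic_for_seeded_cluster_fn():
    rng = np.random.default_rng(2)
    candidates = [random_affinity(rng, 12) for _ in range(4)]
    pheno = random_affinity(rng, 12)
    a = sequential_forward_select(candidates, pheno, _cluster_fn(seed=5))[0]
    b = sequential_forward_select(candidates, pheno, _cluster_fn(seed=5))[0]
    assert a == b
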