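import dataclasses

import numpy as np
import pandas as pd
import pytest

from bagclust import AffinityMatrix, CohortSpec, generate_cohort, residualize_cohort


def random_affinity(rng: np.random.Generator, n: int, index=None) -> AffinityMatrix:
    """Random symmetric affinity with unit diagonal (test helper)."""
    A = rng.uniform(0.0, 1.0, (n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(A, np.arange(n) if index is None else index)


def two_block_affinity(rng: np.random.Generator, n: int) -> tuple[AffinityMatrix, np.ndarray]:
    """Noisy two-block affinity and the planted block labels."""
    half = n // 2
    labels = np.array([1] * half + [2] * (n - half))
    A = rng.uniform(0.0, 0.2, (n, n))
    same = labels[:, None] == labels[None, :]
    A[same] = rng.uniform(0.8, 1.0, same.sum())
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(A, np.arange(n)), labels


SMALL_SPEC = CohortSpec(
    n_participants=60,
    n_brain_features=8,
    n_informative_brain=4,
    n_pheno_features=3,
    k_planted=3,
    effect_size=4.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small strongly separated cohort (raw, with covariate effects)."""
    return generate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_cohort_residualized(small_cohort):
    cohort, planted = small_cohort
    return residualize_cohort(cohort), planted


@pytest.fixture()
def cohort_csvs(tmp_path):
    """Write a tiny cohort pair of CSVs and return their paths."""
    spec = dataclasses.replace(SMALL_SPEC, n_participants=20)
    cohort, planted = generate_cohort(spec)
    brain = pd.concat([cohort.brain, cohort.covariates], axis=1)
    pheno = pd.concat([cohort.phenotype, planted.rename("planted")], axis=1)
    bp, pp = tmp_path / "brain.csv", tmp_path / "phenotype.csv"
    brain.to_csv(bp)
    pheno.to_csv(pp)
    return bp, pp, cohort, planted
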