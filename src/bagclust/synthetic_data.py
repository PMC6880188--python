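"""Seeded synthetic cohorts with planted multi-view structure.

The generator emulates the shape of a multi-site neurodevelopmental
cohort: region-wise continuous brain features (cortical thickness) with
linear age, sex and scanner effects injected, plus a few continuous
phenotype scores.  In ``"clusters"`` mode a planted partition drives
cluster-specific means in the informative brain features (the first
``n_informative_brain`` columns) and in every phenotype score; the
remaining brain features are pure noise.  In ``"continuum"`` mode the
signal follows a one-dimensional latent gradient instead of discrete
means, and the planted "labels" are quantile bins of the latent (useful
for probing continuum-versus-cluster diagnostics).

Each informative feature separates one cluster from the rest by
exactly ``effect_size * noise_sd`` (random sign), and the singled-out
cluster cycles across features in a seeded random order, so every
cluster pair is distinguished by an equal share of the informative
features and no pair is systematically closer than another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import CohortTable

logger = logging.getLogger("bagclust")

__all__ = ["CohortSpec", "generate_cohort", "generate_fixture_suite"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the target study's shape: 226 participants, 76
    brain regions, 3 phenotype scores, ages 6-18, two scanners.
    ``effect_size`` is the gap between adjacent cluster means in units
    of the noise SD; 4 is a strongly separated cohort, 0 a null one.
    Covariate effects are linear and identical across regions: an age
    slope of -0.05 per year emulates developmental cortical thinning,
    with small sex and scanner offsets.
    """

    n_participants: int = 226
    n_brain_features: int = 76
    n_informative_brain: int = 10
    n_pheno_features: int = 3
    k_planted: int = 3
    effect_size: float = 4.0
    noise_sd: float = 1.0
    age_slope: float = -0.05
    sex_offset: float = 0.1
    scanner_offset: float = 0.1
    structure_mode: str = "clusters"
    cluster_size_skew: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative_brain > self.n_brain_features:
            raise ValueError("n_informative_brain exceeds n_brain_features")
        if self.k_planted < 1:
            raise ValueError("k_planted must be >= 1")
        if self.n_pheno_features < 2:
            raise ValueError("need at least 2 phenotype scores")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.structure_mode not in ("clusters", "continuum"):
            raise ValueError("structure_mode must be 'clusters' or 'continuum'")

    @property
    def informative_brain_features(self) -> list[str]:
        return [f"region_{i + 1:03d}" for i in range(self.n_informative_brain)]


_PHENO_NAMES = ("SCQ", "SWAN", "TOCS")


def _planted_labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Planted assignment, 1-based; skew > 0 makes later clusters smaller."""
    k, n = spec.k_planted, spec.n_participants
    weights = np.exp(-spec.cluster_size_skew * np.arange(k))
    weights /= weights.sum()
    counts = np.floor(weights * n).astype(int)
    counts[: n - counts.sum()] += 1
    labels = np.repeat(np.arange(1, k + 1), counts)
    return rng.permutation(labels)


def _cluster_means(k: int, step: float, minority: int, rng: np.random.Generator) -> np.ndarray:
    """One-vs-rest cluster means for a single feature.

    The ``minority`` cluster sits ``step`` away (random sign) from the
    remaining clusters.  Cycling the minority across informative
    features gives a balanced design: every feature separates the
    clusters it distinguishes by exactly ``step``, and no cluster pair
    is systematically closer than another (a collinear grid of means
    would put the outer pair twice as far apart as adjacent pairs and
    plant an unintended hierarchy).
    """
    if k == 1:
        return np.zeros(1)
    means = np.zeros(k)
    means[minority] = step * rng.choice([-1.0, 1.0])
    return means - means.mean()


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, pd.Series]:
    """Generate a cohort and its planted labels (same seed -> same cohort)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_participants, spec.k_planted
    if spec.effect_size == 0 and k > 1:
        logger.warning("effect size 0 with k_planted > 1: planted labels are unrecoverable")

    ids = pd.Index([f"P{i:04d}" for i in range(1, n + 1)], name="participant_id")
    labels = _planted_labels(spec, rng)
    age = rng.uniform(6.0, 18.0, n)
    sex = rng.choice(["F", "M"], n)
    scanner = rng.choice(["scannerA", "scannerB"], n)

    step = spec.effect_size * spec.noise_sd
    if spec.structure_mode == "continuum":
        latent = rng.uniform(-1.0, 1.0, n)
        latent_z = (latent - latent.mean()) / latent.std()
        # planted "labels" for evaluation: quantile bins of the latent
        labels = np.searchsorted(np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1]), latent) + 1

    # minority assignments cycle through a seeded cluster order across all
    # informative features (brain first, then scores) to balance pair separation
    cycle = rng.permutation(k)
    n_signal = spec.n_informative_brain + spec.n_pheno_features
    minorities = [int(cycle[t % k]) for t in range(n_signal)]

    brain = rng.normal(0.0, spec.noise_sd, (n, spec.n_brain_features))
    for j in range(spec.n_informative_brain):
        if spec.structure_mode == "clusters":
            brain[:, j] += _cluster_means(k, step, minorities[j], rng)[labels - 1]
        else:
            brain[:, j] += step * rng.choice([-1.0, 1.0]) * latent_z

    pheno = rng.normal(0.0, spec.noise_sd, (n, spec.n_pheno_features))
    for j in range(spec.n_pheno_features):
        if spec.structure_mode == "clusters":
            m = minorities[spec.n_informative_brain + j]
            pheno[:, j] += _cluster_means(k, step, m, rng)[labels - 1]
        else:
            pheno[:, j] += step * rng.choice([-1.0, 1.0]) * latent_z

    # covariate effects enter every brain feature so residualization has real work
    covar_effect = (
        spec.age_slope * (age - age.mean())
        + spec.sex_offset * (sex == "M")
        + spec.scanner_offset * (scanner == "scannerB")
    )
    brain += covar_effect[:, None]

    brain_cols = [f"region_{i + 1:03d}" for i in range(spec.n_brain_features)]
    pheno_cols = [
        _PHENO_NAMES[j] if j < len(_PHENO_NAMES) else f"score_{j + 1}"
        for j in range(spec.n_pheno_features)
    ]
    cohort = CohortTable.from_frames(
        pd.DataFrame(brain, index=ids, columns=brain_cols),
        pd.DataFrame(pheno, index=ids, columns=pheno_cols),
        pd.DataFrame({"age": age, "sex": sex, "scanner": scanner}, index=ids),
        pd.Series(labels, index=ids, name="planted"),
    )
    planted = pd.Series(labels, index=ids, name="planted")
    return cohort, planted


#: specs of the standard test fixtures (scaled-down study conditions)
FIXTURE_SPECS: dict[str, CohortSpec] = {
    "strong_signal": CohortSpec(
        n_participants=120, n_brain_features=20, n_informative_brain=5,
        n_pheno_features=3, k_planted=3, effect_size=4.0,
    ),
    "null": CohortSpec(
        n_participants=120, n_brain_features=20, n_informative_brain=5,
        n_pheno_features=3, k_planted=3, effect_size=0.0,
    ),
    "continuum": CohortSpec(
        n_participants=120, n_brain_features=20, n_informative_brain=5,
        n_pheno_features=3, k_planted=3, effect_size=4.0, structure_mode="continuum",
    ),
    "one_informative": CohortSpec(
        n_participants=100, n_brain_features=10, n_informative_brain=1,
        n_pheno_features=3, k_planted=3, effect_size=4.0,
    ),
}


def generate_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, dict[str, Path]]:
    """Write the standard synthetic cohorts as CSV pairs readable by ``read_cohort``.

    Each cohort becomes ``<name>_brain.csv`` (features + covariates) and
    ``<name>_phenotype.csv`` (scores + planted-label column).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for name, spec in FIXTURE_SPECS.items():
        cohort, planted = generate_cohort(replace(spec, seed=seed))
        brain = pd.concat([cohort.brain, cohort.covariates], axis=1)
        pheno = pd.concat([cohort.phenotype, planted.rename("planted")], axis=1)
        bp = out_dir / f"{name}_brain.csv"
        pp = out_dir / f"{name}_phenotype.csv"
        brain.to_csv(bp)
        pheno.to_csv(pp)
        paths[name] = {"brain": bp, "phenotype": pp}
    return paths
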