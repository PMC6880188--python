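"""Core data model and delimited-text I/O.

The package operates on a cohort of participants measured in two "views":
a *brain* view (many continuous region-wise features, e.g. cortical
thickness for 76 regions) and a *phenotype* view (a few continuous
behavioural scores such as SCQ, SWAN and TOCS).  Covariates (age, sex,
scanner) travel alongside for residualization, and an optional
categorical label column (e.g. clinical diagnosis) supports agreement
evaluation.

Every matrix produced downstream shares a single canonical participant
order: the lexicographic sort of participant IDs.  This makes all
results independent of input file row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bagclust")

__all__ = [
    "ColumnSchema",
    "CohortTable",
    "AffinityMatrix",
    "ConsensusMatrix",
    "ClusterSolution",
    "PipelineConfig",
    "read_cohort",
    "write_solution",
    "read_solution",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class ColumnSchema:
    """Maps table columns to their roles during ingestion.

    ``brain_cols=None`` means "every column of the brain file that is not
    the ID or a covariate is a brain feature".
    """

    id_col: str = "participant_id"
    age_col: str = "age"
    sex_col: str = "sex"
    scanner_col: str = "scanner"
    score_cols: tuple[str, ...] = ("SCQ", "SWAN", "TOCS")
    label_col: str | None = None
    brain_cols: tuple[str, ...] | None = None

    @property
    def covariate_cols(self) -> tuple[str, str, str]:
        return (self.age_col, self.sex_col, self.scanner_col)


@dataclass
class CohortTable:
    """Participant-indexed cohort with aligned brain and phenotype views.

    All three frames (``brain``, ``phenotype``, ``covariates``) share the
    same unique, lexicographically sorted participant index.  Feature
    values must be complete; ``labels`` may contain missing entries.
    """

    brain: pd.DataFrame
    phenotype: pd.DataFrame
    covariates: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.brain.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate participant IDs: {dupes}")
        for name, frame in [("phenotype", self.phenotype), ("covariates", self.covariates)]:
            if not frame.index.equals(idx):
                raise ValueError(f"{name} index does not match brain index")
        if self.labels is not None and not self.labels.index.equals(idx):
            raise ValueError("labels index does not match brain index")
        if self.phenotype.shape[1] < 2:
            raise ValueError("phenotype view needs at least 2 score columns")
        for name, frame in [("brain", self.brain), ("phenotype", self.phenotype)]:
            if frame.isna().to_numpy().any():
                raise ValueError(f"{name} view contains missing values")
        if self.covariates.isna().to_numpy().any():
            raise ValueError("covariates contain missing values")

    # -- convenience accessors -------------------------------------------------

    @property
    def participant_ids(self) -> np.ndarray:
        return self.brain.index.to_numpy()

    @property
    def n_participants(self) -> int:
        return len(self.brain)

    @property
    def brain_features(self) -> list[str]:
        return list(self.brain.columns)

    @property
    def pheno_features(self) -> list[str]:
        return list(self.phenotype.columns)

    def view(self, which: str) -> pd.DataFrame:
        if which == "brain":
            return self.brain
        if which == "phenotype":
            return self.phenotype
        raise ValueError(f"unknown view {which!r}")

    def replace_feature(self, which: str, name: str, values: np.ndarray) -> "CohortTable":
        """Return a copy with one feature column replaced (views stay aligned)."""
        brain, pheno = self.brain, self.phenotype
        if which == "brain":
            brain = brain.copy()
            brain[name] = np.asarray(values, dtype=float)
        elif which == "phenotype":
            pheno = pheno.copy()
            pheno[name] = np.asarray(values, dtype=float)
        else:
            raise ValueError(f"unknown view {which!r}")
        return CohortTable(brain, pheno, self.covariates, self.labels)

    @classmethod
    def from_frames(
        cls,
        brain: pd.DataFrame,
        phenotype: pd.DataFrame,
        covariates: pd.DataFrame,
        labels: pd.Series | None = None,
    ) -> "CohortTable":
        """Build a cohort in canonical (sorted-ID) order from aligned frames."""
        order = brain.index.sort_values()
        return cls(
            brain.loc[order].astype(float),
            phenotype.loc[order].astype(float),
            covariates.loc[order],
            labels.loc[order] if labels is not None else None,
        )


@dataclass
class AffinityMatrix:
    """Symmetric participant-by-participant similarity in [0, 1].

    ``kernel_scale`` records the Gaussian bandwidth used to build the
    matrix (same units as the feature's pairwise distance); fused
    matrices carry ``kernel_scale=None``.
    """

    values: np.ndarray
    index: np.ndarray
    kernel_scale: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be a square matrix")
        if v.shape[0] != len(self.index):
            raise ValueError("affinity size does not match participant index")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("affinity diagonal must be 1")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def same_index(self, other: "AffinityMatrix") -> bool:
        return np.array_equal(self.index, other.index)


@dataclass
class ConsensusMatrix:
    """Pairwise co-assignment counts accumulated over bagging iterations.

    ``co_sample[i, j]`` counts iterations where both i and j were in the
    subsample; ``co_assign[i, j]`` counts those where they additionally
    landed in the same cluster.  The frequency ``co_assign / co_sample``
    is undefined (NaN) for pairs never jointly sampled; self-pairs are
    defined as 1.
    """

    co_assign: np.ndarray
    co_sample: np.ndarray
    index: np.ndarray

    def __post_init__(self) -> None:
        a, s = np.asarray(self.co_assign), np.asarray(self.co_sample)
        if a.shape != s.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("co_assign/co_sample must be square and congruent")
        if (a > s).any():
            raise ValueError("co_assign cannot exceed co_sample")

    @classmethod
    def empty(cls, index: np.ndarray) -> "ConsensusMatrix":
        n = len(index)
        return cls(np.zeros((n, n), dtype=np.int64), np.zeros((n, n), dtype=np.int64), np.asarray(index))

    def frequency(self) -> np.ndarray:
        """Co-assignment frequency; NaN marks never-co-sampled pairs, diagonal 1."""
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(self.co_sample > 0, self.co_assign / np.maximum(self.co_sample, 1), np.nan)
        np.fill_diagonal(freq, 1.0)
        return freq


@dataclass
class ClusterSolution:
    """Participant -> cluster assignment (labels are 1-based, 1..k)."""

    labels: np.ndarray
    index: np.ndarray
    k: int
    source: str = "final"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.index):
            raise ValueError("labels length does not match participant index")
        if len(self.labels) == 0:
            raise ValueError("empty cluster solution")
        if self.labels.min() < 1:
            raise ValueError("cluster labels must be >= 1")

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.index, name="participant_id"), name="cluster")


@dataclass
class PipelineConfig:
    """Tunable parameters of the bagged clustering pipeline.

    Defaults mirror the full-scale study protocol: 50,000 subsamples per
    run, 10 runs aggregated by an element-wise median, 63.2% of
    participants per subsample, 2 of the phenotype scores and 7 brain
    regions per iteration, cluster counts drawn uniformly from 2..15,
    Gaussian bandwidth at the 75th percentile of pairwise distances and
    a 99th-percentile null threshold.
    """

    n_iterations: int = 50_000
    n_runs: int = 10
    participant_fraction: float = 0.632
    n_pheno_views_sampled: int = 2
    n_brain_features_sampled: int = 7
    k_min: int = 2
    k_max: int = 15
    kernel_percentile: float = 75.0
    null_percentile: float = 99.0
    rng_seed: int = 0
    n_jobs: int = 1

    def validate(self, n_brain_features: int | None = None, n_pheno_features: int | None = None) -> None:
        if not (0 < self.participant_fraction <= 1):
            raise ValueError("participant_fraction must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("require 2 <= k_min <= k_max")
        if self.n_iterations < 1 or self.n_runs < 1:
            raise ValueError("n_iterations and n_runs must be positive")
        if n_brain_features is not None and self.n_brain_features_sampled > n_brain_features:
            raise ValueError("n_brain_features_sampled exceeds available brain features")
        if n_pheno_features is not None and self.n_pheno_views_sampled > n_pheno_features:
            raise ValueError("n_pheno_views_sampled exceeds available phenotype scores")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Delimited-text ingestion
# ---------------------------------------------------------------------------


def read_cohort(
    brain_path: str | Path,
    phenotype_path: str | Path,
    schema: ColumnSchema = ColumnSchema(),
    *,
    delimiter: str = ",",
    on_missing: str = "drop",
) -> CohortTable:
    """Read a cohort from two delimited tables keyed by participant ID.

    Participants must appear in both files; the intersection is kept, in
    lexicographic ID order.  Rows with missing values in any required
    column (features or covariates) are excluded with a warning, or
    rejected outright with ``on_missing="error"``.  Missing labels are
    tolerated (labels are only used for agreement evaluation).
    """
    if on_missing not in ("drop", "error"):
        raise ValueError("on_missing must be 'drop' or 'error'")
    brain_df = pd.read_csv(brain_path, sep=delimiter)
    pheno_df = pd.read_csv(phenotype_path, sep=delimiter)

    for name, df, path in [("brain", brain_df, brain_path), ("phenotype", pheno_df, phenotype_path)]:
        if schema.id_col not in df.columns:
            raise ValueError(f"{name} table {path} lacks ID column {schema.id_col!r}")
        dupes = df[schema.id_col][df[schema.id_col].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate participant ID(s) in {name} table: {sorted(set(dupes))}")

    brain_df = brain_df.set_index(schema.id_col)
    pheno_df = pheno_df.set_index(schema.id_col)

    common = brain_df.index.intersection(pheno_df.index).sort_values()
    n_dropped = (len(brain_df) - len(common)) + (len(pheno_df) - len(common))
    if n_dropped:
        logger.warning("dropped %d row(s) not present in both tables", n_dropped)
    if len(common) == 0:
        raise ValueError("no participants shared between the two tables")
    brain_df = brain_df.loc[common]
    pheno_df = pheno_df.loc[common]

    covariate_cols = [c for c in schema.covariate_cols if c in brain_df.columns]
    if schema.brain_cols is not None:
        feature_cols = list(schema.brain_cols)
        missing_cols = set(feature_cols) - set(brain_df.columns)
        if missing_cols:
            raise ValueError(f"brain table lacks columns {sorted(missing_cols)}")
    else:
        feature_cols = [c for c in brain_df.columns if c not in covariate_cols]
    score_cols = list(schema.score_cols)
    missing_scores = set(score_cols) - set(pheno_df.columns)
    if missing_scores:
        raise ValueError(f"phenotype table lacks score columns {sorted(missing_scores)}")

    required = pd.concat(
        [brain_df[feature_cols + covariate_cols], pheno_df[score_cols]], axis=1
    )
    bad = required.isna().any(axis=1)
    if bad.any():
        offenders = list(required.index[bad])
        if on_missing == "error":
            raise ValueError(f"missing values for participants {offenders}")
        logger.warning(
            "excluding %d participant(s) with missing required values: %s",
            len(offenders), offenders,
        )
        keep = required.index[~bad]
        brain_df, pheno_df = brain_df.loc[keep], pheno_df.loc[keep]

    labels = None
    if schema.label_col is not None:
        if schema.label_col not in pheno_df.columns:
            raise ValueError(f"phenotype table lacks label column {schema.label_col!r}")
        labels = pheno_df[schema.label_col].astype("object")

    covariates = brain_df[covariate_cols]
    logger.info(
        "cohort: %d participants, %d brain features, %d scores",
        len(brain_df), len(feature_cols), len(score_cols),
    )
    return CohortTable.from_frames(
        brain_df[feature_cols].astype(float),
        pheno_df[score_cols].astype(float),
        covariates,
        labels,
    )


# ---------------------------------------------------------------------------
# Solution / matrix round-trip
# ---------------------------------------------------------------------------


def write_matrix(values: np.ndarray, index: np.ndarray, path: str | Path) -> Path:
    """Write a dense square matrix as CSV with an ID header row and column."""
    path = Path(path)
    pd.DataFrame(values, index=pd.Index(index, name="participant_id"), columns=index).to_csv(path)
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy()


def write_solution(
    solution: ClusterSolution,
    consensus: "ConsensusMatrix | np.ndarray",
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the assignment table and consensus frequency matrix to a directory."""
    if isinstance(consensus, ConsensusMatrix):
        if not np.array_equal(consensus.index, solution.index):
            raise ValueError("solution and consensus participant indexes differ")
        freq = consensus.frequency()
    else:
        freq = np.asarray(consensus, dtype=float)
        if freq.shape[0] != len(solution.index):
            raise ValueError("solution and consensus participant indexes differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assign_path = out_dir / "assignments.csv"
    solution.to_series().to_csv(assign_path)
    matrix_path = write_matrix(freq, solution.index, out_dir / "consensus.csv")
    return {"assignments": assign_path, "consensus": matrix_path}


def read_solution(path: str | Path, source: str = "final") -> ClusterSolution:
    df = pd.read_csv(path, index_col=0)
    labels = df["cluster"].to_numpy(dtype=int)
    return ClusterSolution(labels, df.index.to_numpy(), k=int(labels.max()), source=source)
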