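"""Randomized reference cohorts and the consensus significance threshold.

Two null constructions probe whether consensus connections reflect real
participant structure:

* *uniform*: every feature column is replaced by i.i.d. uniform draws
  over that column's observed [min, max];
* *permuted*: every feature column is independently shuffled across
  participants, preserving marginals exactly while destroying
  inter-feature and participant-level structure.

Running the identical pipeline on a null cohort yields a distribution
of co-assignment frequencies expected by chance; two participants are
deemed reliably similar when their real frequency exceeds a high
percentile (default 99th) of the null off-diagonal frequencies.  When
both nulls are available the conservative combined threshold is the
maximum of the two.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_model import CohortTable, ConsensusMatrix, PipelineConfig
from .bagging import PipelineResult, run_pipeline

logger = logging.getLogger("bagclust")

__all__ = [
    "generate_null_uniform",
    "generate_null_permuted",
    "connection_threshold",
    "count_exceeding",
    "null_thresholds",
]


def _null_columns(frame: pd.DataFrame, draw) -> pd.DataFrame:
    out = {}
    for col in frame.columns:
        out[col] = draw(frame[col].to_numpy(dtype=float))
    return pd.DataFrame(out, index=frame.index)


def generate_null_uniform(cohort: CohortTable, rng: np.random.Generator) -> CohortTable:
    """Replace every feature column by uniform draws over its observed range."""
    def draw(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if lo == hi:
            return np.full_like(x, lo)
        return rng.uniform(lo, hi, size=len(x))

    return CohortTable(
        _null_columns(cohort.brain, draw),
        _null_columns(cohort.phenotype, draw),
        cohort.covariates,
        cohort.labels,
    )


def generate_null_permuted(cohort: CohortTable, rng: np.random.Generator) -> CohortTable:
    """Independently permute every feature column across participants."""
    def draw(x: np.ndarray) -> np.ndarray:
        return rng.permutation(x)

    return CohortTable(
        _null_columns(cohort.brain, draw),
        _null_columns(cohort.phenotype, draw),
        cohort.covariates,
        cohort.labels,
    )


def _offdiag_defined(freq: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(freq.shape[0], k=1)
    vals = freq[iu]
    return vals[np.isfinite(vals)]


def connection_threshold(
    null_consensus: ConsensusMatrix | PipelineResult | np.ndarray,
    percentile: float = 99.0,
) -> float:
    """Percentile of the null consensus's defined off-diagonal frequencies."""
    if isinstance(null_consensus, ConsensusMatrix):
        freq = null_consensus.frequency()
    elif isinstance(null_consensus, PipelineResult):
        freq = null_consensus.median_frequency
    else:
        freq = np.asarray(null_consensus, dtype=float)
    vals = _offdiag_defined(freq)
    if len(vals) == 0:
        raise ValueError("no defined off-diagonal frequencies in the null consensus")
    if np.ptp(vals) == 0:
        logger.warning("all null frequencies identical (%g); threshold equals that value", vals[0])
    return float(np.percentile(vals, percentile))


def count_exceeding(real_frequency: np.ndarray, threshold: float) -> int:
    """Number of real off-diagonal pairs whose frequency exceeds the threshold."""
    return int((_offdiag_defined(real_frequency) > threshold).sum())


def null_thresholds(
    cohort: CohortTable,
    config: PipelineConfig,
    rng: np.random.Generator,
    which: str = "both",
) -> dict[str, object]:
    """Run the pipeline on null cohort(s) and report per-null and combined thresholds.

    The null pipelines reuse the real pipeline's config verbatim; only
    the input data differ.
    """
    if which not in ("uniform", "permuted", "both"):
        raise ValueError("which must be 'uniform', 'permuted' or 'both'")
    out: dict[str, object] = {}
    thresholds = []
    if which in ("uniform", "both"):
        null = generate_null_uniform(cohort, rng)
        res = run_pipeline(null, config)
        thr = connection_threshold(res, config.null_percentile)
        out["uniform"] = {"result": res, "threshold": thr}
        thresholds.append(thr)
    if which in ("permuted", "both"):
        null = generate_null_permuted(cohort, rng)
        res = run_pipeline(null, config)
        thr = connection_threshold(res, config.null_percentile)
        out["permuted"] = {"result": res, "threshold": thr}
        thresholds.append(thr)
    out["combined_threshold"] = max(thresholds)
    return out
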