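"""Per-measure Gaussian affinities and their fusion within/across views.

Each measure (one behavioural score, one region's thickness) yields one
participant-by-participant affinity matrix

    A[i, j] = exp(-d(i, j)^2 / (2 sigma^2)),   d(i, j) = |x_i - x_j|,

with the bandwidth sigma set to a percentile (default 75th) of the
n(n-1)/2 pairwise distances of that measure.  Percentiles use linear
interpolation between order statistics throughout the package.

Matrices of the same view are fused by an element-wise arithmetic mean
(clusters may match along any one feature); the brain and phenotype
views are then fused by an element-wise geometric mean, which requires
clusters to agree across the two views.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_model import AffinityMatrix

logger = logging.getLogger("bagclust")

__all__ = ["gaussian_affinity", "fuse_within_type", "fuse_across_types"]


def gaussian_affinity(
    feature_values: np.ndarray,
    index: np.ndarray | None = None,
    scale_percentile: float = 75.0,
    *,
    half_factor: bool = True,
) -> AffinityMatrix:
    """Gaussian affinity of one scalar measure across participants.

    ``half_factor=False`` drops the conventional 1/2 in the exponent
    (i.e. uses exp(-d^2 / sigma^2)).  If all pairwise distances are zero
    the feature carries no information and the affinity degenerates to
    an all-ones matrix (warned).
    """
    x = np.asarray(feature_values, dtype=float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 participants")
    if not np.isfinite(x).all():
        raise ValueError("feature values must be finite")
    if index is None:
        index = np.arange(n)
    elif len(index) != n:
        raise ValueError("index length does not match feature values")

    d = np.abs(x[:, None] - x[None, :])
    iu = np.triu_indices(n, k=1)
    sigma = float(np.percentile(d[iu], scale_percentile))
    if sigma == 0.0:
        logger.warning("all pairwise distances are zero; affinity degenerates to all-ones")
        return AffinityMatrix(np.ones((n, n)), np.asarray(index), kernel_scale=0.0)
    denom = 2.0 * sigma**2 if half_factor else sigma**2
    values = np.exp(-(d**2) / denom)
    np.fill_diagonal(values, 1.0)
    return AffinityMatrix(values, np.asarray(index), kernel_scale=sigma)


def fuse_within_type(affinities: list[AffinityMatrix]) -> AffinityMatrix:
    """Element-wise arithmetic mean of same-view affinity matrices."""
    if not affinities:
        raise ValueError("empty affinity list")
    first = affinities[0]
    for a in affinities[1:]:
        if not first.same_index(a):
            raise ValueError("affinity matrices have mismatched participant indexes")
    stacked = np.stack([a.values for a in affinities])
    fused = stacked.mean(axis=0)
    np.fill_diagonal(fused, 1.0)
    return AffinityMatrix(fused, first.index)


def fuse_across_types(brain: AffinityMatrix, pheno: AffinityMatrix) -> AffinityMatrix:
    """Element-wise geometric mean of the brain and phenotype affinities."""
    if not brain.same_index(pheno):
        raise ValueError("brain and phenotype affinities have mismatched indexes")
    fused = np.sqrt(brain.values * pheno.values)
    np.fill_diagonal(fused, 1.0)
    return AffinityMatrix(fused, brain.index)
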