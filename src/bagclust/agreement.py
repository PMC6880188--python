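"""Partition-agreement measures between clusterings and external labels.

Four standard measures quantify how well a data-driven partition lines
up with categorical labels (e.g. clinical diagnoses):

* normalized mutual information — I(A;B) divided by the arithmetic
  (default) or geometric mean of the two entropies, natural log;
* adjusted Rand index — pair counting, chance-corrected;
* homogeneity — 1 - H(class | cluster) / H(class): do clusters contain
  a single class?
* completeness — 1 - H(cluster | class) / H(cluster): does each class
  stay in one cluster?

Degenerate conventions: two identical trivial (single-cluster)
partitions agree perfectly (NMI = ARI = 1); a trivial partition against
a non-trivial one shares no information (NMI = ARI = 0); homogeneity is
1 when the class labels are constant, and dually for completeness.
The numerical work is delegated to scikit-learn's clustering metrics,
which implement exactly these conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .bagging import PipelineResult, final_clusters
from .io_model import AffinityMatrix, ClusterSolution

logger = logging.getLogger("bagclust")

__all__ = [
    "nmi",
    "adjusted_rand",
    "homogeneity",
    "completeness",
    "AgreementReport",
    "agreement_report",
    "agreement_sweep",
]


def _align(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Align two labelings; pandas Series are joined on their shared index."""
    if isinstance(a, ClusterSolution):
        a = a.to_series()
    if isinstance(b, ClusterSolution):
        b = b.to_series()
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("labelings share no participants")
        if len(common) < len(a) or len(common) < len(b):
            logger.info("agreement computed on %d shared participants", len(common))
        return a.loc[common].to_numpy(), b.loc[common].to_numpy()
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same participants")
    if a.size == 0:
        raise ValueError("empty labelings")
    return a, b


def nmi(a, b, *, average: str = "arithmetic") -> float:
    """Normalized mutual information in [0, 1]."""
    x, y = _align(a, b)
    logger.debug("NMI normalization: %s mean of entropies", average)
    return float(_skm.normalized_mutual_info_score(x, y, average_method=average))


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index (1 = identical partitions, ~0 = chance)."""
    x, y = _align(a, b)
    return float(_skm.adjusted_rand_score(x, y))


def homogeneity(clusters, classes) -> float:
    """1 - H(class | cluster) / H(class); 1 when every cluster is single-class."""
    x, y = _align(clusters, classes)
    return float(_skm.homogeneity_score(y, x))


def completeness(clusters, classes) -> float:
    """1 - H(cluster | class) / H(cluster); dual of homogeneity."""
    x, y = _align(clusters, classes)
    return float(_skm.completeness_score(y, x))


@dataclass
class AgreementReport:
    """All four agreement measures plus the underlying contingency table."""

    nmi: float
    adjusted_rand: float
    homogeneity: float
    completeness: float
    contingency: pd.DataFrame
    percentages: pd.DataFrame

    def as_dict(self) -> dict[str, float]:
        return {
            "nmi": self.nmi,
            "adjusted_rand": self.adjusted_rand,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
        }


def agreement_report(solution: ClusterSolution, labels: pd.Series, *, average: str = "arithmetic") -> AgreementReport:
    """Compare a cluster solution against categorical labels.

    ``percentages`` gives, per cluster, the percentage of its members in
    each label class (rows sum to 100).
    """
    sol = solution.to_series()
    labels = labels.dropna()
    x, y = _align(sol, labels)
    cont = pd.crosstab(pd.Series(x, name="cluster"), pd.Series(y, name="label"))
    pct = cont.div(cont.sum(axis=1), axis=0) * 100.0
    return AgreementReport(
        nmi=nmi(x, y, average=average),
        adjusted_rand=adjusted_rand(x, y),
        homogeneity=homogeneity(x, y),
        completeness=completeness(x, y),
        contingency=cont,
        percentages=pct,
    )


def agreement_sweep(
    consensus: PipelineResult | AffinityMatrix,
    labels: pd.Series,
    k_range: range | list[int] = range(2, 15),
    seed: int = 0,
) -> pd.DataFrame:
    """Agreement measures for final clusterings at each k in ``k_range``."""
    rows = []
    for k in k_range:
        sol = final_clusters(consensus, k, seed)
        rep = agreement_report(sol, labels)
        rows.append({"k": k, **rep.as_dict()})
    return pd.DataFrame(rows).set_index("k")
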