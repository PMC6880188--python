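"""Independent from-scratch oracles used to cross-check the implementation.

Everything here is deliberately written with plain loops, dictionaries
and hand-coded order statistics so it shares no code path with the
package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- order statistics -------------------------------------------------------


def percentile_linear(values, q: float) -> float:
    """Linear-interpolation percentile, hand-coded from the definition."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return xs[lo]
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def median_by_hand(values) -> float:
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mid = n // 2
    if n % 2 == 1:
        return xs[mid]
    return (xs[mid - 1] + xs[mid]) / 2.0


# -- partition agreement ----------------------------------------------------


def contingency(a, b) -> dict[tuple, int]:
    table: dict[tuple, int] = {}
    for x, y in zip(a, b):
        table[(x, y)] = table.get((x, y), 0) + 1
    return table


def _entropy(counts, n) -> float:
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log(p)
    return h


def _marginals(table):
    rows: dict = {}
    cols: dict = {}
    for (x, y), c in table.items():
        rows[x] = rows.get(x, 0) + c
        cols[y] = cols.get(y, 0) + c
    return rows, cols


def nmi_oracle(a, b, average: str = "arithmetic") -> float:
    n = len(a)
    table = contingency(a, b)
    rows, cols = _marginals(table)
    ha = _entropy(rows.values(), n)
    hb = _entropy(cols.values(), n)
    if ha == 0.0 and hb == 0.0:
        return 1.0
    mi = 0.0
    for (x, y), c in table.items():
        mi += (c / n) * math.log(c * n / (rows[x] * cols[y]))
    if average == "arithmetic":
        denom = (ha + hb) / 2.0
    else:
        denom = math.sqrt(ha * hb)
    if denom == 0.0:
        return 0.0
    return max(0.0, min(1.0, mi / denom))


def ari_oracle(a, b) -> float:
    """Adjusted Rand by O(n^2) enumeration of the four pair categories."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if den == 0.0:
        return 1.0 if (n10 == 0 and n01 == 0) else 0.0
    return num / den


def homogeneity_oracle(clusters, classes) -> float:
    """1 - H(class | cluster) / H(class), by direct entropy sums."""
    n = len(clusters)
    table = contingency(clusters, classes)
    rows, cols = _marginals(table)  # rows: clusters, cols: classes
    h_class = _entropy(cols.values(), n)
    if h_class == 0.0:
        return 1.0
    h_cond = 0.0
    for (x, _), c in table.items():
        h_cond -= (c / n) * math.log(c / rows[x])
    return 1.0 - h_cond / h_class


def completeness_oracle(clusters, classes) -> float:
    return homogeneity_oracle(classes, clusters)


# -- cluster quality --------------------------------------------------------


def within_between_oracle(A: np.ndarray, labels: np.ndarray, between_pct: float = 99.0):
    """Exhaustive-loop within/between ratio; returns (overall, per-cluster dict)."""
    per = {}
    num = 0.0
    den = 0
    for c in sorted(set(labels.tolist())):
        members = [i for i in range(len(labels)) if labels[i] == c]
        outside = [i for i in range(len(labels)) if labels[i] != c]
        if len(members) == 1:
            continue
        withins = []
        betweens = []
        for i in members:
            withins.append(median_by_hand([A[i, j] for j in members if j != i]))
            betweens.append(percentile_linear([A[i, j] for j in outside], between_pct))
        w = median_by_hand(withins)
        b = median_by_hand(betweens)
        ratio = w / b if b > 0 else 1e12
        per[c] = (w, b, ratio, len(members))
        num += len(members) * ratio
        den += len(members)
    return num / den, per


# -- normalized cut ---------------------------------------------------------


def best_ncut_partition(A: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive minimizer of the normalized cut over all k-partitions."""
    n = A.shape[0]
    degree = A.sum(axis=1)
    best = None
    best_score = math.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        if list(dict.fromkeys(assign)) != list(range(k)):
            continue  # canonical first-occurrence labeling: skip relabelings
        score = 0.0
        for c in range(k):
            members = [i for i in range(n) if assign[i] == c]
            vol = sum(degree[i] for i in members)
            cut = sum(A[i, j] for i in members for j in range(n) if assign[j] != c)
            if vol == 0:
                score = math.inf
                break
            score += cut / vol
        if score < best_score:
            best_score = score
            best = assign
    return np.asarray(best)
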