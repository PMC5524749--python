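"""Hierarchical clustering of detection profiles with bootstrap stability.

Samples are clustered on 1 - Pearson correlation between their binary
(or quantitative) target profiles, with average linkage.  Cluster stability
is the ordinary bootstrap probability: targets (columns) are resampled with
replacement ``n_boot`` times, the tree is rebuilt, and each original
cluster is scored by the percentage of bootstrap trees containing exactly
the same sample set.  (No multiscale/AU correction is applied; stability
values are plain bootstrap percentages.)

Zero-variance profiles have no defined correlation: they are placed at
distance 0 from identical profiles and the maximal distance 1 - (-1) = 2
is capped to 1 against everything else, a deterministic tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ParameterError


def pearson_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows, with the tie rule."""
    n, m = profiles.shape
    sd = profiles.std(axis=1)
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(profiles[i], profiles[j]):
                dist.append(0.0)
            elif sd[i] == 0 or sd[j] == 0:
                dist.append(1.0)
            else:
                r = float(
                    centered[i] @ centered[j] / (m * sd[i] * sd[j])
                )
                dist.append(1.0 - r)
    return np.asarray(dist)


def _cluster_sets(linkage: np.ndarray, n: int) -> list[frozenset[int]]:
    """Sample-index sets of every internal node except the trivial root."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    sets = []
    for k, (a, b, _d, _c) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        if len(merged) < n:
            sets.append(merged)
    return sets


@dataclass
class ClusterResult:
    """Average-linkage tree over samples plus per-cluster stability."""

    labels: list[str]
    linkage: np.ndarray
    stability: dict[frozenset[str], float]
    n_boot: int

    def stability_of(self, *labels: str) -> float:
        return self.stability[frozenset(labels)]

    def to_newick(self) -> str:
        """Newick string with bootstrap-stability percentages as node labels."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> tuple[str, frozenset[str]]:
            if node.is_leaf():
                return self.labels[node.id], frozenset([self.labels[node.id]])
            left, lset = walk(node.left)
            right, rset = walk(node.right)
            merged = lset | rset
            support = self.stability.get(merged)
            tag = "" if support is None else f"{support:.0f}"
            return f"({left},{right}){tag}:{node.dist:.4f}", merged

        text, _ = walk(tree)
        return text + ";"


def cluster_profiles(
    dm: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> ClusterResult:
    """Cluster sample profiles and score cluster stability by bootstrap.

    ``dm`` is a samples x targets matrix (binary detection or intensities).
    Deterministic under ``seed``.
    """
    if dm.shape[0] < 3:
        raise ParameterError("need at least 3 samples to cluster")
    if dm.shape[1] < 2:
        raise ParameterError("need at least 2 targets to cluster")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    profiles = dm.to_numpy(dtype=float)
    n, m = profiles.shape
    base_linkage = hierarchy.linkage(pearson_distance(profiles), method="average")
    base_sets = _cluster_sets(base_linkage, n)
    counts = {s: 0 for s in base_sets}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        boot = profiles[:, cols]
        linkage = hierarchy.linkage(pearson_distance(boot), method="average")
        seen = set(_cluster_sets(linkage, n))
        for s in base_sets:
            if s in seen:
                counts[s] += 1
    labels = [str(x) for x in dm.index]
    stability = {
        frozenset(labels[i] for i in s): 100.0 * c / n_boot
        for s, c in counts.items()
    }
    return ClusterResult(labels, base_linkage, stability, n_boot)
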