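"""ToxPi-style potency scaling, profile clustering, and merged MSE ranking.

Each endpoint becomes one ToxPi "slice".  A BMC of x µM transforms to
``-log10(x) + 6`` so that lower (more potent) BMCs score higher; a censored
BMC is assigned the sentinel concentration 10^6 µM, which the transform maps
to exactly 0.  Slices are then scaled to [0, 1] by the per-endpoint maximum
across compounds (1 marks the lowest BMC in that endpoint).  The compound
ToxPi score is the weighted mean of its slices.

The merged ranking gives first priority to the most sensitive endpoint
(MSE): compounds are ordered by ascending MSE BMC, but compounds whose MSE
BMCs lie within each other's 3-fold ranges ([BMC/3, BMC*3], merged
transitively) are treated as equipotent and ordered by descending ToxPi
score within the tie group.  Compounds without a specific hit rank last,
ordered by ToxPi score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigurationError

SENTINEL_UM = 1.0e6


def scale_bmcs(
    bmc_matrix: pd.DataFrame,
    sentinel: float = SENTINEL_UM,
    strategy: str = "per_endpoint",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(raw, scaled) slice-score matrices from a compound x endpoint BMC table.

    ``bmc_matrix`` holds BMCs in µM with NaN marking censored entries.
    ``strategy`` selects the normalization denominator: the maximum raw score
    within each endpoint (default) or the global maximum.
    """
    vals = bmc_matrix.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("BMCs must be positive (µM); censored entries are NaN")
    filled = np.where(np.isfinite(vals), vals, sentinel)
    raw = -np.log10(filled) + 6.0
    raw = np.maximum(raw, 0.0)  # concentrations beyond the sentinel floor at 0
    raw_df = pd.DataFrame(raw, index=bmc_matrix.index, columns=bmc_matrix.columns)
    if strategy == "per_endpoint":
        denom = raw_df.max(axis=0)
    elif strategy == "global":
        denom = pd.Series(raw_df.to_numpy().max(), index=bmc_matrix.columns)
    else:
        raise ValueError(f"unknown scaling strategy {strategy!r}")
    denom = denom.replace(0.0, np.nan)
    scaled = (raw_df / denom).fillna(0.0)
    return raw_df, scaled


def toxpi_scores(scaled: pd.DataFrame, weights: dict[str, float] | None = None) -> pd.Series:
    """Weighted mean of scaled slices per compound (equal weights by default)."""
    if weights is None:
        w = pd.Series(1.0, index=scaled.columns)
    else:
        unknown = sorted(set(weights) - set(scaled.columns))
        if unknown:
            raise ConfigurationError(f"weights reference unknown endpoints: {unknown}")
        w = pd.Series({ep: float(weights.get(ep, 0.0)) for ep in scaled.columns})
        if (w < 0).any() or w.sum() == 0:
            raise ConfigurationError("weights must be nonnegative and not all zero")
    return (scaled * w).sum(axis=1) / w.sum()


@dataclass
class ClusterResult:
    labels: list[str]
    linkage_matrix: np.ndarray

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def cluster_profiles(
    scaled: pd.DataFrame, method: str = "average", metric: str = "euclidean"
) -> ClusterResult:
    """Agglomerative clustering of compound slice vectors.

    Average linkage on Euclidean distances by default; rows are sorted by
    compound id before computing distances so the tree is invariant to input
    order (distance ties then break deterministically).
    """
    ordered = scaled.sort_index()
    labels = list(ordered.index)
    if len(labels) < 2:
        return ClusterResult(labels, np.empty((0, 4)))
    z = linkage(pdist(ordered.to_numpy(dtype=float), metric=metric), method=method)
    return ClusterResult(labels, z)


@dataclass
class RankingResult:
    order: list[str]
    method: str  # "toxpi" | "mse" | "merged"
    tie_groups: list[list[str]] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)


def fold_range_tie_groups(mse_bmcs: dict[str, float], fold: float = 3.0) -> list[list[str]]:
    """Transitive closure of pairwise x-fold range overlap on MSE BMCs.

    Two compounds are linked when ``[b/fold, b*fold]`` intervals intersect;
    groups are the connected components, ordered by their smallest BMC.
    """
    comps = sorted(mse_bmcs, key=lambda k: (mse_bmcs[k], k))
    parent = {c: c for c in comps}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(comps):
        for b in comps[i + 1:]:
            la, ha = mse_bmcs[a] / fold, mse_bmcs[a] * fold
            lb, hb = mse_bmcs[b] / fold, mse_bmcs[b] * fold
            if min(ha, hb) >= max(la, lb):
                parent[find(b)] = find(a)
    groups: dict[str, list[str]] = {}
    for c in comps:
        groups.setdefault(find(c), []).append(c)
    return sorted(groups.values(), key=lambda g: min(mse_bmcs[c] for c in g))


def rank_by_mse(mse_bmcs: dict[str, float]) -> RankingResult:
    """Plain ascending-BMC ranking over compounds with a specific hit."""
    order = sorted(mse_bmcs, key=lambda k: (mse_bmcs[k], k))
    return RankingResult(order, "mse", scores=dict(mse_bmcs))


def rank_by_toxpi(toxpi: dict[str, float]) -> RankingResult:
    order = sorted(toxpi, key=lambda k: (-toxpi[k], k))
    return RankingResult(order, "toxpi", scores=dict(toxpi))


def merged_rank(
    mse_bmcs: dict[str, float | None],
    toxpi: dict[str, float],
    fold: float = 3.0,
) -> RankingResult:
    """MSE-first ranking with ToxPi deciding within 3-fold MSE tie groups.

    ``mse_bmcs`` maps every compound to its MSE BMC (µM) or ``None`` when it
    has no specific hit; such compounds rank last in ToxPi order.
    """
    with_mse = {c: float(b) for c, b in mse_bmcs.items() if b is not None}
    without = [c for c, b in mse_bmcs.items() if b is None]
    groups = fold_range_tie_groups(with_mse, fold=fold)
    order: list[str] = []
    for g in groups:
        order.extend(sorted(g, key=lambda c: (-toxpi.get(c, 0.0), c)))
    order.extend(sorted(without, key=lambda c: (-toxpi.get(c, 0.0), c)))
    return RankingResult(order, "merged", tie_groups=groups, scores=dict(toxpi))
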