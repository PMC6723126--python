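"""Tight, non-exhaustive clustering of regulated-transcript profiles.

Expression profiles are Z-scored per gene, over-clustered with seeded
k-means, and only the tight clusters (within-cluster dispersion below a
quantile of the dispersion distribution) are retained; retained clusters
whose centroids correlate strongly are merged, undersized clusters are
dropped, and everything else is left unassigned.  This reproduces the
contract of data-extraction clustering — coherent clusters, roughly half
the genes assigned — without exhaustive partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def zscore_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Z-scores of the time-point log2fc profile.

    Accepts the tidy profile table (control excluded automatically) or an
    already-wide gene-by-condition frame.  Rows are centered to mean 0 and
    scaled to (population) sd 1.  Constant profiles cannot be Z-scored and
    are returned separately as pre-unassigned genes.
    """
    if {"feature_id", "condition", "log2fc"} <= set(profiles.columns):
        sub = profiles.loc[profiles["minutes"].notna()]
        minutes = dict(sub.drop_duplicates("condition").set_index("condition")["minutes"])
        wide = sub.pivot(index="feature_id", columns="condition", values="log2fc")
        wide = wide[sorted(minutes, key=minutes.get)]
    else:
        wide = profiles
    X = wide.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    Z = (X[~constant] - X[~constant].mean(axis=1, keepdims=True)) / sd[~constant, None]
    zdf = pd.DataFrame(Z, index=wide.index[~constant], columns=wide.columns)
    return zdf, list(wide.index[constant])


@dataclass
class ClusterSet:
    """Result of tight-cluster extraction.

    ``assignments`` maps every input gene to a cluster id or -1
    (unassigned); ``centroids`` holds each cluster's mean Z-profile.
    """

    assignments: pd.Series
    centroids: pd.DataFrame
    params: dict

    def __post_init__(self) -> None:
        ids = set(self.assignments.unique()) - {-1}
        if ids != set(self.centroids.index):
            raise ValueError("centroid table does not match cluster ids")
        min_size = self.params.get("min_size", 1)
        sizes = self.assignments[self.assignments >= 0].value_counts()
        if (sizes < min_size).any():
            raise ValueError("cluster below min_size")

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for feat, cid in self.assignments.items():
            if cid >= 0:
                out.setdefault(int(cid), []).append(feat)
        return out

    @property
    def unassigned(self) -> list[str]:
        return list(self.assignments.index[self.assignments == -1])

    @property
    def n_clustered(self) -> int:
        return int((self.assignments >= 0).sum())


def _merge_tight(centroids: dict[int, np.ndarray], members: dict[int, list[int]],
                 Z: np.ndarray, merge_r: float) -> None:
    """Iteratively merge the pair of clusters with the highest centroid
    Pearson correlation above ``merge_r`` (ties: lowest ids)."""
    while len(centroids) > 1:
        ids = sorted(centroids)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ca, cb = centroids[a], centroids[b]
                if ca.std() == 0 or cb.std() == 0:
                    continue
                r = float(np.corrcoef(ca, cb)[0, 1])
                if r > merge_r and (best is None or r > best[0] + 1e-15):
                    best = (r, a, b)
        if best is None:
            return
        _, a, b = best
        members[a] = members[a] + members[b]
        centroids[a] = Z[members[a]].mean(axis=0)
        del members[b], centroids[b]


def extract_tight_clusters(
    Z: pd.DataFrame,
    k_init: int = 30,
    tightness_quantile: float = 0.5,
    merge_r: float = 0.8,
    min_size: int = 5,
    seed: int = 0,
    pre_unassigned: list[str] | None = None,
) -> ClusterSet:
    """Over-cluster, keep the tight clusters, merge correlated ones.

    Steps: (1) k-means with ``k_init`` centers; (2) per-cluster mean
    Euclidean distance to centroid; keep clusters at or below the
    ``tightness_quantile`` of that dispersion distribution; (3) iteratively
    merge kept clusters with centroid correlation > ``merge_r``; (4) drop
    clusters smaller than ``min_size``.  All other genes are unassigned.
    Deterministic given the seed.
    """
    if len(Z) == 0:
        raise ValueError("empty Z matrix")
    if k_init < 2:
        raise ValueError("k_init must be >= 2")
    if k_init > len(Z):
        raise ValueError("k_init exceeds the number of features")
    X = Z.to_numpy(dtype=float)
    km = KMeans(n_clusters=k_init, n_init=10, random_state=seed).fit(X)
    labels = km.labels_

    dispersion = {}
    members: dict[int, list[int]] = {}
    for c in range(k_init):
        idx = np.nonzero(labels == c)[0]
        if len(idx) == 0:
            continue
        members[c] = list(idx)
        dispersion[c] = float(
            np.linalg.norm(X[idx] - km.cluster_centers_[c], axis=1).mean()
        )
    threshold = float(np.quantile(list(dispersion.values()), tightness_quantile))
    kept = {c: members[c] for c in members if dispersion[c] <= threshold}
    centroids = {c: X[kept[c]].mean(axis=0) for c in kept}

    _merge_tight(centroids, kept, X, merge_r)
    kept = {c: m for c, m in kept.items() if len(m) >= min_size}

    assignments = pd.Series(-1, index=Z.index, dtype=int)
    centroid_rows = {}
    for new_id, c in enumerate(sorted(kept, key=lambda c: (-len(kept[c]), c))):
        assignments.iloc[kept[c]] = new_id
        centroid_rows[new_id] = X[kept[c]].mean(axis=0)
    if pre_unassigned:
        extra = pd.Series(-1, index=pd.Index(pre_unassigned), dtype=int)
        assignments = pd.concat([assignments, extra])
    centroids_df = pd.DataFrame.from_dict(centroid_rows, orient="index",
                                          columns=Z.columns)
    centroids_df.index.name = "cluster"
    return ClusterSet(
        assignments=assignments,
        centroids=centroids_df,
        params={
            "k_init": k_init,
            "tightness_quantile": tightness_quantile,
            "merge_r": merge_r,
            "min_size": min_size,
            "seed": seed,
        },
    )


def classify_cluster_shape(mean_profile, rel_threshold: float = 0.5) -> str:
    """Classify a mean Z-profile as 'up', 'down' or 'oscillatory'.

    'oscillatory' is early repression followed by late induction: a
    significant minimum (below ``-rel_threshold`` times the extremum
    magnitude) strictly before a significant maximum, with the dip not at
    the first time point (so monotone ramps, whose Z-scores necessarily
    straddle zero, do not qualify).  Everything else is 'up' or 'down' by
    whether the rise from the starting value to the global maximum exceeds
    the fall from the starting value to the global minimum.
    """
    z = np.asarray(mean_profile, dtype=float)
    if len(z) < 3:
        raise ValueError("profile must have length >= 3")
    ext = float(np.abs(z).max())
    if ext == 0:
        return "up"  # flat: degenerate, arbitrary but deterministic
    i_max, i_min = int(z.argmax()), int(z.argmin())
    sig_max = z[i_max] >= rel_threshold * ext
    sig_min = z[i_min] <= -rel_threshold * ext
    if sig_max and sig_min and 0 < i_min < i_max:
        return "oscillatory"
    rise = z[i_max] - z[0]
    fall = z[0] - z[i_min]
    return "up" if rise >= fall else "down"


@dataclass
class ClusterSummary:
    n_clusters: int
    n_clustered: int
    fraction_clustered_percent: float
    mean_cluster_size: float


def cluster_summary(clusters: ClusterSet | None, n_regulated_total: int,
                    n_clusters: int | None = None,
                    n_clustered: int | None = None) -> ClusterSummary:
    """Headline clustering statistics (counts may be given directly)."""
    from .report import round_half_up

    if clusters is not None:
        n_clusters = len(clusters.centroids)
        n_clustered = clusters.n_clustered
    if n_clusters is None or n_clustered is None:
        raise ValueError("provide a ClusterSet or explicit counts")
    if n_clusters == 0 or n_regulated_total == 0:
        return ClusterSummary(0, 0, 0.0, 0.0)
    return ClusterSummary(
        n_clusters=n_clusters,
        n_clustered=n_clustered,
        fraction_clustered_percent=round_half_up(
            100.0 * n_clustered / n_regulated_total, 1
        ),
        mean_cluster_size=round_half_up(n_clustered / n_clusters, 1),
    )
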