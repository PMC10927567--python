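"""Region-by-region interactome integration and classification.

The per-region differential-release analyses are integrated into a
protein x region matrix of S0-modified test statistics ("t-scores"),
restricted to proteins significant in at least one region. The matrix is
clustered (seeded k-means pre-grouping followed by complete-linkage
Euclidean hierarchical clustering of the group centroids) and each protein
is classified as *region-specific* (significant in fewer than
``multiregion_min`` regions; its primary region is the one with the largest
t-score) or *multiregional*.

Cells for proteins absent from a region's table are filled with 0 — "no
measured enrichment" — with an explicit absence mask, matching the display
convention in which scores at or below 0 share the lowest colour bin. The
display bins use the fixed edges (0, 2, 6, 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .errors import ConfigurationError
from .stats_core import EnrichmentResult

__all__ = [
    "RegionalProfileMatrix",
    "assemble_tscore_matrix",
    "cluster_tscores",
    "classify_region_specificity",
    "bin_tscores",
    "TSCORE_BIN_EDGES",
]

TSCORE_BIN_EDGES = (0.0, 2.0, 6.0, 10.0)
TSCORE_BIN_LABELS = ("le0", "0-2", "2-6", "6-10", "ge10")


@dataclass
class RegionalProfileMatrix:
    """Protein x region t-score matrix with masks and assignments."""

    tscores: pd.DataFrame          # proteins x regions, d_stat values
    significant: pd.DataFrame      # same shape, boolean
    absent: pd.DataFrame           # True where the protein was not in that table
    region_order: list[str]
    cluster_ids: pd.Series | None = None
    specificity: pd.DataFrame | None = None

    @property
    def proteins(self) -> pd.Index:
        return self.tscores.index


def assemble_tscore_matrix(
    results: Mapping[str, EnrichmentResult | pd.DataFrame],
) -> RegionalProfileMatrix:
    """Combine per-region enrichment results into a t-score matrix.

    ``results`` maps region name -> :class:`EnrichmentResult` (or its
    ``frame``). Only proteins significant in at least one region are
    retained; a retained protein absent from some region's table gets a
    t-score of 0 there, recorded in the absence mask.
    """
    if len(results) < 2:
        raise ConfigurationError("need results for at least 2 regions")
    regions = list(results)
    if len(set(regions)) != len(regions):
        raise ConfigurationError("duplicate region names")
    frames = {r: (res.frame if isinstance(res, EnrichmentResult) else res)
              for r, res in results.items()}
    keep: pd.Index | None = None
    for frame in frames.values():
        sig = frame.index[frame["significant"]]
        keep = sig if keep is None else keep.union(sig)
    keep = keep.sort_values()

    tscores = pd.DataFrame(0.0, index=keep, columns=regions)
    significant = pd.DataFrame(False, index=keep, columns=regions)
    absent = pd.DataFrame(True, index=keep, columns=regions)
    for region, frame in frames.items():
        common = keep.intersection(frame.index)
        tscores.loc[common, region] = frame.loc[common, "d_stat"]
        significant.loc[common, region] = frame.loc[common, "significant"]
        absent.loc[common, region] = False
    return RegionalProfileMatrix(
        tscores=tscores, significant=significant, absent=absent,
        region_order=regions,
    )


def cluster_tscores(
    matrix: RegionalProfileMatrix,
    *,
    kmeans_pre_k: int | None = None,
    n_clusters: int | None = None,
    seed: int = 0,
) -> RegionalProfileMatrix:
    """Cluster protein t-score profiles; returns the matrix with cluster ids.

    Rows are pre-grouped by seeded k-means into ``kmeans_pre_k`` groups
    (default min(300, n//2)); the group centroids are then merged by
    complete-linkage Euclidean hierarchical clustering and every protein
    inherits its group's tree position. Flat clusters are cut at
    ``n_clusters`` if given, otherwise at the largest gap between
    consecutive merge heights. Cluster ids are contiguous from 1 in
    dendrogram leaf order.

    Rows are canonically ordered (lexicographically by profile) before
    k-means, so the partition is invariant to input row order per seed.
    """
    X = matrix.tscores.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        ids = pd.Series(1, index=matrix.proteins, name="cluster_id")
        matrix.cluster_ids = ids
        return matrix
    if kmeans_pre_k is None:
        kmeans_pre_k = max(1, min(300, n // 2))
    if kmeans_pre_k > n:
        raise ConfigurationError(
            f"kmeans_pre_k={kmeans_pre_k} exceeds the number of proteins {n}"
        )

    canonical = np.lexsort(X.T[::-1])  # row order independent of input order
    Xc = X[canonical]
    km = KMeans(n_clusters=kmeans_pre_k, random_state=seed, n_init=10)
    group_c = km.fit_predict(Xc)
    group = np.empty(n, dtype=int)
    group[canonical] = group_c
    centroids = km.cluster_centers_

    if kmeans_pre_k == 1:
        leaf_cluster = np.array([1])
    else:
        Z = linkage(centroids, method="complete", metric="euclidean")
        if n_clusters is None:
            heights = Z[:, 2]
            if len(heights) > 1:
                gaps = np.diff(heights)
                n_clusters = len(heights) - int(np.argmax(gaps))
            else:
                n_clusters = 2
        n_clusters = max(1, min(n_clusters, kmeans_pre_k))
        leaf_cluster = fcluster(Z, t=n_clusters, criterion="maxclust")

    raw = leaf_cluster[group]
    # relabel contiguous from 1 in order of first appearance along the tree
    order = {c: i + 1 for i, c in enumerate(pd.unique(leaf_cluster))}
    ids = pd.Series([order[c] for c in raw], index=matrix.proteins,
                    name="cluster_id")
    matrix.cluster_ids = ids
    return matrix


def classify_region_specificity(
    matrix: RegionalProfileMatrix, multiregion_min: int = 3
) -> pd.DataFrame:
    """Classify each retained protein as region-specific or multiregional.

    A protein significant in at least ``multiregion_min`` regions is
    *multiregional*; otherwise it is *region-specific* with its primary
    region the argmax of its t-scores (ties broken by region order and
    recorded in the ``tie`` column). The result is stored on the matrix and
    returned.
    """
    sig_counts = matrix.significant.sum(axis=1)
    tsc = matrix.tscores[matrix.region_order]
    primary = tsc.idxmax(axis=1)
    row_max = tsc.max(axis=1)
    tie = (tsc.eq(row_max, axis=0)).sum(axis=1) > 1
    spec = pd.DataFrame(
        {
            "specificity": np.where(sig_counts >= multiregion_min,
                                    "multiregional", "region_specific"),
            "primary_region": primary.where(sig_counts < multiregion_min),
            "n_significant_regions": sig_counts,
            "tie": tie,
        },
        index=matrix.proteins,
    )
    matrix.specificity = spec
    return spec


def bin_tscores(matrix: RegionalProfileMatrix) -> pd.DataFrame:
    """Assign each cell a display colour-bin class over edges (0, 2, 6, 10)."""
    edges = [-np.inf, *TSCORE_BIN_EDGES, np.inf]
    out = matrix.tscores.apply(
        lambda col: pd.cut(col, bins=edges, labels=TSCORE_BIN_LABELS,
                           right=True).astype(str)
    )
    return out
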