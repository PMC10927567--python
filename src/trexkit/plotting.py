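"""Figure helpers: volcano plots, ranked affinity plots, t-score heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regional import RegionalProfileMatrix, bin_tscores

__all__ = ["ranked_affinity_plot", "tscore_heatmap", "heatmap_coordinates"]


def ranked_affinity_plot(affinity_table: pd.DataFrame, ax=None,
                         highlight: list[str] | None = None):
    """Ranked Ka plot (log scale); optionally highlight named proteins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ranked = affinity_table.dropna(subset=["ka"]).sort_values("ka",
                                                              ascending=False)
    ax.scatter(np.arange(1, len(ranked) + 1), ranked["ka"], s=8, c="0.4")
    if highlight:
        for name in highlight:
            if name in ranked.index:
                pos = ranked.index.get_loc(name) + 1
                ax.scatter([pos], [ranked.loc[name, "ka"]], c="purple", s=25)
                ax.annotate(name, (pos, ranked.loc[name, "ka"]), fontsize=8)
    ax.set_yscale("log")
    ax.set_xlabel("rank")
    ax.set_ylabel("estimated relative affinity Ka")
    return ax


def heatmap_coordinates(matrix: RegionalProfileMatrix) -> pd.DataFrame:
    """Long-format heatmap export: protein order, region, t-score, bin."""
    if matrix.cluster_ids is not None:
        order = matrix.cluster_ids.sort_values(kind="stable").index
    else:
        order = matrix.proteins
    bins = bin_tscores(matrix)
    rows = []
    for pos, protein in enumerate(order):
        for region in matrix.region_order:
            rows.append({
                "protein_id": protein,
                "row": pos,
                "region": region,
                "t_score": matrix.tscores.loc[protein, region],
                "bin": bins.loc[protein, region],
                "absent": bool(matrix.absent.loc[protein, region]),
                "cluster_id": int(matrix.cluster_ids.loc[protein])
                if matrix.cluster_ids is not None else None,
            })
    return pd.DataFrame(rows)


def tscore_heatmap(matrix: RegionalProfileMatrix, ax=None):
    """Heatmap of t-scores in cluster order with the standard colour bins."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 8))
    if matrix.cluster_ids is not None:
        order = matrix.cluster_ids.sort_values(kind="stable").index
    else:
        order = matrix.proteins
    data = matrix.tscores.loc[order, matrix.region_order].to_numpy()
    cmap = ListedColormap(["black", "darkred", "red", "orange", "yellow"])
    norm = BoundaryNorm([-1e9, 0, 2, 6, 10, 1e9], cmap.N)
    ax.imshow(data, aspect="auto", cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_xticks(range(len(matrix.region_order)))
    ax.set_xticklabels(matrix.region_order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(order)} proteins")
    return ax
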