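"""Hierarchical clustering of samples on abundant bait peptidoforms.

Mirrors the heatmap-package defaults: Euclidean distance with complete
linkage on both rows and columns of the log2-transformed, zero-filled
count matrix; sample clusters are read off by cutting the column
dendrogram at the number of condition labels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .io_formats import ExperimentDesign
from .peptidoform import CountMatrix, Peptidoform

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 10
DEFAULT_MIN_SAMPLES = 2


@dataclass
class ClusterResult:
    features: list[Peptidoform]
    matrix: pd.DataFrame  # transformed, features x samples
    method: str
    metric: str
    sample_order: list[str]  # dendrogram leaf order
    feature_order: list[str]
    flat_clusters: dict[str, int]  # sample_id -> cluster label (1..k)
    n_clusters: int


def select_abundant(
    counts: CountMatrix,
    min_total: float = DEFAULT_MIN_TOTAL,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> CountMatrix:
    """Keep peptidoforms with dataset-wide total >= ``min_total`` that are
    detected (count > 0) in at least ``min_samples`` samples."""
    totals = counts.row_totals()
    detected = (counts.df > 0).sum(axis=1)
    keep = totals.index[(totals >= min_total) & (detected >= min_samples)].tolist()
    if not keep:
        logger.warning("no peptidoforms pass the abundance filter; clustering will be skipped")
    return counts.subset_rows(keep)


def log2_zero_fill(counts: CountMatrix) -> pd.DataFrame:
    """log2-transform positive counts; non-detected (zero) entries stay 0.

    Note log2(1) == 0 collides with non-detected; the upstream singleton
    filter removes most count-1 rows.
    """
    values = counts.df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.zeros_like(values)
    np.log2(values, out=out, where=values > 0)
    return pd.DataFrame(out, index=counts.df.index, columns=counts.df.columns)


def hcluster(matrix: pd.DataFrame, n_clusters: int, method: str = "complete",
             metric: str = "euclidean") -> ClusterResult:
    """Cluster rows (peptidoforms) and columns (samples) hierarchically.

    ``n_clusters`` flat sample clusters are produced by cutting the column
    dendrogram; it is normally the number of distinct condition labels.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.shape[0] < 1:
        raise ValueError("need at least 1 feature to cluster")
    col_link = linkage(matrix.to_numpy().T, method=method, metric=metric)
    if matrix.shape[0] >= 2:
        row_link = linkage(matrix.to_numpy(), method=method, metric=metric)
        feature_order = [matrix.index[i] for i in leaves_list(row_link)]
    else:
        feature_order = list(matrix.index)
    sample_order = [matrix.columns[i] for i in leaves_list(col_link)]
    labels = fcluster(col_link, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        features=[],
        matrix=matrix,
        method=method,
        metric=metric,
        sample_order=sample_order,
        feature_order=feature_order,
        flat_clusters={s: int(l) for s, l in zip(matrix.columns, labels)},
        n_clusters=n_clusters,
    )


def cluster_counts(
    counts: CountMatrix,
    design: ExperimentDesign,
    min_total: float = DEFAULT_MIN_TOTAL,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> ClusterResult | None:
    """Abundance-filter, transform and cluster; None when nothing passes."""
    abundant = select_abundant(counts, min_total, min_samples)
    if abundant.df.shape[0] == 0:
        return None
    transformed = log2_zero_fill(abundant)
    k = len(set(design.condition_of(s) for s in transformed.columns))
    result = hcluster(transformed, n_clusters=max(k, 1))
    result.features = [abundant.peptidoforms[key] for key in abundant.keys]
    return result


def condition_agreement(
    result: ClusterResult, design: ExperimentDesign
) -> tuple[int, int]:
    """How many samples sit in a cluster whose majority condition is their own.

    Each flat cluster is assigned its majority condition; ties break
    toward the condition with more samples overall, then lexicographic.
    """
    condition_sizes = Counter(design.condition_of(s) for s in result.flat_clusters)
    by_cluster: dict[int, list[str]] = {}
    for sample, cl in result.flat_clusters.items():
        by_cluster.setdefault(cl, []).append(sample)
    n_correct = 0
    for cl, members in by_cluster.items():
        votes = Counter(design.condition_of(s) for s in members)
        majority = min(
            votes,
            key=lambda c: (-votes[c], -condition_sizes[c], c),
        )
        n_correct += sum(1 for s in members if design.condition_of(s) == majority)
    return n_correct, len(result.flat_clusters)


def plot_heatmap(result: ClusterResult, path: str) -> None:
    """Render the clustered matrix to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = result.matrix.loc[result.feature_order, result.sample_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * ordered.shape[1] + 2), max(3, 0.25 * ordered.shape[0] + 1))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 PSM count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
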