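"""Extreme-DE gene selection, row standardization and two-way hierarchical clustering.

Reproduces the heatmap-style analysis: take the k most up- and k most
down-regulated DE genes, z-score each gene across samples, cluster genes
and samples (Ward linkage on Euclidean distances by default) and score how
cleanly a two-cluster cut of the sample tree separates the true groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_io import DataError
from .normalize_filter import NormalizedTable


@dataclass
class ClusterResult:
    gene_order: list          # selected genes in dendrogram leaf order
    sample_order: list        # samples in dendrogram leaf order
    row_linkage: np.ndarray   # scipy linkage matrix over genes
    col_linkage: np.ndarray   # scipy linkage matrix over samples
    purity: float             # 2-cut column partition vs true groups

    def to_frame(self) -> pd.DataFrame:
        n = max(len(self.gene_order), len(self.sample_order))
        return pd.DataFrame({
            "rank": range(n),
            "gene": list(self.gene_order) + [""] * (n - len(self.gene_order)),
            "sample": list(self.sample_order) + [""] * (n - len(self.sample_order)),
            "purity": [self.purity] + [np.nan] * (n - 1),
        })


def select_extreme_de(records: pd.DataFrame, k: int = 20) -> list[str]:
    """The k most up- and k most down-regulated DE genes by signed fold.

    Ranking is by fold_linear (descending for up, ascending for down) with
    ties broken by smaller p-value, then gene id.  Only ``is_de`` genes are
    eligible; a shortfall in either direction is an error.
    """
    if k <= 0:
        raise DataError("k must be positive")
    de = records.loc[records["is_de"]]
    up = de.loc[de["fold_linear"] > 0].sort_values(
        ["fold_linear", "p_value", "gene_id"], ascending=[False, True, True])
    down = de.loc[de["fold_linear"] < 0].sort_values(
        ["fold_linear", "p_value", "gene_id"], ascending=[True, True, True])
    if len(up) < k or len(down) < k:
        raise DataError(
            f"need {k} DE genes per direction but found {len(up)} up / {len(down)} down"
        )
    return up["gene_id"].head(k).tolist() + down["gene_id"].head(k).tolist()


def row_standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each gene row to mean 0, sd 1 (population divisor n)."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(f"zero-variance row(s): {list(values.index[zero])}")
    out = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _purity(assignment: np.ndarray, labels: np.ndarray) -> float:
    levels = np.unique(labels)
    agree = int(((assignment == 1) == (labels == levels[0])).sum())
    return max(agree, len(labels) - agree) / len(labels)


def hierarchical_cluster(
    standardized: pd.DataFrame,
    groups: pd.Series,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of genes and of samples, plus 2-cut purity.

    Deterministic given input order (scipy breaks distance ties by lowest
    merge index).  Purity cuts the sample tree into two clusters and scores
    the best-matched agreement with the true group labels.
    """
    if standardized.shape[0] < 2 or standardized.shape[1] < 2:
        raise DataError("clustering needs at least 2 genes and 2 samples")
    rows = standardized.to_numpy(dtype=float)
    row_linkage = hierarchy.linkage(pdist(rows, metric=metric), method=method)
    col_linkage = hierarchy.linkage(pdist(rows.T, metric=metric), method=method)
    gene_order = [standardized.index[i] for i in hierarchy.leaves_list(row_linkage)]
    sample_order = [standardized.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    two_cut = hierarchy.fcluster(col_linkage, t=2, criterion="maxclust")
    labels = groups.loc[standardized.columns].to_numpy()
    return ClusterResult(
        gene_order=gene_order,
        sample_order=sample_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        purity=_purity(two_cut, labels),
    )


def cluster_extreme_de(
    norm: NormalizedTable,
    records: pd.DataFrame,
    k: int = 20,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterResult:
    """Select the 2k most extreme DE genes, standardize rows and cluster."""
    genes = select_extreme_de(records, k=k)
    sub = norm.values.loc[genes]
    return hierarchical_cluster(row_standardize(sub), norm.groups,
                                method=method, metric=metric)


def plot_heatmap(standardized: pd.DataFrame, result: ClusterResult,
                 path: Optional[str] = None):  # pragma: no cover - optional artifact
    """Optional heatmap export (matplotlib); the tested surface is orders/purity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = standardized.loc[result.gene_order, result.sample_order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="bwr")
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels(ordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
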