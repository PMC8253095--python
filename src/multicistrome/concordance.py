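"""Cross-sample Pearson correlation matrices and complete-linkage
hierarchical clustering of the correlation structure.

Distance between samples is 1 - r. Labels are put in lexicographic order
before agglomeration, so the dendrogram is invariant to input column order
(the documented tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, diag 1; NaN rows/cols for degenerate columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    labels: list[str]  # lexicographic clustering order
    linkage: np.ndarray  # scipy linkage matrix (merge pairs + heights)
    leaf_order: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"


def correlation_matrix(m: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r between columns of an observations x samples frame.

    Zero-variance columns yield NaN correlations (missing, not 0).
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    values = m.to_numpy(dtype=float)
    std = values.std(axis=0)
    corr = np.corrcoef(values, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    degenerate = std == 0
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return CorrelationMatrix(labels=list(m.columns), values=corr)


def hierarchical_cluster(c: CorrelationMatrix) -> Dendrogram:
    """Complete-linkage agglomeration on distance d = 1 - r.

    Labels are clustered in lexicographic order (the deterministic tie-break);
    missing correlations among clustered labels are an error.
    """
    if len(c.labels) < 2:
        raise ValueError("need at least 2 labels to cluster")
    order = np.argsort(np.asarray(c.labels, dtype=object))
    labels = [c.labels[i] for i in order]
    values = c.values[np.ix_(order, order)]
    if np.isnan(values).any():
        raise ValueError("missing correlations; drop degenerate labels first")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2, 0.0)  # enforce exact symmetry
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    leaves = hierarchy.leaves_list(z)
    return Dendrogram(
        labels=labels,
        linkage=z,
        leaf_order=[labels[i] for i in leaves],
    )


def cut_clusters(d: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Flat cluster ids per label at a given cluster count."""
    assignments = hierarchy.fcluster(d.linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(d.labels, (int(a) for a in assignments)))
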