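"""Global expression structure: PCA and hierarchical clustering of samples.

Both operate on the variance-stabilized matrix.  PCA treats samples as
observations and genes as variables (column-centered covariance
eigendecomposition); clustering is average-linkage agglomeration on the
1 - Pearson correlation distance between sample expression profiles,
exported as a Newick tree.  In the paired desert/mesic design these
summaries show whether expression tracks phylogeny (pair structure) or
habitat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_fractions: np.ndarray  # non-increasing, sums to <= 1


def sample_pca(x: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of samples on variance-stabilized expression (genes x samples in)."""
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mat = x.to_numpy(dtype=float).T  # samples x genes
    keep = mat.var(axis=0) > 0
    mat = mat[:, keep]
    k = min(mat.shape) if n_components is None else min(n_components, min(mat.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(mat)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(pd.DataFrame(scores, index=x.columns, columns=cols),
                     pca.explained_variance_ratio_)


def correlation_distance(x: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample profiles; symmetric, zero diagonal."""
    mat = x.to_numpy(dtype=float)
    sds = mat.std(axis=0)
    if (sds == 0).any():
        bad = x.columns[sds == 0][0]
        raise ValueError(f"sample {bad!r} has constant expression; correlation distance undefined")
    d = 1.0 - np.corrcoef(mat.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return pd.DataFrame(d, index=x.columns, columns=x.columns)


def sample_cluster(x: pd.DataFrame, method: str = "average") -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of samples; returns (linkage matrix, labels)."""
    if x.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    d = correlation_distance(x)
    z = hierarchy.linkage(squareform(d.to_numpy(), checks=False), method=method)
    return z, list(x.columns)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist
        length = max(parent_height - height, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({walk(node.left, height)},{walk(node.right, height)}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cophenetic_groups(z: np.ndarray, labels: list[str], n_clusters: int) -> dict[str, int]:
    """Cut the tree into ``n_clusters`` flat clusters (label -> cluster id)."""
    assign = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assign)))
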