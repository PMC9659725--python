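"""Bivariate hierarchical clustering and PCA of differential proteins.

The differential-protein count matrix is row-centered (each protein's
mean across samples becomes 0, the above/below-average convention of the
heatmap display), then clustered with average linkage (UPGMA) on
Euclidean distances independently along rows (proteins) and columns
(samples).  PCA is run over samples using the centered protein
abundances as variables; per-group bivariate-normal summaries (mean and
2x2 covariance of the first two score dimensions) are returned for
density/ellipse rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from sklearn.decomposition import PCA

from .errors import StatsPreconditionError


def center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's mean; constant rows become all-zero."""
    arr = matrix.astype(float)
    return arr.sub(arr.mean(axis=1), axis=0)


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = rec(tree, tree.dist)
    # root branch length is meaningless; strip it
    return body.rsplit(":", 1)[0] + ";"


@dataclass
class LinkageResult:
    """Row and column merge trees from average-linkage biclustering."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    metric: str = "euclidean"
    method: str = "average"

    @property
    def row_order(self) -> list[str]:
        return [self.row_labels[i] for i in leaves_list(self.row_linkage)]

    @property
    def col_order(self) -> list[str]:
        return [self.col_labels[i] for i in leaves_list(self.col_linkage)]

    def to_newick(self, axis: str = "col") -> str:
        if axis == "row":
            return _linkage_to_newick(self.row_linkage, self.row_labels)
        if axis == "col":
            return _linkage_to_newick(self.col_linkage, self.col_labels)
        raise ValueError("axis must be 'row' or 'col'")

    def merge_table(self, axis: str = "col") -> pd.DataFrame:
        z = self.row_linkage if axis == "row" else self.col_linkage
        return pd.DataFrame(z, columns=["left", "right", "height", "size"])


def upgma_bicluster(matrix: pd.DataFrame) -> LinkageResult:
    """UPGMA agglomeration on Euclidean distances, rows and columns.

    SciPy's agglomeration breaks distance ties by lowest pair index,
    which makes the merge sequence deterministic.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise StatsPreconditionError("biclustering needs >= 2 rows and >= 2 columns")
    arr = matrix.to_numpy(float)
    return LinkageResult(
        row_linkage=linkage(arr, method="average", metric="euclidean"),
        col_linkage=linkage(arr.T, method="average", metric="euclidean"),
        row_labels=[str(i) for i in matrix.index],
        col_labels=[str(c) for c in matrix.columns],
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray
    group_means: dict[str, np.ndarray]  # group -> (PC1, PC2) mean
    group_covs: dict[str, np.ndarray]  # group -> 2x2 covariance
    center: np.ndarray | None = None  # per-protein mean removed before the SVD

    def simulate_group_density(self, group: str, n: int, seed: int = 0) -> np.ndarray:
        """Draws from the group's fitted bivariate normal in (PC1, PC2),
        for rendering score-plane densities."""
        rng = np.random.default_rng(seed)
        return rng.multivariate_normal(self.group_means[group], self.group_covs[group], size=n)


def pca_with_group_densities(
    matrix: pd.DataFrame,
    sample_groups: pd.Series,
    scale: bool = False,
) -> PcaResult:
    """PCA of samples in protein-abundance space with per-group
    bivariate-normal summaries of the first two score dimensions.

    Rows (proteins) are centered; ``scale=True`` additionally divides by
    the row SD.  The sign of each component is fixed so its
    largest-magnitude loading is positive.  Groups with a single sample
    get a zero covariance.
    """
    if matrix.shape[1] < 3:
        raise StatsPreconditionError("PCA needs >= 3 samples")
    if matrix.shape[0] < 2:
        raise StatsPreconditionError("PCA needs >= 2 proteins")
    centered = center_rows(matrix)
    if scale:
        sd = centered.std(axis=1, ddof=1).replace(0.0, 1.0)
        centered = centered.div(sd, axis=0)
    x = centered.to_numpy(float).T  # samples x proteins
    n_comp = min(x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # proteins x components
    for j in range(n_comp):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    scores_df = pd.DataFrame(scores, index=matrix.columns, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=matrix.index, columns=comp_names)

    labels = pd.Series(sample_groups).loc[matrix.columns]
    means, covs = {}, {}
    for g in sorted(labels.unique()):
        pts = scores_df.loc[labels[labels == g].index, ["PC1", "PC2"]].to_numpy()
        means[g] = pts.mean(axis=0)
        covs[g] = np.cov(pts.T, ddof=1) if pts.shape[0] > 1 else np.zeros((2, 2))
    return PcaResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        group_means=means,
        group_covs=covs,
        center=pca.mean_,
    )
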