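"""Heatmap-style hierarchical clustering: row scaling, Spearman distance,
complete linkage.

Rows (genes) are standardized to mean 0 / SD 1 (sample SD, n-1); both axes
are then clustered with complete linkage on ``1 - Spearman's rho``. The
agglomeration is written out explicitly so ties break deterministically on
the lexicographically smallest index pair; the merge table is emitted in
the standard linkage-matrix layout so tree utilities (leaf order, cluster
cuts) can be reused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


class ClusterError(ValueError):
    pass


@dataclass
class ScaledMatrix:
    values: pd.DataFrame
    row_means: pd.Series
    row_sds: pd.Series
    dropped: tuple[str, ...] = ()


def scale_rows(matrix: pd.DataFrame) -> ScaledMatrix:
    """Standardize each row to mean 0, SD 1 (n-1 denominator).

    Zero-variance rows cannot be scaled; they are dropped with a warning
    and listed in the result.
    """
    if matrix.shape[1] < 2:
        raise ClusterError("need >= 2 samples to scale rows")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    dropped = tuple(matrix.index[sds == 0.0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance row(s): "
            f"{list(dropped[:5])}", stacklevel=2,
        )
    keep = matrix.index[sds > 0.0]
    scaled = matrix.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    return ScaledMatrix(
        values=scaled, row_means=means[keep], row_sds=sds[keep],
        dropped=dropped,
    )


def spearman_distance(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Pairwise ``1 - Spearman's rho`` distances along rows or columns."""
    data = matrix if axis == "rows" else matrix.T
    if axis not in ("rows", "columns"):
        raise ClusterError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if data.shape[1] < 3:
        raise ClusterError("need >= 3 observations per vector")
    arr = data.to_numpy(dtype=float)
    sds = arr.std(axis=1)
    if (sds == 0).any():
        bad = data.index[sds == 0]
        raise ClusterError(
            f"zero-variance vector(s), distance undefined: {list(bad[:5])}"
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=data.index, columns=data.index)


@dataclass
class Dendrogram:
    """Merge tree in linkage-matrix form plus the input labels."""

    linkage: np.ndarray  # (n-1, 4): id_i, id_j, height, cluster size
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k clusters."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=list(self.labels), name="cluster")


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of a symmetric distance matrix.

    At each step the minimal-distance active pair is merged, ties broken by
    the lexicographically smallest (original-index) pair; the new cluster's
    distance to the rest is the pairwise maximum. Merge heights are
    non-decreasing (complete linkage is monotone).
    """
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ClusterError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ClusterError("distance matrix must be symmetric")
    n = arr.shape[0]
    if n < 2:
        raise ClusterError("need >= 2 items to cluster")
    d = arr.copy().astype(float)
    np.fill_diagonal(d, np.inf)
    active = list(range(n))          # positions into d
    cluster_id = list(range(n))      # linkage ids of active clusters
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = d[np.ix_(active, active)]
        iu = np.triu_indices(len(active), k=1)
        vals = sub[iu]
        # argmin returns the first minimum; triu_indices enumerates pairs
        # row-major, i.e. lexicographically — deterministic tie-break on
        # the smallest index pair (active preserves ascending input order)
        pos = int(np.argmin(vals))
        best = float(vals[pos])
        bi, bj = int(iu[0][pos]), int(iu[1][pos])
        pi, pj = active[bi], active[bj]
        id_i, id_j = cluster_id[bi], cluster_id[bj]
        new_id = n + step
        size = sizes[id_i] + sizes[id_j]
        merges[step] = [min(id_i, id_j), max(id_i, id_j), best, size]
        sizes[new_id] = size
        # complete linkage: distance to merged cluster = max
        d[pi, :] = np.maximum(d[pi, :], d[pj, :])
        d[:, pi] = d[pi, :]
        d[pi, pi] = np.inf
        del active[bj]
        del cluster_id[bj]
        cluster_id[bi] = new_id
    return Dendrogram(linkage=merges, labels=tuple(map(str, dist.index)))


def cluster_axes(
    matrix: pd.DataFrame,
) -> tuple[ScaledMatrix, Dendrogram, Dendrogram]:
    """Scale rows, then cluster genes (rows) and samples (columns).

    Spearman is computed on the scaled values for both axes; for the gene
    axis the row scaling is a per-row affine map and leaves Spearman
    unchanged.
    """
    scaled = scale_rows(matrix)
    gene_tree = complete_linkage(spearman_distance(scaled.values, "rows"))
    sample_tree = complete_linkage(
        spearman_distance(scaled.values, "columns")
    )
    return scaled, gene_tree, sample_tree


def cluster_purity(assignments: pd.Series, truth: pd.Series) -> float:
    """Fraction of items in the majority truth label of their cluster."""
    joined = pd.DataFrame({"cluster": assignments, "truth": truth}).dropna()
    correct = sum(
        grp["truth"].value_counts().iloc[0]
        for _, grp in joined.groupby("cluster")
    )
    return correct / len(joined)
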