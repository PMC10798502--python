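"""Genetic-divergence grouping of genotypes.

Mahalanobis D-squared distances between genotype trait-mean vectors scaled
by the inverse pooled within-genotype covariance, grouped either by
Tocher's threshold rule or by agglomerative (Ward / average) linkage.
Summary tables report intra- and inter-cluster mean distances, cluster
trait means and membership percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import TraitTable

__all__ = [
    "DistanceMatrix",
    "ClusterSolution",
    "trait_mean_matrix",
    "pooled_within_covariance",
    "mahalanobis_d2",
    "standardized_euclidean_d2",
    "cluster_genotypes",
    "tocher_cluster",
    "cluster_summary",
    "dendrogram_newick",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray          # squared distances, symmetric, zero diagonal
    metric: str = "mahalanobis_D2"

    def __post_init__(self) -> None:
        d = np.asarray(self.D, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0) or np.any(d < -1e-12):
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.D = np.clip(d, 0.0, None)

    def sqrt(self) -> "DistanceMatrix":
        """Distance-scale (D, not D^2) presentation of the same matrix."""
        return DistanceMatrix(self.labels, np.sqrt(self.D), metric=self.metric + "_sqrt")


@dataclass
class ClusterSolution:
    assignments: pd.Series        # genotype -> cluster id (1-based)
    method: str

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())

    def members(self, cluster: int) -> list[str]:
        return self.assignments.index[self.assignments == cluster].tolist()


def trait_mean_matrix(table: TraitTable, traits=None) -> pd.DataFrame:
    """Genotype x trait matrix of means over all environments and replicates."""
    traits = list(traits) if traits is not None else table.traits
    mat = table.data.pivot_table(index="genotype", columns="trait", values="value",
                                 aggfunc="mean")
    return mat.reindex(index=table.genotypes, columns=traits)


def pooled_within_covariance(table: TraitTable, traits=None) -> pd.DataFrame:
    """Trait covariance of replicate-level residuals within genotype x environment.

    Residuals are deviations of plot values from their genotype-environment
    cell mean, pooled over all cells; df = G * Y * (R - 1).
    """
    traits = list(traits) if traits is not None else table.traits
    wide = table.data.pivot_table(
        index=["genotype", "environment", "replicate"], columns="trait",
        values="value", aggfunc="first",
    )[traits]
    cellmeans = wide.groupby(level=["genotype", "environment"]).transform("mean")
    resid = (wide - cellmeans).to_numpy(float)
    n_cells = len(wide.groupby(level=["genotype", "environment"]))
    df = len(wide) - n_cells
    if df <= 0:
        raise ValueError("no replicate residual degrees of freedom")
    cov = resid.T @ resid / df
    return pd.DataFrame(cov, index=traits, columns=traits)


def _d2_from_precision(means: pd.DataFrame, prec: np.ndarray, metric: str) -> DistanceMatrix:
    x = means.to_numpy(float)
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, prec, diff)
    d2 = 0.5 * (d2 + d2.T)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(list(means.index), d2, metric=metric)


def mahalanobis_d2(means: pd.DataFrame, pooled_cov: pd.DataFrame) -> DistanceMatrix:
    """D2(i, j) = (x_i - x_j)' S^-1 (x_i - x_j) over genotype trait means."""
    cov = pooled_cov.loc[means.columns, means.columns].to_numpy(float)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        log.warning("pooled covariance singular; using pseudo-inverse")
        prec = np.linalg.pinv(cov)
    return _d2_from_precision(means, prec, "mahalanobis_D2")


def standardized_euclidean_d2(means: pd.DataFrame) -> DistanceMatrix:
    """Fallback when replicate-level residuals are unavailable: unit-variance
    scaling per trait (diagonal precision)."""
    log.warning("method downgrade: standardized Euclidean distance in use")
    var = means.var(axis=0, ddof=1).to_numpy(float)
    prec = np.diag(1.0 / var)
    return _d2_from_precision(means, prec, "standardized_euclidean")


def tocher_cluster(dm: DistanceMatrix) -> ClusterSolution:
    """Tocher's threshold grouping on the (squared) distance matrix.

    The admission threshold is the largest nearest-neighbour distance over
    all genotypes.  Each cluster is seeded with the closest remaining pair;
    the genotype with the smallest average distance to current members is
    admitted while the cluster's average within-pair distance stays at or
    below the threshold.  Ties break on input order.
    """
    d = dm.D
    n = len(dm.labels)
    if n == 1:
        return ClusterSolution(pd.Series([1], index=dm.labels), "tocher")
    offdiag = d + np.diag(np.full(n, np.inf))
    threshold = offdiag.min(axis=1).max()
    remaining = list(range(n))
    clusters: list[list[int]] = []
    while remaining:
        if len(remaining) == 1:
            clusters.append([remaining.pop()])
            break
        sub = offdiag[np.ix_(remaining, remaining)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        if i > j:
            i, j = j, i
        cluster = [remaining[i], remaining[j]]
        remaining = [x for x in remaining if x not in cluster]
        while remaining:
            avg_to_members = [
                (d[c, cluster].mean(), idx, c) for idx, c in enumerate(remaining)
            ]
            _, _, best = min(avg_to_members, key=lambda t: (t[0], t[1]))
            trial = cluster + [best]
            pairs = d[np.ix_(trial, trial)]
            m = len(trial)
            avg_within = pairs.sum() / (m * (m - 1))
            if avg_within <= threshold:
                cluster.append(best)
                remaining.remove(best)
            else:
                break
        clusters.append(cluster)
    assign = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters, start=1):
        assign[members] = cid
    return ClusterSolution(pd.Series(assign, index=dm.labels), "tocher")


def cluster_genotypes(
    dm: DistanceMatrix, method: str = "tocher", k: int | None = None
) -> ClusterSolution:
    """Group genotypes by Tocher's rule or agglomerative linkage cut to k."""
    if method == "tocher":
        return tocher_cluster(dm)
    if method not in ("ward", "average"):
        raise ValueError(f"unknown clustering method {method!r}")
    if k is None:
        k = 5
    if k > len(dm.labels):
        raise ValueError(f"k={k} exceeds number of genotypes {len(dm.labels)}")
    # linkage operates on the distance scale
    condensed = squareform(np.sqrt(dm.D), checks=False)
    z = hierarchy.linkage(condensed, method=method)
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return ClusterSolution(pd.Series(flat, index=dm.labels), method)


def linkage_tree(dm: DistanceMatrix, method: str = "ward") -> np.ndarray:
    condensed = squareform(np.sqrt(dm.D), checks=False)
    return hierarchy.linkage(condensed, method=method)


def dendrogram_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            name = labels[node.id].replace(" ", "_")
            return f"{name}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_summary(
    sol: ClusterSolution, dm: DistanceMatrix, means: pd.DataFrame,
    *, scale: str = "sqrt",
) -> dict:
    """Intra/inter distance table, cluster trait means, and membership shares.

    ``scale="sqrt"`` reports distances (D); ``scale="d2"`` reports squared
    distances.  Intra of a singleton cluster is 0 by convention.
    """
    if list(sol.assignments.index) != dm.labels:
        raise ValueError("solution labels do not match distance matrix labels")
    d = np.sqrt(dm.D) if scale == "sqrt" else dm.D
    ids = sorted(sol.assignments.unique())
    dist = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a_pos, a in enumerate(ids):
        ia = np.flatnonzero(sol.assignments.to_numpy() == a)
        if len(ia) > 1:
            sub = d[np.ix_(ia, ia)]
            intra = sub[np.triu_indices(len(ia), 1)].mean()
        else:
            intra = 0.0
        dist.loc[a, a] = intra
        for b in ids[a_pos + 1:]:
            ib = np.flatnonzero(sol.assignments.to_numpy() == b)
            inter = d[np.ix_(ia, ib)].mean()
            dist.loc[a, b] = dist.loc[b, a] = inter
    cmeans = (
        means.assign(_cluster=sol.assignments.to_numpy())
        .groupby("_cluster")
        .mean()
        .loc[ids]
    )
    sizes = sol.assignments.value_counts().loc[ids]
    membership = pd.DataFrame(
        {
            "cluster": ids,
            "n": sizes.to_numpy(),
            "percentage": 100.0 * sizes.to_numpy() / len(sol.assignments),
            "genotypes": [", ".join(sol.members(c)) for c in ids],
        }
    )
    return {"distances": dist, "cluster_means": cmeans, "membership": membership}
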