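"""Genetic-diversity clustering of family genotypic values.

Pairwise squared Mahalanobis distances d2(g1, g2) = (g1-g2)' S^-1 (g1-g2)
between posterior-mean genotypic-value vectors, Ward minimum-variance
agglomeration performed in whitened coordinates (so the fusion levels are
exact within-cluster SSE increases in the Mahalanobis metric), and the
Mojena stopping rule for the number of clusters.

The metric matrix S defaults to the residual covariance R0 — the
classical choice for generalized distances between genotype means — with
the genetic (G0) or phenotypic (G0+R0) covariance selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import solve_triangular

from halfsib.traits import as_cov_matrix


def _whiten(values: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Map points so that squared Euclidean distance equals Mahalanobis d2."""
    S = as_cov_matrix(S, "S")
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"S is numerically singular (condition number {cond:.3g})")
    L = np.linalg.cholesky(S)
    return solve_triangular(L, values.T, lower=True).T


def mahalanobis_matrix(gv: pd.DataFrame, S) -> pd.DataFrame:
    """Symmetric matrix of squared Mahalanobis distances between families.

    ``gv`` is families x traits (posterior-mean genotypic values); ``S``
    the positive-definite metric covariance.
    """
    X = _whiten(gv.to_numpy(dtype=float), S)
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return pd.DataFrame(d2, index=gv.index, columns=gv.index)


@dataclass
class Dendrogram:
    """Ward merge history.

    ``linkage`` is a scipy-format linkage matrix on whitened coordinates;
    ``fusion_levels[j]`` is the increase in total within-cluster SSE at
    merge j (the Mojena alpha_j).  Leaves 0..n-1 are ``families`` in
    order; internal node n+j is created by merge j.
    """

    families: tuple[str, ...]
    linkage: np.ndarray
    fusion_levels: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.families)

    def merge_members(self) -> list[tuple[frozenset, frozenset]]:
        """Member family-ID sets joined at each merge step."""
        sets: dict[int, frozenset] = {
            i: frozenset([f]) for i, f in enumerate(self.families)
        }
        out = []
        n = self.n_leaves
        for j, (a, b, *_rest) in enumerate(self.linkage):
            sa, sb = sets[int(a)], sets[int(b)]
            out.append((sa, sb))
            sets[n + j] = sa | sb
        return out


def ward_cluster(gv: pd.DataFrame, S) -> Dendrogram:
    """Ward's minimum-variance agglomeration in the Mahalanobis metric.

    The points are whitened by a Cholesky factor of S^-1 and clustered
    with Ward linkage; each fusion level is converted to the SSE
    increase of the merge (scipy's Ward height h satisfies
    h^2 = 2 * delta-SSE).
    """
    if len(gv) < 2:
        raise ValueError("need at least 2 families to cluster")
    X = _whiten(gv.to_numpy(dtype=float), S)
    Z = hierarchy.linkage(X, method="ward")
    levels = Z[:, 2] ** 2 / 2.0
    return Dendrogram(tuple(str(f) for f in gv.index), Z, levels)


@dataclass
class ClusterAssignment:
    """Partition of the families produced by a dendrogram cut."""

    labels: pd.Series           # family_id -> cluster label (1..k)
    k: int
    threshold: float

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_values(ascending=False)


def mojena_cut(dend: Dendrogram, omega: float = 1.25) -> ClusterAssignment:
    """Mojena stopping rule.

    With fusion levels alpha_1..alpha_{n-1} (agglomeration order), the
    threshold is mean(alpha) + omega * sd(alpha) (sample sd, n-1
    divisor).  The dendrogram is cut immediately before the first merge
    whose level exceeds the threshold, giving k = n - j + 1 clusters for
    first exceedance at step j; if no level exceeds it, k = 1.
    """
    alpha = np.asarray(dend.fusion_levels, dtype=float)
    if alpha.size < 1:
        raise ValueError("dendrogram has no merges")
    mean = alpha.mean()
    sd = alpha.std(ddof=1) if alpha.size > 1 else 0.0
    threshold = mean + omega * sd
    exceed = np.nonzero(alpha > threshold)[0]
    n = dend.n_leaves
    if exceed.size == 0:
        k = 1
    else:
        j = int(exceed[0]) + 1          # first exceedance, 1-based step
        k = n - j + 1
    flat = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=pd.Index(dend.families, name="family_id"), name="cluster")
    return ClusterAssignment(labels=labels, k=int(labels.nunique()), threshold=float(threshold))


def merge_table(dend: Dendrogram) -> pd.DataFrame:
    """Delimited-friendly merge history: step, joined member sets, level."""
    rows = []
    for j, (sa, sb) in enumerate(dend.merge_members(), start=1):
        rows.append(
            {
                "step": j,
                "members_a": ";".join(sorted(sa)),
                "members_b": ";".join(sorted(sb)),
                "fusion_level": dend.fusion_levels[j - 1],
            }
        )
    return pd.DataFrame(rows)


def to_newick(dend: Dendrogram) -> str:
    """Newick export with branch lengths = parent fusion level minus child
    fusion level (leaves sit at height 0)."""
    n = dend.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for j, (a, b, *_rest) in enumerate(dend.linkage):
        node = n + j
        children[node] = (int(a), int(b))
        heights[node] = float(dend.fusion_levels[j])

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < n:
            return f"{dend.families[node]}:{bl:.6g}"
        a, b = children[node]
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

    root = n + len(children) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
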