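"""Repertoire diversity statistics and between-sample comparisons.

Alpha diversity is the Shannon entropy (natural log) of the cluster
abundance distribution.  Richness is the bias-corrected Chao1 estimate
from singleton/doubleton counts.  Sample coverage is Good's criterion
1 - n1/N.  Beta diversity is a pairwise dissimilarity matrix
(Bray-Curtis on counts by default, Jaccard on presence/absence as a
companion) summarised by a UPGMA dendrogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

SUPPORTED_BETA_METRICS = ("braycurtis", "jaccard")


@dataclass
class AbundanceVector:
    """Per-cluster read counts of one sample."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("abundance counts must be >= 1")

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def n1(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def S_obs(self) -> int:
        return len(self.counts)


def shannon(v: AbundanceVector) -> float:
    """Shannon entropy in nats: -sum p_i ln p_i."""
    if not v.counts:
        raise ValueError("empty abundance vector")
    n = v.N
    return float(-sum((c / n) * math.log(c / n) for c in v.counts.values()))


def chao1(v: AbundanceVector) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1))."""
    if not v.counts:
        raise ValueError("empty abundance vector")
    f1 = sum(1 for c in v.counts.values() if c == 1)
    f2 = sum(1 for c in v.counts.values() if c == 2)
    return v.S_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def goods_coverage(v: AbundanceVector) -> float:
    """Good's criterion 1 - n1/N, the estimated repertoire coverage."""
    if not v.counts:
        raise ValueError("empty abundance vector")
    return 1.0 - v.n1 / v.N


def sample_stats(vectors: Sequence[AbundanceVector]) -> pd.DataFrame:
    """Per-sample summary table: N, clusters, Shannon, Chao1, coverage."""
    rows = [
        {
            "sample_id": v.sample_id,
            "N": v.N,
            "clusters": v.S_obs,
            "shannon": shannon(v),
            "chao1": chao1(v),
            "goods_coverage": goods_coverage(v),
        }
        for v in vectors
    ]
    return pd.DataFrame(rows)


def _count_matrix(vectors: Sequence[AbundanceVector]) -> pd.DataFrame:
    ids = sorted({cid for v in vectors for cid in v.counts})
    mat = pd.DataFrame(0, index=[v.sample_id for v in vectors], columns=ids, dtype=float)
    for v in vectors:
        for cid, c in v.counts.items():
            mat.loc[v.sample_id, cid] = c
    return mat


def beta_matrix(
    vectors: Sequence[AbundanceVector], metric: str = "braycurtis"
) -> tuple[pd.DataFrame, str]:
    """Pairwise dissimilarity matrix and UPGMA dendrogram (Newick).

    Cluster identifiers must already be matched across samples (shared
    clusters carry the same id).  ``metric`` is one of
    ``braycurtis`` (counts) or ``jaccard`` (presence/absence).
    """
    if len(vectors) < 2:
        raise ValueError("beta diversity needs at least two samples")
    if metric not in SUPPORTED_BETA_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {', '.join(SUPPORTED_BETA_METRICS)}"
        )
    mat = _count_matrix(vectors)
    data = mat.values
    if metric == "jaccard":
        data = (data > 0).astype(float)
    cond = pdist(data, metric=metric)
    dm = pd.DataFrame(squareform(cond), index=mat.index, columns=mat.index)
    link = hierarchy.linkage(cond, method="average")
    tree = hierarchy.to_tree(link)
    newick = _to_newick(tree, list(mat.index), tree.dist) + ";"
    return dm, newick


def _to_newick(node, labels: list[str], parent_height: float) -> str:
    """Newick text with ultrametric branch lengths from UPGMA merge heights."""
    blen = f"{parent_height - node.dist:.6g}"
    if node.is_leaf():
        return f"{labels[node.id]}:{blen}"
    left = _to_newick(node.get_left(), labels, node.dist)
    right = _to_newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{blen}"


def shared_abundance_correlation(
    a: AbundanceVector, b: AbundanceVector, min_shared: int = 3
) -> dict:
    """Pearson correlation of abundances of clusters shared by two samples.

    Computed on log10 counts (cluster sizes span orders of magnitude);
    the linear-scale coefficient is reported alongside.  Fewer than
    ``min_shared`` shared clusters -> both values NaN.
    """
    shared = sorted(set(a.counts) & set(b.counts))
    if len(shared) < min_shared:
        return {"n_shared": len(shared), "pearson_log10": float("nan"),
                "pearson_linear": float("nan")}
    xa = np.array([a.counts[c] for c in shared], dtype=float)
    xb = np.array([b.counts[c] for c in shared], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_log = sps.pearsonr(np.log10(xa), np.log10(xb)).statistic
        r_lin = sps.pearsonr(xa, xb).statistic
    return {
        "n_shared": len(shared),
        "pearson_log10": float(r_log),
        "pearson_linear": float(r_lin),
    }


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (probability-mass rule).

    A zero margin makes the test degenerate; p = 1 is returned with a
    warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)
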