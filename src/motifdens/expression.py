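"""Expression space: distances, k-neighbor graphs, hubness balancing, k-means.

The neighborhood pipeline has three stages.  The raw kNN digraph puts an arc
g -> g' when g' is among the k nearest profiles of g.  In high-dimensional
expression data its in-degree distribution is strongly skewed (hubness): a
few genes sit in very many neighborhoods while others sit in almost none,
which biases any density estimate built on the neighborhoods.  Symmetrizing
the graph guarantees every gene belongs to at least k neighborhoods, and a
balanced stage then resamples exactly k neighbors per gene from the
symmetrized neighborhood with probability inversely proportional to each
candidate's symmetrized in-degree, flattening the in-degree distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Pearson distance is undefined for flat profiles; carries the genes."""

    def __init__(self, gene_ids: list[str]):
        self.gene_ids = gene_ids
        super().__init__(f"zero-variance expression profiles: {gene_ids[:10]}"
                         + ("..." if len(gene_ids) > 10 else ""))


@dataclass
class ExpressionMatrix:
    """n genes x p conditions of real expression values."""

    gene_ids: list[str]
    values: np.ndarray
    condition_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError("values must be (n_genes, n_conditions)")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")
        if self.condition_names is None:
            self.condition_names = [f"c{i}" for i in range(self.values.shape[1])]

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path, drop_missing: bool = True) -> "ExpressionMatrix":
        """Load a TSV with a condition-name header and gene IDs in column 1.

        Rows with any missing value are dropped (count logged); set
        ``drop_missing=False`` to fail instead.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.isna().any(axis=1)
        if bad.any():
            if not drop_missing:
                raise ValueError(f"{int(bad.sum())} genes have missing values")
            log.warning("dropping %d genes with missing expression values", int(bad.sum()))
            df = df.loc[~bad]
        return cls(list(df.index.astype(str)), df.to_numpy(float), list(df.columns.astype(str)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids,
                     columns=self.condition_names).to_csv(path, sep="\t",
                                                          index_label="gene")

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.values[idx], self.condition_names)


def pairwise_distance(X: ExpressionMatrix, metric: str = "euclidean") -> np.ndarray:
    """Symmetric n x n distances: L2, or 1 - Pearson correlation, between rows."""
    if metric == "euclidean":
        return squareform(pdist(X.values, metric="euclidean"))
    if metric == "pearson":
        sd = X.values.std(axis=1)
        flat = [g for g, s in zip(X.gene_ids, sd) if s == 0]
        if flat:
            raise ZeroVarianceError(flat)
        D = 1.0 - np.corrcoef(X.values)
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class NeighborGraph:
    """Directed neighbor graph over genes at one of the three stages."""

    gene_ids: list[str]
    neighbors: list[np.ndarray]  # per-gene ordered neighbor indices
    k: int
    stage: str  # 'knn' | 'symmetrized' | 'balanced'

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def in_degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=np.int64)
        for nb in self.neighbors:
            np.add.at(d, nb, 1)
        return d

    def out_degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    def arc_set(self) -> set[tuple[int, int]]:
        return {(g, int(h)) for g, nb in enumerate(self.neighbors) for h in nb}

    def to_dense(self, dtype=np.float32) -> np.ndarray:
        """Row-stochastic-free 0/1 adjacency, rows = genes, cols = neighbors."""
        A = np.zeros((self.n, self.n), dtype=dtype)
        for g, nb in enumerate(self.neighbors):
            A[g, nb] = 1
        return A

    def to_edgelist_tsv(self, path) -> None:
        rows = [(self.gene_ids[g], self.gene_ids[int(h)])
                for g, nb in enumerate(self.neighbors) for h in nb]
        pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


def knn_graph(X: ExpressionMatrix, k: int, metric: str = "euclidean",
              distances: np.ndarray | None = None) -> NeighborGraph:
    """k nearest neighbors per gene; a gene is never its own neighbor.

    Distance ties are broken by gene input order (stable sort), so the graph
    is deterministic.
    """
    n = X.n
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    D = pairwise_distance(X, metric) if distances is None else distances
    order = np.argsort(D, axis=1, kind="stable")
    neighbors = []
    for g in range(n):
        row = order[g]
        neighbors.append(row[row != g][:k].astype(np.int64))
    return NeighborGraph(list(X.gene_ids), neighbors, k, "knn")


def symmetrize(g: NeighborGraph) -> NeighborGraph:
    """Close the arc set under reversal (stage knn -> symmetrized)."""
    if g.stage != "knn":
        raise ValueError("symmetrize expects a knn-stage graph")
    src = np.concatenate([np.full(len(nb), i, dtype=np.int64)
                          for i, nb in enumerate(g.neighbors)])
    dst = np.concatenate(g.neighbors)
    arcs = np.unique(np.concatenate(
        [np.stack([src, dst], 1), np.stack([dst, src], 1)]), axis=0)
    lo = np.searchsorted(arcs[:, 0], np.arange(g.n), side="left")
    hi = np.searchsorted(arcs[:, 0], np.arange(g.n), side="right")
    neighbors = [arcs[a:b, 1] for a, b in zip(lo, hi)]
    return NeighborGraph(list(g.gene_ids), neighbors, g.k, "symmetrized")


def balanced_neighbor_sample(gstar: NeighborGraph, k: int | None = None,
                             seed: int = 0) -> NeighborGraph:
    """Sample exactly k neighbors per gene inversely to symmetrized in-degree.

    For each gene, k neighbors are drawn sequentially without replacement
    from its symmetrized neighborhood with P(g') proportional to 1/d(g')
    renormalized over the not-yet-chosen candidates, d(g') being the fixed
    in-degree of g' in the symmetrized graph.  Implemented by exponential
    keys (draw E ~ Exp(1) per candidate, keep the k smallest E/w), which
    yields exactly that sequential distribution.  Genes are processed in
    input order under a single seeded generator, so the result is
    reproducible.
    """
    if gstar.stage != "symmetrized":
        raise ValueError("balanced sampling expects a symmetrized graph")
    k = gstar.k if k is None else k
    d = gstar.in_degrees().astype(float)
    rng = np.random.default_rng(seed)
    neighbors = []
    for g, cand in enumerate(gstar.neighbors):
        if len(cand) <= k:
            if len(cand) < k:
                log.warning("gene %s has only %d symmetrized neighbors (< k=%d)",
                            gstar.gene_ids[g], len(cand), k)
            neighbors.append(cand.copy())
            continue
        w = 1.0 / d[cand]
        keys = rng.exponential(size=len(cand)) / w
        take = np.argsort(keys, kind="stable")[:k]
        neighbors.append(cand[take])
    return NeighborGraph(list(gstar.gene_ids), neighbors, k, "balanced")


def build_neighbor_graph(X: ExpressionMatrix, k: int, metric: str = "euclidean",
                         seed: int = 0,
                         distances: np.ndarray | None = None) -> NeighborGraph:
    """Convenience: knn -> symmetrize -> balanced sample in one call."""
    return balanced_neighbor_sample(symmetrize(knn_graph(X, k, metric, distances)),
                                    k, seed)


@dataclass
class Partition:
    """Hard clustering of the gene universe (the discrete baselines)."""

    labels: np.ndarray
    k_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min() < 0 or self.labels.max() >= self.k_clusters:
            raise ValueError("labels out of range")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k_clusters)

    def indicator(self, dtype=np.float32) -> np.ndarray:
        B = np.zeros((self.k_clusters, len(self.labels)), dtype=dtype)
        B[self.labels, np.arange(len(self.labels))] = 1
        return B


def kmeans_partition(X: ExpressionMatrix, k_clusters: int, restarts: int = 100,
                     seed: int = 0) -> Partition:
    """Best-of-``restarts`` Lloyd k-means on Euclidean distance."""
    if k_clusters >= X.n:
        if k_clusters > X.n:
            raise ValueError("k_clusters > n")
        return Partition(np.arange(X.n), k_clusters)
    km = KMeans(n_clusters=k_clusters, n_init=restarts, init="random",
                algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(X.values)
    return Partition(labels, k_clusters)
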