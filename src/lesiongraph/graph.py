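"""Image-to-image graph construction.

Every image is a node carrying its ten-feature vector; every unordered pair
of nodes gets an edge weighted by the Spearman rank correlation of the two
feature rows.  Edges can then be filtered by a lower-bound threshold on the
correlation, and the surviving edge set materialized as a binary adjacency
matrix for the GNN.

Spearman is computed as Pearson correlation of average ranks — the general
definition, which reduces to the classical 1 - 6*sum(d^2)/(n(n^2-1)) formula
when there are no ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

DENSE_ADJACENCY_MAX_NODES = 2000
EXACT_ONE_TOL = 1e-12


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeTable:
    """Unordered edges (source < target) with Spearman weights."""

    source: np.ndarray   # int
    target: np.ndarray   # int
    weight: np.ndarray   # float in [-1, 1]
    n_nodes: int

    def __len__(self) -> int:
        return int(self.source.size)

    def to_frame(self, one_based: bool = False) -> pd.DataFrame:
        off = 1 if one_based else 0
        return pd.DataFrame({"Source": self.source + off,
                             "Target": self.target + off,
                             "Correlation": self.weight})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_nodes: int,
                   one_based: bool = False) -> "EdgeTable":
        off = 1 if one_based else 0
        return cls(df["Source"].to_numpy(dtype=int) - off,
                   df["Target"].to_numpy(dtype=int) - off,
                   df["Correlation"].to_numpy(dtype=float), n_nodes)


@dataclass(frozen=True)
class Graph:
    """Node features X (n x 10), labels (n), edges and binary adjacency."""

    X: np.ndarray
    labels: np.ndarray
    edges: EdgeTable
    adjacency: object  # dense ndarray or scipy.sparse matrix

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]


def spearman(u, v) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Average ranks for ties; raises for constant input, where the
    correlation is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("need two equal-length 1-D vectors with n >= 2")
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("values must be finite")
    ru = rankdata(u)
    rv = rankdata(v)
    if ru.std() == 0 or rv.std() == 0:
        raise UndefinedCorrelationError("constant vector: all ranks tied")
    ru = ru - ru.mean()
    rv = rv - rv.mean()
    return float((ru @ rv) / np.sqrt((ru @ ru) * (rv @ rv)))


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return rankdata(X, axis=1)


def build_edge_table(table: pd.DataFrame | np.ndarray,
                     feature_columns=None) -> EdgeTable:
    """All-pairs Spearman edges over the rows of a feature table.

    Accepts either the feature DataFrame (id/features/label columns) or a
    bare (n x p) array of feature rows.  One edge per unordered pair,
    ordered by (source, target) ascending; n(n-1)/2 edges in total.
    """
    if isinstance(table, pd.DataFrame):
        if feature_columns is None:
            feature_columns = [c for c in table.columns if c not in ("id", "label")]
        X = table[feature_columns].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    R = _rank_rows(X)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=1))
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise UndefinedCorrelationError(
            f"row(s) {bad.tolist()} have all-tied features; correlation undefined")
    Rn = R / norms[:, None]
    C = np.clip(Rn @ Rn.T, -1.0, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    return EdgeTable(iu.astype(np.int64), ju.astype(np.int64), C[iu, ju], n)


def threshold_edges(edges: EdgeTable, tau: float | None) -> EdgeTable:
    """Keep edges with weight >= tau; tau=None keeps all.

    tau = 1.0 is treated as exact equality (within 1e-12), matching a
    "correlation exactly 1" selection rather than a >= bound.
    """
    if tau is None:
        return edges
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [-1, 1], got {tau}")
    if tau == 1.0:
        keep = np.abs(edges.weight - 1.0) <= EXACT_ONE_TOL
    else:
        keep = edges.weight >= tau
    return EdgeTable(edges.source[keep], edges.target[keep],
                     edges.weight[keep], edges.n_nodes)


def to_adjacency(edges: EdgeTable, dense_max_nodes: int = DENSE_ADJACENCY_MAX_NODES):
    """Symmetric binary adjacency with zero diagonal.

    Dense ndarray for graphs up to ``dense_max_nodes`` nodes, CSR beyond;
    identical semantics either way.
    """
    n = edges.n_nodes
    s, t = edges.source, edges.target
    if len(edges) and (s.min() < 0 or t.max() >= n or s.max() >= n or t.min() < 0):
        raise IndexError("edge endpoint outside [0, n)")
    if n <= dense_max_nodes:
        A = np.zeros((n, n), dtype=np.float64)
        A[s, t] = 1.0
        A[t, s] = 1.0
        np.fill_diagonal(A, 0.0)
        return A
    data = np.ones(2 * len(edges))
    A = sparse.coo_matrix(
        (data, (np.concatenate([s, t]), np.concatenate([t, s]))), shape=(n, n))
    A = A.tocsr()
    A.data[:] = 1.0
    A.setdiag(0.0)
    A.eliminate_zeros()
    return A


def build_graph(table: pd.DataFrame, tau: float | None = None,
                feature_columns=None) -> Graph:
    """Feature table -> (thresholded) graph with adjacency."""
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c not in ("id", "label")]
    edges = threshold_edges(build_edge_table(table, feature_columns), tau)
    return Graph(
        X=table[feature_columns].to_numpy(dtype=float),
        labels=table["label"].to_numpy(dtype=int),
        edges=edges,
        adjacency=to_adjacency(edges),
    )
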