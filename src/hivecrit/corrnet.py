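"""Pearson correlation networks from node time-series.

Nodes are lattice sites of an Ising run or individual animals; each node
carries a time-series (spins, or kinetic energy).  The sample Pearson
coefficient

    r(x, y) = E[(x - mu_x)(y - mu_y)] / (sigma_x sigma_y)

is computed for every pair, and an undirected simple graph is obtained by
connecting pairs with r_ij > p for a threshold p.  Because networks from
different systems are only comparable at similar density, the threshold is
chosen to hit a target mean degree <k> rather than fixed a priori.

Zero-variance series (frozen lattice sites, motionless individuals) have an
undefined Pearson coefficient; their correlations are defined as 0 here and
the nodes are flagged in ``CorrelationMatrix.zero_variance_nodes`` so that
downstream reports can count them.  Such nodes become isolated for any p >= 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "CorrelationMatrix",
    "ThresholdScan",
    "ThresholdChoice",
    "BinaryNetwork",
    "pearson_matrix",
    "scan_thresholds",
    "choose_threshold",
    "build_network",
]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Pearson coefficients with unit diagonal."""

    r: np.ndarray
    node_ids: list
    zero_variance_nodes: frozenset = frozenset()

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle off-diagonal correlations, sorted ascending."""
        iu = np.triu(np.ones(self.r.shape, dtype=bool), k=1)
        vals = np.sort(self.r[iu])
        return vals

    def save(self, path: str | Path) -> None:
        """Binary array container plus a JSON node-id manifest alongside."""
        path = Path(path)
        np.save(path, self.r)
        manifest = {
            "node_ids": [str(i) for i in self.node_ids],
            "zero_variance_nodes": sorted(int(i) for i in self.zero_variance_nodes),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest))


@dataclass
class ThresholdScan:
    thresholds: np.ndarray
    mean_degrees: np.ndarray


class ThresholdChoice(NamedTuple):
    p: float
    k_mean: float


@dataclass
class BinaryNetwork:
    """Undirected simple graph from thresholding; isolated nodes retained."""

    n: int
    node_ids: list
    edges: np.ndarray  # (E, 2) int, each row i < j
    threshold_used: float = np.nan

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size and (
            (self.edges[:, 0] == self.edges[:, 1]).any()
            or self.edges.min() < 0
            or self.edges.max() >= self.n
        ):
            raise ValueError("edges must join distinct nodes within range")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n if self.n else 0.0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        nx.set_node_attributes(g, {i: str(self.node_ids[i]) for i in range(self.n)}, "label")
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, threshold: float = np.nan) -> "BinaryNetwork":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        edges = np.array([[index[u], index[v]] for u, v in g.edges() if u != v], dtype=np.int64)
        edges = edges.reshape(-1, 2)
        edges.sort(axis=1)
        return cls(n=len(nodes), node_ids=list(nodes), edges=edges, threshold_used=threshold)

    def save_edgelist(self, path: str | Path) -> None:
        """TAB-separated edge list plus a sidecar node list (isolated nodes kept)."""
        path = Path(path)
        with open(path, "w") as fh:
            for i, j in self.edges:
                fh.write(f"{self.node_ids[i]}\t{self.node_ids[j]}\n")
        nodes_path = path.with_suffix(path.suffix + ".nodes")
        nodes_path.write_text("\n".join(str(v) for v in self.node_ids) + "\n")

    def save_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def pearson_matrix(
    series: np.ndarray,
    node_ids: Sequence | None = None,
    dtype=np.float32,
) -> CorrelationMatrix:
    """Pairwise sample Pearson coefficients between the rows of ``series``.

    Parameters
    ----------
    series : array (n_nodes, n_samples)
        One time-series per node; at least 2 nodes and 3 samples.
    node_ids : optional sequence of identifiers, default 0..n-1.
    dtype : floating dtype of the output matrix.  float32 halves memory and
        matrix-multiply time for the 10^4-node case with ~1e-6 precision,
        ample for thresholding.

    Zero-variance rows get correlation 0 with everything and are flagged.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("series must be 2D (n_nodes, n_samples)")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 node series")
    if m < 3:
        raise ValueError("need at least 3 samples per series")
    if node_ids is None:
        node_ids = list(range(n))
    elif len(node_ids) != n:
        raise ValueError("node_ids length mismatch")

    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    ss = np.einsum("ij,ij->i", xc, xc)
    zero_var = ss <= 0.0
    norm = np.sqrt(np.where(zero_var, 1.0, ss))
    z = np.asarray(xc / norm[:, None], dtype=dtype)
    r = z @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        r=r,
        node_ids=list(node_ids),
        zero_variance_nodes=frozenset(np.flatnonzero(zero_var).tolist()),
    )


def _mean_degree_at(sorted_vals: np.ndarray, p: float, n: int) -> float:
    # number of upper-triangle entries strictly greater than p
    count = sorted_vals.size - np.searchsorted(sorted_vals, p, side="right")
    return 2.0 * count / n


def scan_thresholds(corr: CorrelationMatrix, thresholds: Sequence[float]) -> ThresholdScan:
    """Mean degree of the r > p graph for each threshold, without building graphs."""
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size > 1 and not np.all(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be strictly increasing")
    vals = corr.offdiag_values()
    ks = np.array([_mean_degree_at(vals, p, corr.n) for p in thresholds])
    return ThresholdScan(thresholds=thresholds, mean_degrees=ks)


def choose_threshold(
    corr: CorrelationMatrix,
    target_k: float,
    tol: float | None = None,
) -> ThresholdChoice:
    """Threshold p whose r > p graph has mean degree closest to ``target_k``.

    Bisection on p against the (monotone, step-wise) mean-degree curve; when
    the discrete edge structure cannot reach ``tol`` (default 1% of
    target_k), the closest achievable threshold is returned.  The achieved
    mean degree is always reported alongside p.
    """
    n = corr.n
    if not (0 <= target_k <= n - 1):
        raise ValueError(f"target mean degree {target_k} unachievable for n={n}")
    if tol is None:
        tol = 0.01 * max(target_k, 1.0)
    vals = corr.offdiag_values()

    lo, hi = -1.0 - 1e-9, 1.0
    # bisection: mean degree is non-increasing in p
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        k = _mean_degree_at(vals, mid, n)
        if abs(k - target_k) <= tol:
            return ThresholdChoice(p=float(mid), k_mean=float(k))
        if k > target_k:
            lo = mid
        else:
            hi = mid
    # discrete structure cannot reach tol: pick the order statistic whose
    # edge count is closest to the target
    m_target = target_k * n / 2.0
    count = int(np.clip(round(m_target), 0, vals.size))
    # thresholds realizing "count" edges lie between vals[-count-1] and vals[-count]
    for c in (count, count - 1, count + 1):
        if not (0 <= c <= vals.size):
            continue
        upper = vals[vals.size - c] if c >= 1 else 1.0
        lower = vals[vals.size - c - 1] if c < vals.size else -1.0 - 1e-9
        if lower < upper:
            p = 0.5 * (lower + upper)
            return ThresholdChoice(p=float(p), k_mean=_mean_degree_at(vals, p, n))
    # ties everywhere: fall back to the closest achievable point on the curve
    candidates = np.unique(vals)
    best = min(candidates, key=lambda p: abs(_mean_degree_at(vals, p, n) - target_k))
    return ThresholdChoice(p=float(best), k_mean=_mean_degree_at(vals, best, n))


def build_network(corr: CorrelationMatrix, p: float) -> BinaryNetwork:
    """Undirected graph connecting pairs with r_ij > p (strict); isolated nodes kept."""
    mask = np.triu(corr.r > p, k=1)
    edges = np.argwhere(mask)
    return BinaryNetwork(
        n=corr.n,
        node_ids=list(corr.node_ids),
        edges=edges,
        threshold_used=float(p),
    )
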