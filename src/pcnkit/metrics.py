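"""Residue-level network metrics, implemented from first principles.

Degree, Watts-Strogatz clustering coefficient, Brandes betweenness
centrality, per-component closeness, BFS all-pairs shortest paths, and
z-score outlier selection.  These are the quantities whose residue-wise
differences between a reference and its mutants carry the signal in a
contact-network comparison, so they are implemented here directly (and
cross-validated against an independent graph library in the test suite
only).

All per-residue outputs are pandas Series indexed by author residue number.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ContactNetwork

__all__ = ["degree", "clustering_coefficient", "betweenness", "closeness",
           "shortest_paths", "zscore_select", "ZScoreSelection", "metric_table",
           "global_summary"]


def _index(network: ContactNetwork) -> pd.Index:
    return pd.Index(network.structure.author_numbers, name="residue")


def degree(network: ContactNetwork) -> pd.Series:
    """Number of contacts of each residue (adjacency row sums)."""
    return pd.Series(network.adjacency.sum(axis=1).astype(int),
                     index=_index(network), name="degree")


def clustering_coefficient(network: ContactNetwork) -> pd.Series:
    """C_i = 2 e_i / (k_i (k_i - 1)), zero for nodes of degree < 2.

    e_i counts edges among the neighbours of i ("cliquishness" of the
    neighbourhood).
    """
    a = network.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    # e_i = half the number of ordered neighbour pairs that are connected
    e = np.einsum("ij,jk,ki->i", a, a, a) / 2.0  # closed triangles through i
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * e / (k * (k - 1.0)), 0.0)
    return pd.Series(c, index=_index(network), name="clustering")


def _bfs(adj_lists: list[list[int]], s: int) -> tuple[list[int], list[list[int]],
                                                      list[float], list[int]]:
    """Brandes-style BFS from s: order of settlement, predecessor lists,
    path counts sigma, distances (-1 = unreachable)."""
    n = len(adj_lists)
    dist = [-1] * n
    sigma = [0.0] * n
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[s] = 0
    sigma[s] = 1.0
    order: list[int] = []
    q = deque([s])
    while q:
        v = q.popleft()
        order.append(v)
        for w in adj_lists[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, preds, sigma, dist


def _adj_lists(network: ContactNetwork) -> list[list[int]]:
    a = network.adjacency
    return [list(np.nonzero(a[i])[0]) for i in range(a.shape[0])]


def betweenness(network: ContactNetwork, normalized: bool = False) -> pd.Series:
    """Betweenness centrality via Brandes' accumulation.

    BC_i sums, over unordered node pairs (s, t) with s != i != t, the
    fraction of shortest s-t paths that pass through i.  The normalised
    variant divides by (n-1)(n-2)/2, the number of such pairs.
    """
    adj = _adj_lists(network)
    n = len(adj)
    bc = np.zeros(n)
    for s in range(n):
        order, preds, sigma, _ = _bfs(adj, s)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair was counted from both endpoints
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0
        bc = bc / denom if denom > 0 else np.zeros(n)
    return pd.Series(bc, index=_index(network), name="betweenness")


def closeness(network: ContactNetwork) -> pd.Series:
    """Per-component closeness: n_reachable / sum of hop distances.

    Within the connected component of i this equals (|C|-1) / sum_t d(i,t);
    isolated nodes score 0.
    """
    adj = _adj_lists(network)
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        _, _, _, dist = _bfs(adj, i)
        reach = [d for d in dist if d > 0]
        if reach:
            out[i] = len(reach) / sum(reach)
    return pd.Series(out, index=_index(network), name="closeness")


def shortest_paths(network: ContactNetwork) -> np.ndarray:
    """All-pairs hop-distance matrix (positional indexing).

    Unreachable pairs are ``inf``; the diagonal is zero.
    """
    adj = _adj_lists(network)
    n = len(adj)
    m = np.full((n, n), np.inf)
    for i in range(n):
        _, _, _, dist = _bfs(adj, i)
        for j, d in enumerate(dist):
            if d >= 0:
                m[i, j] = d
    return m


def eccentricity(network: ContactNetwork) -> pd.Series:
    """Maximum finite hop distance from each residue."""
    sp = shortest_paths(network)
    finite = np.where(np.isfinite(sp), sp, 0.0)
    return pd.Series(finite.max(axis=1).astype(int), index=_index(network),
                     name="eccentricity")


@dataclass(frozen=True)
class ZScoreSelection:
    metric: str
    threshold: float
    zscores: pd.Series  # full series, indexed like the input
    selected: pd.Series  # z-scores of the residues with z > threshold


def zscore_select(values: pd.Series, threshold: float,
                  metric: str = "") -> ZScoreSelection:
    """Standardise ``values`` within the structure and select z > threshold.

    Population standard deviation is used (standardisation within one
    network's residue population).  A constant series yields an empty
    selection with a warning rather than an error.
    """
    if len(values) < 2:
        raise ValueError("need at least two values for z-scores")
    x = values.astype(float)
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        warnings.warn(f"constant {metric or 'metric'} series: empty z-score selection")
        z = pd.Series(np.zeros(len(x)), index=x.index)
        return ZScoreSelection(metric=metric, threshold=threshold, zscores=z,
                               selected=z.iloc[0:0])
    z = (x - x.mean()) / sd
    return ZScoreSelection(metric=metric, threshold=threshold, zscores=z,
                           selected=z[z > threshold])


def metric_table(network: ContactNetwork) -> pd.DataFrame:
    """Per-residue metric table: degree, clustering, betweenness, closeness,
    eccentricity — one row per residue, indexed by author number."""
    return pd.DataFrame({
        "degree": degree(network),
        "clustering": clustering_coefficient(network),
        "betweenness": betweenness(network),
        "closeness": closeness(network),
        "eccentricity": eccentricity(network),
    })


def global_summary(network: ContactNetwork) -> dict[str, float]:
    """Whole-network averages: mean degree, mean clustering, characteristic
    path length (mean over reachable pairs) and diameter."""
    t = metric_table(network)
    sp = shortest_paths(network)
    off = sp[~np.eye(sp.shape[0], dtype=bool)]
    reachable = off[np.isfinite(off)]
    return {
        "n_nodes": int(network.n),
        "n_edges": int(network.n_edges),
        "mean_degree": float(t["degree"].mean()),
        "mean_clustering": float(t["clustering"].mean()),
        "characteristic_path_length": float(reachable.mean()) if len(reachable) else float("nan"),
        "diameter": float(reachable.max()) if len(reachable) else float("nan"),
    }
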