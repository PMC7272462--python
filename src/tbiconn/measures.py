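"""Weighted graph-theory measures on structural connectomes.

All measures operate on symmetric nonnegative weight matrices and follow the
weighted-undirected conventions of the Brain Connectivity Toolbox: edge
weights are connection magnitudes, path computations run over the reciprocal
lengths l_ij = 1/w_ij (strong connections are short), clustering uses the
Onnela geometric-mean form on max-scaled weights, and betweenness is Brandes'
exact algorithm with shortest-path multiplicity sharing.

Measures
--------
* strength          -- sum of weights incident to a node (centrality)
* global efficiency -- mean inverse shortest path length (integration)
* characteristic path length -- mean shortest path over reachable pairs
* nodal efficiency  -- per-node mean inverse distance to all other nodes
* local efficiency  -- global efficiency of each node's neighborhood subgraph
* clustering        -- fraction of a node's neighbors that interconnect (segregation)
* betweenness       -- share of all-pairs shortest paths through a node
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .build import WeightedNetwork

#: relative tolerance for comparing shortest-path lengths (tie detection)
LENGTH_RTOL = 1e-12

NODAL_MEASURES = (
    "strength",
    "raw_strength",
    "nodal_efficiency",
    "local_efficiency",
    "clustering",
    "betweenness",
)
GLOBAL_MEASURES = (
    "strength",
    "raw_strength",
    "global_efficiency",
    "characteristic_path_length",
    "clustering",
)


def _as_weights(network: WeightedNetwork | np.ndarray) -> np.ndarray:
    w = network.weights if isinstance(network, WeightedNetwork) else network
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return w


def length_matrix(
    network: WeightedNetwork | np.ndarray, mapping: str = "inverse"
) -> np.ndarray:
    """Map connection weights to path lengths; absent edges become infinite.

    ``mapping='inverse'`` uses l = 1/w (the toolbox default); ``'neglog'``
    uses l = -log(w), which is additive over multiplicative path reliabilities
    but requires weights <= 1.
    """
    w = _as_weights(network)
    lengths = np.full_like(w, np.inf)
    mask = w > 0
    if mapping == "inverse":
        lengths[mask] = 1.0 / w[mask]
    elif mapping == "neglog":
        if np.any(w > 1):
            raise ValueError("neglog mapping requires weights <= 1")
        lengths[mask] = -np.log(w[mask])
    else:
        raise ValueError(f"unknown weight-length mapping {mapping!r}")
    np.fill_diagonal(lengths, 0.0)
    return lengths


def node_strength(network: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Strength s_i = sum_j w_ij (row sums of the weight matrix)."""
    return _as_weights(network).sum(axis=1)


def shortest_paths(
    network: WeightedNetwork | np.ndarray, mapping: str = "inverse"
) -> np.ndarray:
    """All-pairs shortest-path distance matrix (Dijkstra over l = 1/w).

    Unreachable pairs are marked infinite; the diagonal is zero.
    """
    w = _as_weights(network)
    lengths = length_matrix(w, mapping=mapping)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    np.fill_diagonal(finite, 0.0)
    graph = csr_matrix(finite)
    return dijkstra(graph, directed=False)


def global_efficiency(
    network: WeightedNetwork | np.ndarray,
    distances: np.ndarray | None = None,
    mapping: str = "inverse",
) -> float:
    """Mean of 1/d_ij over ordered pairs i != j; unreachable pairs contribute 0."""
    w = _as_weights(network)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = shortest_paths(w, mapping=mapping) if distances is None else distances
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(
    network: WeightedNetwork | np.ndarray,
    distances: np.ndarray | None = None,
    mapping: str = "inverse",
) -> np.ndarray:
    """Per-node efficiency: mean of 1/d_ij over all other nodes j."""
    w = _as_weights(network)
    n = w.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    d = shortest_paths(w, mapping=mapping) if distances is None else distances
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def characteristic_path_length(
    network: WeightedNetwork | np.ndarray,
    distances: np.ndarray | None = None,
    mapping: str = "inverse",
) -> float:
    """Mean shortest-path length over reachable ordered pairs i != j."""
    w = _as_weights(network)
    d = shortest_paths(w, mapping=mapping) if distances is None else distances
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("characteristic path length undefined: no reachable pair")
    return float(d[finite].mean())


def clustering_coefficient(network: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering on max-scaled weights.

    C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) / (k_i (k_i - 1)) with
    w' = w / max(w) and k_i the binary degree; C_i = 0 for k_i < 2.
    Values lie in [0, 1].
    """
    w = _as_weights(network)
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(w.shape[0])
    scaled = w / wmax
    cbrt = np.cbrt(scaled)
    triangles = np.einsum("ij,jh,hi->i", cbrt, cbrt, cbrt)
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def local_efficiency(network: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Per-node global efficiency of the subgraph induced by its neighbors.

    Nodes with fewer than 2 neighbors score 0 (their neighborhood has no pairs).
    """
    w = _as_weights(network)
    n = w.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        nbrs = nbrs[nbrs != i]
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eloc[i] = global_efficiency(sub)
    return eloc


def betweenness_centrality(
    network: WeightedNetwork | np.ndarray, mapping: str = "inverse"
) -> np.ndarray:
    """Exact weighted betweenness (Brandes), endpoints excluded.

    b_i is the sum over source-target pairs (counted once per unordered pair)
    of the fraction of shortest paths between them passing through i. Ties
    among equal-length paths are detected with relative tolerance 1e-12 and
    multiplicities are shared.
    """
    w = _as_weights(network)
    n = w.shape[0]
    lengths = length_matrix(w, mapping=mapping)
    edge = np.isfinite(lengths) & ~np.eye(n, dtype=bool)
    lengths_f = np.where(edge, lengths, np.inf)
    dist = shortest_paths(w, mapping=mapping)
    bc = np.zeros(n)
    for s in range(n):
        d = dist[s]
        reachable = np.isfinite(d)
        # shortest-path predecessor DAG: edge u->v lies on a shortest path
        # from s iff d[u] + l[u,v] == d[v] (relative tolerance on lengths)
        through = d[:, None] + lengths_f
        with np.errstate(invalid="ignore"):
            pred = edge & np.isfinite(through) & (
                np.abs(through - d[None, :]) <= LENGTH_RTOL * np.maximum(np.abs(through), 1.0)
            )
        order = np.argsort(d[reachable], kind="stable")
        nodes = np.flatnonzero(reachable)[order]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in nodes[1:]:
            sigma[v] = pred[:, v] @ sigma
        delta = np.zeros(n)
        for v in nodes[:0:-1]:
            if sigma[v] == 0:
                continue
            mask = pred[:, v]
            delta[mask] += sigma[mask] / sigma[v] * (1.0 + delta[v])
        bc[nodes[1:]] += delta[nodes[1:]]
    return bc / 2.0  # undirected: each pair visited from both endpoints


def measure_table(
    networks: Iterable[tuple[str, WeightedNetwork]],
    mapping: str = "inverse",
) -> pd.DataFrame:
    """Assemble per-subject global and nodal measures into a long-format table.

    Parameters
    ----------
    networks
        Iterable of (subject_id, WeightedNetwork); all networks must share
        the same parcellation (node labels).

    Returns
    -------
    DataFrame with columns subject_id, scope ('global'|'node'), node_label,
    measure, value. Raw strength rows report pre-normalization streamline
    strengths (weights times total fibers); all other measures use normalized
    weights.
    """
    rows: list[tuple[str, str, str, str, float]] = []
    labels_ref: list[str] | None = None
    for subject_id, net in networks:
        if labels_ref is None:
            labels_ref = list(net.node_labels)
        elif list(net.node_labels) != labels_ref:
            raise ValueError(f"parcellation mismatch for subject {subject_id!r}")
        d = shortest_paths(net, mapping=mapping)
        nodal = {
            "strength": node_strength(net),
            "raw_strength": node_strength(net.raw_counts()),
            "nodal_efficiency": nodal_efficiency(net, distances=d),
            "local_efficiency": local_efficiency(net),
            "clustering": clustering_coefficient(net),
            "betweenness": betweenness_centrality(net, mapping=mapping),
        }
        global_vals = {
            "strength": float(nodal["strength"].mean()),
            "raw_strength": float(nodal["raw_strength"].mean()),
            "global_efficiency": global_efficiency(net, distances=d),
            "characteristic_path_length": characteristic_path_length(net, distances=d),
            "clustering": float(nodal["clustering"].mean()),
        }
        for measure in GLOBAL_MEASURES:
            rows.append((subject_id, "global", "", measure, global_vals[measure]))
        for measure in NODAL_MEASURES:
            values = nodal[measure]
            for label, value in zip(labels_ref, values):
                rows.append((subject_id, "node", label, measure, float(value)))
    return pd.DataFrame(
        rows, columns=["subject_id", "scope", "node_label", "measure", "value"]
    )


def normalize_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each (scope, measure) family to [0, 1] across the cohort.

    The mapping is linear and shared across subjects within a family, so
    group-comparison F statistics are unchanged by it. A constant family is
    mapped to 0 with a warning. Scaling parameters are recorded in the
    returned frame's ``attrs['normalization']``.
    """
    out = table.copy()
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for (scope, measure), idx in out.groupby(["scope", "measure"]).groups.items():
        vals = out.loc[idx, "value"].to_numpy(dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        params[(scope, measure)] = (lo, hi)
        if hi > lo:
            out.loc[idx, "value"] = (vals - lo) / (hi - lo)
        else:
            warnings.warn(
                f"measure {measure!r} ({scope}) is constant across the cohort; scaled to 0",
                stacklevel=2,
            )
            out.loc[idx, "value"] = 0.0
    out.attrs["normalization"] = params
    return out
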