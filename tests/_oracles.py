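"""Independent oracles used by the test suite.

These deliberately share no path-computation or covariance code with the
package: nearest-facility distances are re-derived by per-facility
single-source Dijkstra on a graph augmented with explicit point nodes, and
sandwich covariances are re-derived from the textbook matrix formula.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd


def _augment_with_points(graph: nx.Graph, snaps: dict[str, object]) -> nx.Graph:
    """Insert snapped points as explicit nodes WITHOUT removing host edges.

    Each point node connects to both endpoints of its host edge with the two
    along-edge half lengths, and directly to any other point on the same edge
    with the along-edge gap.  The original edge stays: a path through it has
    the same length as one through a point node, so shortest paths are
    unaffected.
    """
    g = graph.copy()
    by_edge: dict[tuple, list] = {}
    for name, s in snaps.items():
        node = ("pt", name)
        g.add_node(node)
        g.add_edge(node, s.node_a, length_km=s.offset_km)
        g.add_edge(node, s.node_b, length_km=s.edge_length_km - s.offset_km)
        by_edge.setdefault((s.node_a, s.node_b), []).append((s.offset_km, node))
    for pts in by_edge.values():
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = abs(pts[i][0] - pts[j][0])
                a, b = pts[i][1], pts[j][1]
                if g.has_edge(a, b):
                    d = min(d, g.edges[a, b]["length_km"])
                g.add_edge(a, b, length_km=d)
    return g


def brute_force_nearest(network, facilities, query_xy, query_ids=None):
    """Per-facility single-source Dijkstra minimum; shares only the snapper."""
    in_scope = [f for f in facilities if f.in_scope]
    if query_ids is None:
        query_ids = [f"q{i}" for i in range(len(query_xy))]
    fac_snaps = {
        f"f::{f.facility_id}": network.snap(f.x, f.y, f.facility_id) for f in in_scope
    }
    q_snaps = {
        f"q::{qid}": network.snap(x, y, qid)
        for (x, y), qid in zip(query_xy, query_ids)
    }
    g = _augment_with_points(network.graph, {**fac_snaps, **q_snaps})
    out = []
    for qid in query_ids:
        qnode = ("pt", f"q::{qid}")
        best = math.inf
        for fname in fac_snaps:
            fnode = ("pt", fname)
            try:
                d = nx.dijkstra_path_length(g, fnode, qnode, weight="length_km")
            except nx.NetworkXNoPath:
                d = math.inf
            best = min(best, d)
        out.append(best)
    return np.array(out)


def sandwich_cov(X: np.ndarray, y: np.ndarray, hc: str = "HC3") -> np.ndarray:
    """(X'X)^-1 X' diag(w_i e_i^2) X (X'X)^-1 from first principles."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    e = y - X @ beta
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)  # leverage diag of hat matrix
    if hc == "HC0":
        w = e**2
    elif hc == "HC1":
        w = e**2 * n / (n - p)
    elif hc == "HC3":
        w = e**2 / (1.0 - h) ** 2
    else:
        raise ValueError(hc)
    return xtx_inv @ (X.T * w) @ X @ xtx_inv


def ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


def random_geometric_network(rng: np.random.Generator, max_nodes: int = 50):
    """Random planar-ish test graph: uniform nodes, random edges, Euclidean lengths."""
    from rxaccess.network import RoadNetwork

    n = int(rng.integers(5, max_nodes + 1))
    xs = rng.uniform(0, 10, size=n)
    ys = rng.uniform(0, 10, size=n)
    nodes = pd.DataFrame(
        {"node_id": [f"v{i}" for i in range(n)], "x_km": xs, "y_km": ys}
    )
    m = int(rng.integers(n, 3 * n))
    a = rng.integers(0, n, size=m)
    b = rng.integers(0, n, size=m)
    keep = a != b
    a, b = a[keep], b[keep]
    edges = pd.DataFrame(
        {
            "node_a": [f"v{i}" for i in a],
            "node_b": [f"v{i}" for i in b],
            "length_km": np.hypot(xs[a] - xs[b], ys[a] - ys[b]) + 1e-6,
        }
    )
    return RoadNetwork.from_tables(nodes, edges)
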