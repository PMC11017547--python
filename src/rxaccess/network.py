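"""Road networks and shortest network distances to the nearest facility.

The network is an undirected weighted graph in a planar, projected frame with
coordinates and edge lengths in kilometres.  Off-network points (census-block
centroids, pharmacy locations) are snapped to the nearest edge by perpendicular
projection; a snapped point splits its host edge into two traversable
half-edges.  The distance from a block to its nearest in-scope pharmacy is the
shortest-path length along the network between the two snap locations, computed
with a single multi-source Dijkstra sweep seeded at every in-scope facility.

The straight-line gap between a point and its snap location (the "snap
displacement") is reported for quality control but never added to the network
distance.  Points on a component that contains no in-scope facility receive an
infinite distance and are flagged unreachable rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkInputError",
    "FacilityPoint",
    "SnappedPoint",
    "RoadNetwork",
    "build_network",
    "snap_point",
    "nearest_facility_distances",
]


class NetworkInputError(ValueError):
    """Raised when node/edge/facility inputs violate the schema contracts."""


def _edge_key(a, b) -> tuple[str, str]:
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class FacilityPoint:
    """A candidate destination (pharmacy).

    ``in_scope`` encodes the border rule: facilities in neighbouring states
    count as destinations, facilities across an international border do not.
    Out-of-scope facilities are carried through the pipeline but never
    contribute to any distance.
    """

    facility_id: str
    x: float
    y: float
    in_scope: bool = True

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise NetworkInputError(
                f"facility {self.facility_id!r} has non-finite coordinates"
            )


@dataclass(frozen=True)
class SnappedPoint:
    """A point projected onto the network.

    ``offset_km`` measures along the host edge from ``node_a`` (the
    lexicographically smaller endpoint); ``displacement_km`` is the
    straight-line gap between the original point and its snap location.
    """

    point_id: str
    node_a: str
    node_b: str
    edge_length_km: float
    offset_km: float
    displacement_km: float

    def __post_init__(self):
        if not -1e-9 <= self.offset_km <= self.edge_length_km + 1e-9:
            raise ValueError(
                f"snap offset {self.offset_km} outside [0, {self.edge_length_km}]"
            )
        if self.displacement_km < 0:
            raise ValueError("snap displacement must be non-negative")


class RoadNetwork:
    """Undirected weighted road graph with planar node coordinates (km).

    Parallel edges between the same node pair are collapsed to the shortest;
    the graph may be disconnected (component count is tracked so unreachable
    query points can be flagged downstream).
    """

    def __init__(self, graph: nx.Graph):
        for n, d in graph.nodes(data=True):
            if "x" not in d or "y" not in d:
                raise NetworkInputError(f"node {n!r} lacks coordinates")
            if not (math.isfinite(d["x"]) and math.isfinite(d["y"])):
                raise NetworkInputError(f"node {n!r} has non-finite coordinates")
        for a, b, d in graph.edges(data=True):
            L = d.get("length_km")
            if L is None or not math.isfinite(L) or L <= 0:
                raise NetworkInputError(
                    f"edge ({a!r},{b!r}) has non-positive or missing length"
                )
        self.graph = graph
        self._seg_cache: tuple | None = None

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def node_xy(self, node_id) -> tuple[float, float]:
        d = self.graph.nodes[str(node_id)]
        return d["x"], d["y"]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        node_table: pd.DataFrame,
        edge_table: pd.DataFrame,
        infer_missing_lengths: bool = True,
    ) -> "RoadNetwork":
        """Build a network from ``node_id,x_km,y_km`` and ``node_a,node_b[,length_km]``.

        Missing edge lengths default to the Euclidean node distance unless
        ``infer_missing_lengths`` is disabled, in which case they are an error.
        Duplicate node-pair edges keep the minimum length; self-loops are
        rejected.
        """
        for col in ("node_id", "x_km", "y_km"):
            if col not in node_table.columns:
                raise NetworkInputError(f"node table missing column {col!r}")
        for col in ("node_a", "node_b"):
            if col not in edge_table.columns:
                raise NetworkInputError(f"edge table missing column {col!r}")

        g = nx.Graph()
        for row in node_table.itertuples(index=False):
            nid = str(row.node_id)
            if nid in g:
                raise NetworkInputError(f"duplicate node id {nid!r}")
            g.add_node(nid, x=float(row.x_km), y=float(row.y_km))

        has_len = "length_km" in edge_table.columns
        for row in edge_table.itertuples(index=False):
            a, b = str(row.node_a), str(row.node_b)
            if a == b:
                raise NetworkInputError(f"self-loop edge at node {a!r}")
            for n in (a, b):
                if n not in g:
                    raise NetworkInputError(
                        f"edge ({a!r},{b!r}) references absent node {n!r}"
                    )
            L = float(row.length_km) if has_len else math.nan
            if not math.isfinite(L):
                if not infer_missing_lengths:
                    raise NetworkInputError(
                        f"edge ({a!r},{b!r}) lacks length_km and inference is disabled"
                    )
                ax, ay = g.nodes[a]["x"], g.nodes[a]["y"]
                bx, by = g.nodes[b]["x"], g.nodes[b]["y"]
                L = math.hypot(bx - ax, by - ay)
            if L <= 0:
                raise NetworkInputError(f"edge ({a!r},{b!r}) has non-positive length {L}")
            if g.has_edge(a, b):
                L = min(L, g.edges[a, b]["length_km"])  # parallel edges: keep shorter
            g.add_edge(a, b, length_km=L)
        return cls(g)

    # -- snapping ----------------------------------------------------------
    def _segments(self):
        """Edge endpoint arrays sorted by (node_a, node_b) key for tie-breaks."""
        if self._seg_cache is None:
            keys = sorted(_edge_key(a, b) for a, b in self.graph.edges())
            ax = np.empty(len(keys))
            ay = np.empty(len(keys))
            bx = np.empty(len(keys))
            by = np.empty(len(keys))
            ln = np.empty(len(keys))
            for i, (a, b) in enumerate(keys):
                ax[i], ay[i] = self.node_xy(a)
                bx[i], by[i] = self.node_xy(b)
                ln[i] = self.graph.edges[a, b]["length_km"]
            self._seg_cache = (keys, ax, ay, bx, by, ln)
        return self._seg_cache

    def snap(self, x: float, y: float, point_id: str = "point") -> SnappedPoint:
        return self.snap_many([x], [y], [point_id])[0]

    def snap_many(
        self, xs: Sequence[float], ys: Sequence[float], ids: Sequence[str]
    ) -> list[SnappedPoint]:
        """Project points onto their nearest edge (vectorised over edges).

        The projection falls back to the nearest endpoint when it lands outside
        the segment.  Exact displacement ties resolve to the edge with the
        lexicographically smallest (node_a, node_b) key.
        """
        if self.n_edges == 0:
            raise NetworkInputError("cannot snap to an empty network")
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
            bad = [str(i) for i, (a, b) in enumerate(zip(xs, ys))
                   if not (math.isfinite(a) and math.isfinite(b))]
            raise NetworkInputError(f"non-finite point coordinates at rows {bad}")
        keys, ax, ay, bx, by, ln = self._segments()
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy

        out: list[SnappedPoint] = []
        chunk = 256
        for lo in range(0, len(xs), chunk):
            px = xs[lo : lo + chunk, None]
            py = ys[lo : lo + chunk, None]
            t = ((px - ax) * dx + (py - ay) * dy) / seg2
            t = np.clip(t, 0.0, 1.0)
            cx = ax + t * dx
            cy = ay + t * dy
            disp = np.hypot(px - cx, py - cy)
            best = np.argmin(disp, axis=1)  # first minimum = smallest edge key
            for j, e in enumerate(best):
                i = lo + j
                a, b = keys[e]
                # offset in true edge-length units, not straight-line units
                out.append(
                    SnappedPoint(
                        point_id=str(ids[i]),
                        node_a=a,
                        node_b=b,
                        edge_length_km=float(ln[e]),
                        offset_km=float(t[j, e] * ln[e]),
                        displacement_km=float(disp[j, e]),
                    )
                )
        return out

    # -- distances ---------------------------------------------------------
    def nearest_facility_distances(
        self,
        facilities: Iterable[FacilityPoint],
        query_xy: Sequence[tuple[float, float]],
        query_ids: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Shortest network distance from each query point to any in-scope facility.

        Returns a DataFrame ``point_id, distance_km, snap_displacement_km,
        reachable``, one row per query point in input order.  Implemented as a
        single multi-source Dijkstra sweep seeded at every in-scope facility
        snap location; contractually equal to the minimum over per-facility
        shortest paths.  Unreachable points get ``distance_km = inf`` and
        ``reachable = False``.
        """
        facilities = list(facilities)
        in_scope = [f for f in facilities if f.in_scope]
        if not in_scope:
            raise NetworkInputError("no in-scope facilities: distances undefined")
        if query_ids is None:
            query_ids = [f"q{i}" for i in range(len(query_xy))]

        fac_snaps = self.snap_many(
            [f.x for f in in_scope],
            [f.y for f in in_scope],
            [f.facility_id for f in in_scope],
        )

        # Augment a copy of the graph: each facility snap becomes a real node
        # splitting its host edge (facilities sharing an edge form a chain).
        g2 = self.graph.copy()
        by_edge: dict[tuple[str, str], list[tuple[float, object]]] = {}
        for i, s in enumerate(fac_snaps):
            by_edge.setdefault((s.node_a, s.node_b), []).append(
                (s.offset_km, ("__rxfac__", i))
            )
        sources = [("__rxfac__", i) for i in range(len(fac_snaps))]
        for (a, b), offs in by_edge.items():
            L = self.graph.edges[a, b]["length_km"]
            offs.sort(key=lambda p: p[0])
            if g2.has_edge(a, b):
                g2.remove_edge(a, b)
            prev, prev_off = a, 0.0
            for off, vn in offs:
                g2.add_node(vn)
                g2.add_edge(prev, vn, length_km=max(off - prev_off, 0.0))
                prev, prev_off = vn, off
            g2.add_edge(prev, b, length_km=max(L - prev_off, 0.0))

        dist = nx.multi_source_dijkstra_path_length(g2, sources, weight="length_km")

        q_snaps = self.snap_many(
            [p[0] for p in query_xy], [p[1] for p in query_xy], list(query_ids)
        )
        rows = []
        for s in q_snaps:
            cands = [
                dist.get(s.node_a, math.inf) + s.offset_km,
                dist.get(s.node_b, math.inf) + (s.edge_length_km - s.offset_km),
            ]
            # facilities on the query's own host edge: direct along-edge path
            for off, _ in by_edge.get((s.node_a, s.node_b), []):
                cands.append(abs(s.offset_km - off))
            d = min(cands)
            rows.append(
                {
                    "point_id": s.point_id,
                    "distance_km": d,
                    "snap_displacement_km": s.displacement_km,
                    "reachable": math.isfinite(d),
                }
            )
        return pd.DataFrame(rows)


def build_network(
    node_table: pd.DataFrame,
    edge_table: pd.DataFrame,
    infer_missing_lengths: bool = True,
) -> RoadNetwork:
    """Functional alias for :meth:`RoadNetwork.from_tables`."""
    return RoadNetwork.from_tables(node_table, edge_table, infer_missing_lengths)


def snap_point(network: RoadNetwork, x: float, y: float, point_id: str = "point") -> SnappedPoint:
    """Functional alias for :meth:`RoadNetwork.snap`."""
    return network.snap(x, y, point_id)


def nearest_facility_distances(
    network: RoadNetwork,
    facilities: Iterable[FacilityPoint],
    query_xy: Sequence[tuple[float, float]],
    query_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Functional alias for :meth:`RoadNetwork.nearest_facility_distances`."""
    return network.nearest_facility_distances(facilities, query_xy, query_ids)
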