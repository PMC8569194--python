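"""River-network graph metrics: the raw dyadic covariates.

A drainage network is a rooted tree: every reach (edge) points from a child
node toward its parent, downstream to the single outlet.  From this substrate
four raw covariates are computed for every within-basin pair of sites:

* network distance — length of the unique tree path between the two nodes (km)
* Euclidean distance — planar straight-line distance (km)
* flow connection — 1 if one site lies on the other's downstream path to the
  outlet (ancestor/descendant in the drainage tree), else 0
* Strahler-order difference — absolute difference of the stream-size indices

together with the absolute annual-precipitation difference (mm).  Pairs whose
network/Euclidean distance ratio is <= 2 are discarded so that the network
distance is not confounded by overland proximity: two sites a short flight
apart but far apart along the channels would otherwise dilute the
network-distance signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RiverNetwork",
    "PairObservation",
    "FilterReport",
    "ScreenReport",
    "InvalidNetworkError",
    "strahler_orders",
    "network_distance",
    "euclidean_distance",
    "flow_connected",
    "ratio_filter",
    "build_pairs",
    "covariate_screen",
    "read_network_csv",
    "write_network_csv",
]

#: documented column order of the assembled pair table
PAIR_COLUMNS = [
    "site_a",
    "site_b",
    "basin_id",
    "sorensen",
    "network_distance_km",
    "euclidean_distance_km",
    "flow_connection",
    "strahler_difference",
    "precipitation_difference_mm",
]

COVARIATE_COLUMNS = [
    "network_distance_km",
    "flow_connection",
    "strahler_difference",
    "precipitation_difference_mm",
]


class InvalidNetworkError(ValueError):
    """The graph is not a valid rooted drainage tree."""


@dataclass
class RiverNetwork:
    """Rooted drainage tree with node coordinates and positive reach lengths.

    ``graph`` is a directed networkx graph whose edges point child -> parent
    (downstream); node attributes ``x_km``/``y_km`` give planar coordinates
    and the edge attribute ``length_km`` the channel length of the reach.
    ``outlet`` is the single root (no outgoing edge).
    """

    graph: nx.DiGraph
    outlet: int
    _parent: dict = field(default=None, repr=False, compare=False)
    _dist_to_outlet: dict = field(default=None, repr=False, compare=False)
    _depth: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        g = self.graph
        n, m = g.number_of_nodes(), g.number_of_edges()
        if n == 0:
            raise InvalidNetworkError("empty network")
        if self.outlet not in g:
            raise InvalidNetworkError("outlet not a node of the graph")
        if m != n - 1:
            raise InvalidNetworkError(f"tree must have n-1 edges, got {m} for {n} nodes")
        if not nx.is_weakly_connected(g):
            raise InvalidNetworkError("network is not connected")
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidNetworkError("network contains a cycle")
        if g.out_degree(self.outlet) != 0:
            raise InvalidNetworkError("outlet must have no downstream edge")
        for node in g:
            if node != self.outlet and g.out_degree(node) != 1:
                raise InvalidNetworkError(
                    f"non-outlet node {node} must have exactly one downstream edge"
                )
        for u, v, data in g.edges(data=True):
            if not data.get("length_km", 0) > 0:
                raise InvalidNetworkError(f"edge ({u},{v}) has non-positive length")

    # ---- cached tree structure -----------------------------------------

    def parent_of(self, node):
        """Downstream neighbour of ``node`` (None for the outlet)."""
        return self._parents().get(node)

    def _parents(self) -> dict:
        if self._parent is None:
            self._parent = {u: v for u, v in self.graph.edges()}
        return self._parent

    def _downstream_tables(self) -> tuple[dict, dict]:
        """Per node: path length (km) and edge count down to the outlet."""
        if self._dist_to_outlet is None:
            parents = self._parents()
            dist = {self.outlet: 0.0}
            depth = {self.outlet: 0}
            # children-before-parents order reversed gives root-first order
            order = list(nx.topological_sort(self.graph))
            for node in reversed(order):
                if node == self.outlet:
                    continue
                p = parents[node]
                dist[node] = dist[p] + self.graph.edges[node, p]["length_km"]
                depth[node] = depth[p] + 1
            self._dist_to_outlet = dist
            self._depth = depth
        return self._dist_to_outlet, self._depth

    def coordinates(self, node) -> tuple[float, float]:
        data = self.graph.nodes[node]
        return float(data["x_km"]), float(data["y_km"])

    @property
    def node_ids(self) -> list:
        return list(self.graph.nodes)

    def edge_list(self) -> list[tuple]:
        """Edges as (child, parent, length_km) tuples."""
        return [
            (u, v, float(d["length_km"])) for u, v, d in self.graph.edges(data=True)
        ]


def strahler_orders(network: RiverNetwork) -> dict:
    """Strahler stream order of every node of a drainage tree.

    Headwater (leaf) nodes have order 1.  A junction's order is the maximum
    of its children's orders, incremented by one when at least two children
    attain that maximum.  Orders therefore never decrease downstream and the
    outlet carries the basin's maximal order.
    """
    g = network.graph
    orders: dict = {}
    for node in nx.topological_sort(g):  # children before parents
        child_orders = [orders[c] for c, _ in g.in_edges(node)]
        if not child_orders:
            orders[node] = 1
        else:
            top = max(child_orders)
            orders[node] = top + 1 if child_orders.count(top) >= 2 else top
    return orders


def network_distance(network: RiverNetwork, node_a, node_b) -> float:
    """Channel length of the unique tree path between two nodes, in km."""
    for node in (node_a, node_b):
        if node not in network.graph:
            raise ValueError(f"node {node} is not on this network")
    if node_a == node_b:
        return 0.0
    dist, depth = network._downstream_tables()
    parents = network._parents()
    # lowest common ancestor by walking the deeper node up to equal depth
    a, b = node_a, node_b
    while depth[a] > depth[b]:
        a = parents[a]
    while depth[b] > depth[a]:
        b = parents[b]
    while a != b:
        a, b = parents[a], parents[b]
    return dist[node_a] + dist[node_b] - 2.0 * dist[a]


def euclidean_distance(xy_a: tuple[float, float], xy_b: tuple[float, float]) -> float:
    """Planar straight-line distance between two coordinate pairs (km)."""
    return float(np.hypot(xy_a[0] - xy_b[0], xy_a[1] - xy_b[1]))


def flow_connected(network: RiverNetwork, node_a, node_b) -> int:
    """1 if one node lies on the other's downstream path to the outlet.

    Equivalent to an ancestor/descendant relation in the drainage tree; a
    node is flow-connected to itself by convention.
    """
    for node in (node_a, node_b):
        if node not in network.graph:
            raise ValueError(f"node {node} is not on this network")
    if node_a == node_b:
        return 1
    _, depth = network._downstream_tables()
    parents = network._parents()
    hi, lo = (node_a, node_b) if depth[node_a] > depth[node_b] else (node_b, node_a)
    while depth[hi] > depth[lo]:
        hi = parents[hi]
    return int(hi == lo)


@dataclass
class PairObservation:
    """One dyad: Sorensen value plus all raw covariates."""

    site_a: str
    site_b: str
    basin_id: object
    sorensen: float
    network_distance_km: float
    euclidean_distance_km: float
    flow_connection: int
    strahler_difference: int
    precipitation_difference_mm: float


@dataclass
class FilterReport:
    """Bookkeeping of the network/Euclidean ratio filter."""

    n_before: int
    n_after: int
    n_zero_euclidean: int
    threshold: float

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_zero_euclidean": self.n_zero_euclidean,
            "threshold": self.threshold,
        }


def build_pairs(
    sites: pd.DataFrame,
    networks: Mapping[object, RiverNetwork],
    similarity_table: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the pair table: one row per within-basin dyad, all covariates.

    Parameters
    ----------
    sites : DataFrame
        One row per site with columns ``site_id, basin_id, node_id, x_km,
        y_km, precip_mm`` and (optionally) ``strahler_order``.  When the
        ``strahler_order`` column is present (e.g. supplied by an external
        hydrographic database) it overrides orders computed from the tree.
    networks : mapping basin id -> RiverNetwork
    similarity_table : DataFrame
        Output of :func:`riverddcs.similarity.pairwise_sorensen`, covering
        all within-basin pairs.

    Returns an (unfiltered) DataFrame in the :data:`PAIR_COLUMNS` order;
    Strahler and precipitation differences are absolute values.
    """
    site_info = sites.set_index("site_id")
    use_external_orders = "strahler_order" in sites.columns and sites[
        "strahler_order"
    ].notna().all()
    computed_orders = {b: strahler_orders(net) for b, net in networks.items()}

    rows = []
    for rec in similarity_table.itertuples(index=False):
        sa, sb, basin = rec.site_a, rec.site_b, rec.basin
        if basin not in networks:
            raise KeyError(f"no network supplied for basin {basin}")
        net = networks[basin]
        try:
            info_a, info_b = site_info.loc[sa], site_info.loc[sb]
        except KeyError as err:
            raise KeyError(f"site missing from site table: {err}") from err
        node_a, node_b = info_a["node_id"], info_b["node_id"]
        if use_external_orders:
            order_a, order_b = info_a["strahler_order"], info_b["strahler_order"]
        else:
            order_a = computed_orders[basin][node_a]
            order_b = computed_orders[basin][node_b]
        rows.append(
            (
                sa,
                sb,
                basin,
                rec.sorensen,
                network_distance(net, node_a, node_b),
                euclidean_distance(
                    (info_a["x_km"], info_a["y_km"]), (info_b["x_km"], info_b["y_km"])
                ),
                flow_connected(net, node_a, node_b),
                int(abs(order_a - order_b)),
                abs(float(info_a["precip_mm"]) - float(info_b["precip_mm"])),
            )
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def ratio_filter(
    pairs: pd.DataFrame, threshold: float = 2.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain pairs whose network/Euclidean distance ratio is strictly > threshold.

    Pairs at exactly the threshold are excluded.  Dyads with zero Euclidean
    distance (coincident coordinates) have an undefined ratio and are
    excluded with a logged warning rather than retained as infinite ratios.
    Idempotent: filtering an already-filtered table changes nothing.
    """
    n_before = len(pairs)
    zero = pairs["euclidean_distance_km"] <= 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.warning(
            "%d pair(s) with zero Euclidean distance excluded (undefined ratio)",
            n_zero,
        )
    ok = ~zero & (
        pairs["network_distance_km"] > threshold * pairs["euclidean_distance_km"]
    )
    filtered = pairs[ok].reset_index(drop=True)
    report = FilterReport(
        n_before=n_before,
        n_after=len(filtered),
        n_zero_euclidean=n_zero,
        threshold=threshold,
    )
    return filtered, report


@dataclass
class ScreenReport:
    """Pairwise-correlation screen of the four raw covariates."""

    correlations: pd.DataFrame
    threshold: float
    undefined: list
    all_below: bool | None

    def to_dict(self) -> dict:
        return {
            "correlations": self.correlations.to_dict(),
            "threshold": self.threshold,
            "undefined": [list(pair) for pair in self.undefined],
            "all_below": self.all_below,
        }


def covariate_screen(pairs: pd.DataFrame, threshold: float = 0.27) -> ScreenReport:
    """Pairwise Pearson correlations of the four raw covariates.

    A constant covariate yields undefined (NaN) correlations, which are
    reported rather than raised.  ``all_below`` is True when every defined
    off-diagonal absolute correlation is below the threshold, and None when
    any entry is undefined.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to compute correlations")
    cols = COVARIATE_COLUMNS
    corr = pairs[cols].astype(float).corr()
    undefined = []
    values = []
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            r = corr.loc[ci, cj]
            if np.isnan(r):
                undefined.append((ci, cj))
            else:
                values.append(abs(r))
    all_below = None if undefined else bool(all(v < threshold for v in values))
    return ScreenReport(
        correlations=corr, threshold=threshold, undefined=undefined, all_below=all_below
    )


# ---- I/O ----------------------------------------------------------------


def write_network_csv(
    network: RiverNetwork, edges_path: str | Path, nodes_path: str | Path
) -> None:
    """Write a network as an edge-list CSV and a node-coordinate CSV."""
    pd.DataFrame(
        network.edge_list(), columns=["child_id", "parent_id", "length_km"]
    ).to_csv(edges_path, index=False)
    pd.DataFrame(
        [(n, *network.coordinates(n)) for n in network.node_ids],
        columns=["id", "x_km", "y_km"],
    ).to_csv(nodes_path, index=False)


def read_network_csv(edges_path: str | Path, nodes_path: str | Path) -> RiverNetwork:
    """Read a network written by :func:`write_network_csv`."""
    edges = pd.read_csv(edges_path)
    nodes = pd.read_csv(nodes_path)
    g = nx.DiGraph()
    for rec in nodes.itertuples(index=False):
        g.add_node(int(rec.id), x_km=float(rec.x_km), y_km=float(rec.y_km))
    for rec in edges.itertuples(index=False):
        g.add_edge(int(rec.child_id), int(rec.parent_id), length_km=float(rec.length_km))
    outlets = [n for n in g if g.out_degree(n) == 0]
    if len(outlets) != 1:
        raise InvalidNetworkError(f"expected exactly one outlet, found {len(outlets)}")
    return RiverNetwork(graph=g, outlet=outlets[0])
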