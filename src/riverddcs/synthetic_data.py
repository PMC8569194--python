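"""Synthetic dendritic river networks, censuses and similarities.

Field campaigns of the kind this pipeline analyses — hundreds of vegetation
censuses across many river basins, with network topology and Strahler orders
from a hydrographic database and precipitation from a climate surface — are
rarely redistributable.  This module generates stand-ins with the statistical
structure the model assumes, so every downstream stage is exercisable and
parameter recovery can be verified against known ground truth.

Two similarity generators are provided on purpose:

* :func:`simulate_sorensen_from_model` draws dyad similarities directly from
  the beta-regression likelihood at known parameters — the fitted model is
  then the true model, as parameter-recovery and calibration experiments
  require;
* :func:`simulate_communities` is a mechanistic occupancy generator (species
  spread from core sites with distance- and climate-limited occupancy) that
  produces actual presence/absence matrices for end-to-end runs through the
  Sorensen stage.

Networks are random binary-merge drainage trees.  Edges may meander: each
reach's straight-line chord is its channel length divided by a meander factor
>= 1, so network distance >= Euclidean distance by construction and the
network/Euclidean ratio filter is meaningful on synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import bayes_model
from .bayes_model import ModelParameters
from .network_metrics import (
    RiverNetwork,
    network_distance,
    strahler_orders,
    write_network_csv,
)
from .similarity import CommunityMatrix

__all__ = [
    "TrueParameters",
    "Site",
    "SimulationConfig",
    "generate_network",
    "generate_basins",
    "simulate_sorensen_from_model",
    "simulate_communities",
    "make_true_parameters",
    "run_simulation",
]

#: ground-truth parameters are structurally identical to a model draw
TrueParameters = ModelParameters


@dataclass(frozen=True)
class Site:
    """One census location on a basin's network."""

    site_id: str
    basin_id: int
    node_id: int
    precip_mm: float
    x_km: float
    y_km: float
    strahler_order: int

    def __post_init__(self) -> None:
        if self.precip_mm < 0:
            raise ValueError("precipitation must be non-negative")
        if self.strahler_order < 1:
            raise ValueError("Strahler order must be >= 1")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_network(
    n_leaves: int,
    mean_edge_length_km: float = 6.0,
    seed: int | np.random.Generator = 0,
    meander_range: tuple[float, float] = (1.15, 1.6),
) -> RiverNetwork:
    """Random binary-merge drainage tree with coordinates.

    Starts from ``n_leaves`` headwater nodes and repeatedly merges two
    randomly chosen subtree roots into a new downstream junction until a
    single root — the outlet — remains.  Edge channel lengths are gamma
    distributed around ``mean_edge_length_km``; coordinates are laid out
    outlet-first so that each edge's straight-line chord equals its channel
    length divided by a meander factor drawn from ``meander_range`` (>= 1),
    guaranteeing chord <= channel length.  Deterministic given ``seed``.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if not mean_edge_length_km > 0:
        raise ValueError("mean_edge_length_km must be positive")
    if not meander_range[0] >= 1.0:
        raise ValueError("meander factors must be >= 1")
    rng = _as_rng(seed)

    g = nx.DiGraph()
    roots = list(range(n_leaves))
    g.add_nodes_from(roots)
    next_id = n_leaves
    while len(roots) > 1:
        i, j = rng.choice(len(roots), size=2, replace=False)
        a, b = roots[int(i)], roots[int(j)]
        junction = next_id
        next_id += 1
        g.add_node(junction)
        for child in (a, b):
            length = rng.gamma(4.0, mean_edge_length_km / 4.0)
            g.add_edge(child, junction, length_km=max(length, 1e-3))
        roots = [r for r in roots if r not in (a, b)] + [junction]
    outlet = roots[0]

    # outlet-first layout: each child sits one chord away from its parent,
    # fanned out around the direction the parent was entered from
    g.nodes[outlet]["x_km"] = 0.0
    g.nodes[outlet]["y_km"] = 0.0
    stack = [(outlet, np.pi / 2.0)]  # grow the basin "upstream" of the outlet
    while stack:
        node, heading = stack.pop()
        children = [u for u, _ in g.in_edges(node)]
        if not children:
            continue
        offsets = np.linspace(-0.9, 0.9, len(children)) if len(children) > 1 else [0.0]
        for child, off in zip(children, offsets):
            angle = heading + off + rng.uniform(-0.25, 0.25)
            meander = rng.uniform(*meander_range)
            chord = g.edges[child, node]["length_km"] / meander
            g.nodes[child]["x_km"] = g.nodes[node]["x_km"] + chord * np.cos(angle)
            g.nodes[child]["y_km"] = g.nodes[node]["y_km"] + chord * np.sin(angle)
            stack.append((child, angle))
    return RiverNetwork(graph=g, outlet=outlet)


def _stratified_site_nodes(
    orders: dict, n_sites: int, rng: np.random.Generator
) -> list:
    """Pick distinct nodes spread across Strahler orders (round-robin)."""
    by_order: dict[int, list] = {}
    for node, order in orders.items():
        by_order.setdefault(order, []).append(node)
    pools = []
    for order in sorted(by_order):
        nodes = sorted(by_order[order])
        rng.shuffle(nodes)
        pools.append(nodes)
    chosen: list = []
    while len(chosen) < n_sites:
        progressed = False
        for pool in pools:
            if pool and len(chosen) < n_sites:
                chosen.append(pool.pop())
                progressed = True
        if not progressed:
            break
    return chosen


def generate_basins(
    n_basins: int = 11,
    sites_per_basin: int = 30,
    n_leaves: int = 64,
    mean_edge_length_km: float = 6.0,
    precip_base_mm: float = 3000.0,
    precip_gradient_mm_per_km: float = 1.2,
    precip_noise_sd: float = 30.0,
    basin_spacing_km: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[int, RiverNetwork], pd.DataFrame]:
    """Generate independent basins with sites, Strahler orders and climate.

    Basins are laid out along a west-east axis ``basin_spacing_km`` apart and
    annual precipitation declines linearly along that axis (plus a weaker
    north-south component) with Gaussian noise, clipped at zero — emulating a
    smooth regional climate gradient.  Sites sit exactly on network nodes,
    distinct within a basin, stratified across Strahler orders so that
    order-difference levels are populated.

    Returns ``(networks, sites)`` where ``networks`` maps basin id (1-based)
    to its :class:`RiverNetwork` and ``sites`` is a DataFrame with columns
    ``site_id, basin_id, node_id, x_km, y_km, precip_mm, strahler_order``.
    """
    if n_basins < 1:
        raise ValueError("n_basins must be >= 1")
    if sites_per_basin < 2:
        raise ValueError("sites_per_basin must be >= 2")
    rng = _as_rng(seed)

    networks: dict[int, RiverNetwork] = {}
    rows = []
    for b in range(1, n_basins + 1):
        net = generate_network(n_leaves, mean_edge_length_km, rng)
        offset = (b - 1) * basin_spacing_km
        for node in net.graph.nodes:
            net.graph.nodes[node]["x_km"] += offset
        networks[b] = net
        n_nodes = net.graph.number_of_nodes()
        if sites_per_basin > n_nodes:
            raise ValueError(
                f"sites_per_basin={sites_per_basin} exceeds the {n_nodes} nodes "
                f"of basin {b}"
            )
        orders = strahler_orders(net)
        nodes = _stratified_site_nodes(orders, sites_per_basin, rng)
        for k, node in enumerate(nodes, start=1):
            x, y = net.coordinates(node)
            precip = (
                precip_base_mm
                - precip_gradient_mm_per_km * (x + 0.3 * y)
                + (rng.normal(0.0, precip_noise_sd) if precip_noise_sd > 0 else 0.0)
            )
            rows.append(
                (
                    f"b{b:02d}s{k:03d}",
                    b,
                    node,
                    x,
                    y,
                    max(precip, 0.0),
                    orders[node],
                )
            )
    sites = pd.DataFrame(
        rows,
        columns=["site_id", "basin_id", "node_id", "x_km", "y_km",
                 "precip_mm", "strahler_order"],
    )
    return networks, sites


def simulate_sorensen_from_model(
    design, truth: TrueParameters, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Similarities drawn from the beta-regression likelihood at ``truth``.

    For each dyad, logit(mu) is the model's linear predictor and the value a
    ``Beta(mu * kappa, (1 - mu) * kappa)`` draw, strictly inside (0, 1).
    Deterministic given ``seed``.
    """
    return bayes_model.simulate_similarities(truth, design, _as_rng(seed))


def make_true_parameters(
    n_sites: int,
    n_basins: int,
    seed: int | np.random.Generator = 0,
    mu_distance: float = -0.4,
    mu_flow: float = 0.05,
    mu_precipitation: float = -0.3,
    kappa: float = 30.0,
    alpha_baseline: float = 0.2,
    sigma_s: float = 0.2,
    sigma_strahler: float = 0.15,
    sigma_distance: float = 0.1,
    sigma_flow: float = 0.05,
    sigma_precipitation: float = 0.1,
) -> TrueParameters:
    """Ground-truth parameters with fixed hyperparameters for recovery tests.

    Hyper-means, scales, the baseline and kappa are set explicitly; the
    group-level vectors (site/Strahler intercepts, per-basin slopes) are
    drawn from their hierarchical distributions at those values.
    """
    rng = _as_rng(seed)
    return TrueParameters(
        alpha_baseline=alpha_baseline,
        alpha_s=rng.normal(0.0, sigma_s, size=n_sites),
        sigma_s=sigma_s,
        alpha_c=rng.normal(0.0, 0.3, size=n_basins),
        alpha_o=rng.normal(0.0, sigma_strahler, size=7),
        sigma_strahler=sigma_strahler,
        beta_distance=rng.normal(mu_distance, sigma_distance, size=n_basins),
        beta_flow=rng.normal(mu_flow, sigma_flow, size=n_basins),
        beta_precip=rng.normal(mu_precipitation, sigma_precipitation, size=n_basins),
        mu_distance=mu_distance,
        mu_flow=mu_flow,
        mu_precipitation=mu_precipitation,
        sigma_distance=sigma_distance,
        sigma_flow=sigma_flow,
        sigma_precipitation=sigma_precipitation,
        kappa=kappa,
    )


def simulate_communities(
    sites: pd.DataFrame,
    networks: dict[int, RiverNetwork],
    n_species: int = 120,
    occupancy_params: tuple[float, float, float] = (2.0, 0.08, 0.01),
    seed: int | np.random.Generator = 0,
) -> CommunityMatrix:
    """Mechanistic presence/absence generator: dispersal from core sites.

    Each species is seeded at a random core site and occupies site ``s`` of
    the same basin with probability
    ``logistic(a0 - a1 * network_distance(core, s) - a2 * |precip_s - precip_core|)``
    where ``occupancy_params = (a0, a1, a2)`` (a1 in 1/km, a2 in 1/mm).
    Sites in other basins are never occupied (dispersal cannot leave the
    basin).  Every site is guaranteed at least one species: an empty site
    receives the species whose core is nearest along the network.
    Deterministic given ``seed``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    a0, a1, a2 = occupancy_params
    rng = _as_rng(seed)

    site_ids = list(sites["site_id"])
    n_sites = len(site_ids)
    basin = sites["basin_id"].to_numpy()
    node = sites["node_id"].to_numpy()
    precip = sites["precip_mm"].to_numpy(float)

    core_idx = rng.integers(0, n_sites, size=n_species)
    presence = np.zeros((n_sites, n_species), dtype=np.int8)
    # network distance from each species' core to every same-basin site
    dist = np.full((n_species, n_sites), np.inf)
    for sp in range(n_species):
        ci = core_idx[sp]
        net = networks[basin[ci]]
        same = np.flatnonzero(basin == basin[ci])
        for s in same:
            dist[sp, s] = network_distance(net, node[ci], node[s])
    with np.errstate(invalid="ignore"):  # 0 * inf across basins -> masked out
        logit_p = (
            a0 - a1 * dist
            - a2 * np.abs(precip[None, :] - precip[core_idx][:, None])
        )
        prob = np.where(
            np.isfinite(dist) & np.isfinite(logit_p), expit(logit_p), 0.0
        )
    presence = (rng.random((n_species, n_sites)) < prob).astype(np.int8).T

    empty = np.flatnonzero(presence.sum(axis=1) == 0)
    for s in empty:
        nearest = int(np.argmin(dist[:, s]))
        presence[s, nearest] = 1

    return CommunityMatrix(
        pd.DataFrame(
            presence,
            index=pd.Index(site_ids, name="site_id"),
            columns=[f"sp{j:04d}" for j in range(n_species)],
        )
    )


# ---------------------------------------------------------------------------
# configuration and file output
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All generator knobs, loadable from YAML."""

    n_basins: int = 11
    sites_per_basin: int = 30
    n_leaves: int = 64
    mean_edge_length_km: float = 6.0
    precip_base_mm: float = 3000.0
    precip_gradient_mm_per_km: float = 1.2
    precip_noise_sd: float = 30.0
    basin_spacing_km: float = 100.0
    n_species: int = 120
    occupancy_a0: float = 2.0
    occupancy_a1: float = 0.08
    occupancy_a2: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_simulation(config: SimulationConfig, out_dir: str | Path,
                   seed: int | None = None) -> dict:
    """Generate basins, sites and communities, and write all CSV outputs.

    Writes per-basin edge/node CSVs, a site table, the community table in
    long and wide form, and a provenance JSON recording the configuration
    and seed.  Returns a manifest of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)

    networks, sites = generate_basins(
        n_basins=config.n_basins,
        sites_per_basin=config.sites_per_basin,
        n_leaves=config.n_leaves,
        mean_edge_length_km=config.mean_edge_length_km,
        precip_base_mm=config.precip_base_mm,
        precip_gradient_mm_per_km=config.precip_gradient_mm_per_km,
        precip_noise_sd=config.precip_noise_sd,
        basin_spacing_km=config.basin_spacing_km,
        seed=rng,
    )
    communities = simulate_communities(
        sites,
        networks,
        n_species=config.n_species,
        occupancy_params=(config.occupancy_a0, config.occupancy_a1,
                          config.occupancy_a2),
        seed=rng,
    )

    manifest: dict = {"networks": {}}
    for b, net in networks.items():
        edges = out / f"basin{b:02d}_edges.csv"
        nodes = out / f"basin{b:02d}_nodes.csv"
        write_network_csv(net, edges, nodes)
        manifest["networks"][b] = {"edges": str(edges), "nodes": str(nodes)}
    sites_path = out / "sites.csv"
    sites.to_csv(sites_path, index=False)
    manifest["sites"] = str(sites_path)
    long_path, wide_path = out / "community_long.csv", out / "community_wide.csv"
    communities.to_long_csv(long_path)
    communities.to_wide_csv(wide_path)
    manifest["community_long"] = str(long_path)
    manifest["community_wide"] = str(wide_path)

    provenance = {"config": asdict(config), "seed": used_seed}
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    manifest["provenance"] = str(out / "provenance.json")
    return manifest
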