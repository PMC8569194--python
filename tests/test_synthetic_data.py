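"""Generator contracts: tree invariants, determinism, statistical structure."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import riverddcs as rd
from riverddcs import bayes_model
from riverddcs.network_metrics import read_network_csv


def _exhaustive_tree_check(net):
    """Brute-force connectivity/acyclicity audit, independent of networkx."""
    nodes = list(net.graph.nodes)
    edges = net.edge_list()
    assert len(edges) == len(nodes) - 1
    adjacency = {n: set() for n in nodes}
    for u, v, w in edges:
        assert w > 0
        adjacency[u].add(v)
        adjacency[v].add(u)
    seen, stack = {nodes[0]}, [nodes[0]]
    while stack:  # undirected DFS reaches every node exactly once
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    assert seen == set(nodes)
    out_degree = {n: 0 for n in nodes}
    for u, _, _ in edges:
        out_degree[u] += 1
    outlets = [n for n, d in out_degree.items() if d == 0]
    assert outlets == [net.outlet]
    assert all(d == 1 for n, d in out_degree.items() if n != net.outlet)


@pytest.mark.parametrize("n_leaves", [2, 8, 50])
def test_generated_network_invariants(n_leaves):
    net = rd.generate_network(n_leaves, seed=1)
    _exhaustive_tree_check(net)
    if n_leaves == 2:
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2
    # chord never exceeds channel length (meander >= 1)
    for u, v, length in net.edge_list():
        chord = rd.euclidean_distance(net.coordinates(u), net.coordinates(v))
        assert chord <= length + 1e-9


def test_generate_network_validates_arguments():
    with pytest.raises(ValueError):
        rd.generate_network(1)
    with pytest.raises(ValueError):
        rd.generate_network(4, mean_edge_length_km=0.0)


def test_seed_determinism():
    a = rd.generate_network(8, seed=1)
    b = rd.generate_network(8, seed=1)
    assert a.edge_list() == b.edge_list()
    assert all(a.coordinates(n) == b.coordinates(n) for n in a.graph.nodes)

    _, sites1 = rd.generate_basins(n_basins=2, sites_per_basin=5, n_leaves=8, seed=3)
    _, sites2 = rd.generate_basins(n_basins=2, sites_per_basin=5, n_leaves=8, seed=3)
    pd.testing.assert_frame_equal(sites1, sites2)


def test_generate_basins_bookkeeping():
    networks, sites = rd.generate_basins(n_basins=11, sites_per_basin=30, seed=2)
    assert len(sites) == 330
    assert set(sites["basin_id"]) == set(range(1, 12))
    assert len(networks) == 11
    # sites on distinct nodes within each basin
    for _, group in sites.groupby("basin_id"):
        assert group["node_id"].is_unique
    assert (sites["precip_mm"] >= 0).all()
    assert (sites["strahler_order"] >= 1).all()


def test_precipitation_noiseless_limit():
    _, sites = rd.generate_basins(
        n_basins=2, sites_per_basin=6, n_leaves=8, precip_noise_sd=0.0,
        precip_base_mm=1000.0, precip_gradient_mm_per_km=1.0, seed=4,
    )
    expected = 1000.0 - 1.0 * (sites["x_km"] + 0.3 * sites["y_km"])
    assert np.allclose(sites["precip_mm"], np.maximum(expected, 0.0))


def test_too_many_sites_raises():
    with pytest.raises(ValueError, match="exceeds"):
        rd.generate_basins(n_basins=1, sites_per_basin=100, n_leaves=8, seed=0)


def test_default_strahler_difference_range(default_design):
    """Default study conditions populate at least order-difference levels 0..4."""
    levels = set(np.unique(default_design.strahler_level))
    assert {0, 1, 2, 3, 4} <= levels


# ---- model-faithful similarity generator ---------------------------------


def _flat_params(n_sites, n_basins, kappa, **overrides):
    """Parameters at zero (scales epsilon) except the given overrides."""
    base = dict(
        alpha_baseline=0.0,
        alpha_s=np.zeros(n_sites),
        sigma_s=1e-9,
        alpha_c=np.zeros(n_basins),
        alpha_o=np.zeros(7),
        sigma_strahler=1e-9,
        beta_distance=np.zeros(n_basins),
        beta_flow=np.zeros(n_basins),
        beta_precip=np.zeros(n_basins),
        mu_distance=0.0,
        mu_flow=0.0,
        mu_precipitation=0.0,
        sigma_distance=1e-9,
        sigma_flow=1e-9,
        sigma_precipitation=1e-9,
        kappa=kappa,
    )
    base.update(overrides)
    return rd.TrueParameters(**base)


def test_uniform_limit_is_beta_1_1(default_design):
    """All parameters zero, kappa=2: similarities are U(0,1) draws."""
    truth = _flat_params(default_design.n_sites, default_design.n_basins, kappa=2.0)
    y = rd.simulate_sorensen_from_model(default_design, truth, seed=5)
    assert y.min() > 0 and y.max() < 1
    stat = stats.kstest(y[:2000], "uniform").statistic
    assert stat < 1.63 / np.sqrt(min(len(y), 2000))  # 1% critical value


def test_concentration_limit(default_design):
    truth = _flat_params(default_design.n_sites, default_design.n_basins, kappa=1e6)
    y = rd.simulate_sorensen_from_model(default_design, truth, seed=6)
    assert abs(y.mean() - 0.5) < 0.01


def test_kappa_must_be_positive(default_design):
    truth = _flat_params(default_design.n_sites, default_design.n_basins, kappa=1.0)
    truth.kappa = -1.0  # bypass constructor check to exercise the simulator's
    with pytest.raises(ValueError):
        rd.simulate_sorensen_from_model(default_design, truth, seed=0)


def test_similarity_seed_determinism(default_design):
    truth = _flat_params(default_design.n_sites, default_design.n_basins, kappa=10.0)
    y1 = rd.simulate_sorensen_from_model(default_design, truth, seed=9)
    y2 = rd.simulate_sorensen_from_model(default_design, truth, seed=9)
    assert np.array_equal(y1, y2)


def test_distance_slope_sign_recovered_by_ols(default_design):
    """OLS of logit(y) on transformed distance as a crude slope oracle."""
    n_basins = default_design.n_basins
    truth = _flat_params(
        default_design.n_sites, n_basins, kappa=30.0,
        beta_distance=np.full(n_basins, -0.4), mu_distance=-0.4,
    )
    y = rd.simulate_sorensen_from_model(default_design, truth, seed=7)
    assert len(y) >= 2000
    slope = stats.linregress(default_design.x_distance, np.log(y / (1 - y))).slope
    assert slope < 0
    assert slope == pytest.approx(-0.4, abs=0.1)


def test_beta_moments(default_design):
    """Sample mean -> mu and variance -> mu(1-mu)/(1+kappa) within 3 SE."""
    mu, kappa = 0.42, 12.0
    truth = _flat_params(
        default_design.n_sites, default_design.n_basins, kappa=kappa,
        alpha_baseline=float(np.log(mu / (1 - mu))),
    )
    rng = np.random.default_rng(8)
    draws = np.concatenate(
        [rd.simulate_sorensen_from_model(default_design, truth, seed=rng)
         for _ in range(4)]
    )[:10000]
    n = len(draws)
    var_expected = mu * (1 - mu) / (1 + kappa)
    se_mean = np.sqrt(var_expected / n)
    assert abs(draws.mean() - mu) < 3 * se_mean
    m4 = np.mean((draws - draws.mean()) ** 4)
    se_var = np.sqrt(max(m4 - var_expected**2, 0.0) / n)
    assert abs(draws.var(ddof=1) - var_expected) < 3 * se_var


def test_null_model_similarities_exchangeable(default_design):
    """With all effects zero, dyad similarities carry no covariate signal."""
    truth = _flat_params(default_design.n_sites, default_design.n_basins, kappa=8.0)
    y = rd.simulate_sorensen_from_model(default_design, truth, seed=10)
    rng = np.random.default_rng(11)
    observed = abs(np.corrcoef(default_design.x_distance, y)[0, 1])
    null = np.array(
        [
            abs(np.corrcoef(default_design.x_distance, rng.permutation(y))[0, 1])
            for _ in range(999)
        ]
    )
    assert observed < np.quantile(null, 0.99)


# ---- mechanistic community generator -------------------------------------


def test_saturated_occupancy(small_pipeline):
    sites, networks = small_pipeline["sites"], small_pipeline["networks"]
    matrix = rd.simulate_communities(
        sites, networks, n_species=20, occupancy_params=(50.0, 0.0, 0.0), seed=1
    )
    # every species everywhere within its own basin -> within-basin Sorensen 1
    table = rd.pairwise_sorensen(
        matrix, dict(zip(sites["site_id"], sites["basin_id"]))
    )
    assert (table["sorensen"] == 1.0).all()


def test_point_occupancy_limit(small_pipeline):
    sites, networks = small_pipeline["sites"], small_pipeline["networks"]
    matrix = rd.simulate_communities(
        sites, networks, n_species=40, occupancy_params=(2.0, 100.0, 0.0), seed=2
    )
    presence = matrix.data.to_numpy()
    # species confined to (essentially) their core sites
    assert presence.sum() <= 40 + len(sites)
    assert (presence.sum(axis=1) >= 1).all()  # every site still occupied


def test_similarity_decays_with_network_distance(small_pipeline):
    pairs = small_pipeline["pairs"]
    rho = stats.spearmanr(
        pairs["network_distance_km"], pairs["sorensen"]
    ).statistic
    assert rho < 0


def test_run_simulation_outputs(tmp_path):
    config = rd.SimulationConfig(
        n_basins=2, sites_per_basin=5, n_leaves=8, n_species=20, seed=5
    )
    manifest = rd.run_simulation(config, tmp_path)
    sites = pd.read_csv(manifest["sites"])
    assert len(sites) == 10
    with open(tmp_path / "provenance.json") as fh:
        prov = json.load(fh)
    assert prov["seed"] == 5 and prov["config"]["n_basins"] == 2
    net = read_network_csv(
        tmp_path / "basin01_edges.csv", tmp_path / "basin01_nodes.csv"
    )
    _exhaustive_tree_check(net)
    wide = rd.CommunityMatrix.from_wide_csv(manifest["community_wide"])
    long = rd.CommunityMatrix.from_long_csv(manifest["community_long"])
    for site in wide.site_ids:
        assert wide.species_set(site) == long.species_set(site)


def test_yaml_config_round_trip(tmp_path):
    config = rd.SimulationConfig(n_basins=3, seed=9)
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    assert rd.SimulationConfig.from_yaml(path) == config
    path.write_text("not_a_knob: 1\n")
    with pytest.raises(KeyError):
        rd.SimulationConfig.from_yaml(path)
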