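"""Shared fixtures: small synthetic pipelines reused across test modules.

Expensive objects (the full default-scale design, a fitted small model) are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import riverddcs as rd

settings.register_profile(
    "ci", derandomize=True, database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_pipeline(n_basins, sites_per_basin, seed, n_species=60, **kw):
    """Run generate -> communities -> sorensen -> covariates -> filter -> design."""
    rng = np.random.default_rng(seed)
    networks, sites = rd.generate_basins(
        n_basins=n_basins, sites_per_basin=sites_per_basin, seed=rng, **kw
    )
    matrix = rd.simulate_communities(sites, networks, n_species=n_species, seed=rng)
    basin_of = dict(zip(sites["site_id"], sites["basin_id"]))
    sims = rd.pairwise_sorensen(matrix, basin_of)
    pairs = rd.build_pairs(sites, networks, sims)
    filtered, filt_report = rd.ratio_filter(pairs)
    design = rd.build_design(filtered if len(filtered) >= 10 else pairs)
    return {
        "networks": networks,
        "sites": sites,
        "matrix": matrix,
        "sims": sims,
        "pairs": pairs,
        "filtered": filtered,
        "filter_report": filt_report,
        "design": design,
    }


@pytest.fixture(scope="session")
def small_pipeline():
    """Two basins x 10 sites: fast end-to-end fixture."""
    return build_pipeline(n_basins=2, sites_per_basin=10, n_leaves=16, seed=11)


@pytest.fixture(scope="session")
def default_design():
    """Design table at the default study scale (11 basins x 30 sites)."""
    return build_pipeline(n_basins=11, sites_per_basin=30, seed=7)["design"]


@pytest.fixture(scope="session")
def tiny_fit():
    """A small model fitted to data simulated from known parameters.

    Returns (design, truth, draws); reused by sampler, diagnostics and
    reporting tests.
    """
    pipe = build_pipeline(n_basins=2, sites_per_basin=10, n_leaves=16, seed=11)
    design = pipe["design"]
    truth = rd.make_true_parameters(design.n_sites, design.n_basins, seed=21)
    design.y = rd.simulate_sorensen_from_model(design, truth, seed=22)
    draws = rd.fit(
        design, chains=2, warmup=300, sampling=300, seed=23, target_accept=0.9
    )
    return design, truth, draws


@pytest.fixture()
def ratio_fixture():
    """Ten pairs with known network/Euclidean ratios {1.0 ... 8}."""
    ratios = [1.0, 1.5, 2.0, 2.1, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    return pd.DataFrame(
        {
            "site_a": [f"a{i}" for i in range(10)],
            "site_b": [f"b{i}" for i in range(10)],
            "basin_id": 1,
            "sorensen": 0.5,
            "network_distance_km": [10.0 * r for r in ratios],
            "euclidean_distance_km": 10.0,
            "flow_connection": 0,
            "strahler_difference": 0,
            "precipitation_difference_mm": 0.0,
        }
    )
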