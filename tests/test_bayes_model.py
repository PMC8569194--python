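"""Likelihood, priors, gradients, NUTS sampling and diagnostics."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

import riverddcs as rd
from riverddcs import bayes_model as bm
from riverddcs._nuts import sample_nuts
from riverddcs.bayes_model import _Packer, _PreparedDesign, _logp_and_grad


def _zero_params(n_sites, n_basins, kappa=2.0, **overrides):
    fields = dict(
        alpha_baseline=0.0, alpha_s=np.zeros(n_sites), sigma_s=1e-9,
        alpha_c=np.zeros(n_basins), alpha_o=np.zeros(7), sigma_strahler=1e-9,
        beta_distance=np.zeros(n_basins), beta_flow=np.zeros(n_basins),
        beta_precip=np.zeros(n_basins), mu_distance=0.0, mu_flow=0.0,
        mu_precipitation=0.0, sigma_distance=1e-9, sigma_flow=1e-9,
        sigma_precipitation=1e-9, kappa=kappa,
    )
    fields.update(overrides)
    return rd.ModelParameters(**fields)


def _swapped_roles(design):
    import copy

    other = copy.copy(design)
    other.site1, other.site2 = design.site2.copy(), design.site1.copy()
    return other


# ---- linear predictor ----------------------------------------------------


def test_linear_predictor_values_and_symmetry(small_pipeline):
    design = small_pipeline["design"]
    params = _zero_params(design.n_sites, design.n_basins)
    eta = rd.linear_predictor(params, design)
    assert np.allclose(expit(eta), 0.5)  # all parameters zero -> mu = 1/2

    params.alpha_baseline = 0.3
    eta = rd.linear_predictor(params, design)
    assert np.allclose(expit(eta), 0.5744, atol=1e-4)

    rng = np.random.default_rng(0)
    params.alpha_s = rng.normal(size=design.n_sites)
    assert np.allclose(
        rd.linear_predictor(params, design),
        rd.linear_predictor(params, _swapped_roles(design)),
    )


def test_linear_predictor_index_bounds(small_pipeline):
    design = small_pipeline["design"]
    params = _zero_params(design.n_sites - 1, design.n_basins)
    with pytest.raises(IndexError):
        rd.linear_predictor(params, design)


# ---- beta log density ----------------------------------------------------


def test_beta_log_density_closed_forms():
    for y in (0.1, 0.5, 0.93):
        assert rd.beta_log_density(y, 0.5, 2.0) == pytest.approx(0.0)  # Beta(1,1)
    assert rd.beta_log_density(0.5, 0.5, 4.0) == pytest.approx(np.log(1.5))


def test_beta_log_density_integrates_to_one():
    rng = np.random.default_rng(2)
    for _ in range(20):
        mu = rng.uniform(0.05, 0.95)
        kappa = rng.uniform(0.5, 60.0)
        total, _ = integrate.quad(
            lambda y: np.exp(rd.beta_log_density(y, mu, kappa)), 0.0, 1.0
        )
        assert total == pytest.approx(1.0, abs=1e-6)


def test_beta_log_density_matches_scipy_to_1e8():
    grid_y = np.linspace(0.01, 0.99, 25)
    for mu in (0.2, 0.5, 0.8):
        for kappa in (0.7, 5.0, 40.0):
            ours = rd.beta_log_density(grid_y, mu, kappa)
            ref = stats.beta.logpdf(grid_y, mu * kappa, (1 - mu) * kappa)
            assert np.allclose(ours, ref, atol=1e-8)


def test_beta_log_density_boundary_and_domain_errors():
    with pytest.raises(ValueError):
        rd.beta_log_density(0.0, 0.5, 2.0)
    with pytest.raises(ValueError):
        rd.beta_log_density(1.0, 0.5, 2.0)
    with pytest.raises(ValueError):
        rd.beta_log_density(0.5, 0.5, -1.0)


def test_squeeze_boundary():
    y = np.array([0.0, 0.5, 1.0])
    squeezed = rd.squeeze_boundary(y, n=100)
    assert squeezed[0] > 0 and squeezed[-1] < 1
    assert squeezed[1] == pytest.approx(0.5)


# ---- log posterior -------------------------------------------------------


def test_log_posterior_symmetric_under_role_swap(tiny_fit):
    design, _, _ = tiny_fit
    pk = _Packer(design.n_sites, design.n_basins)
    rng = np.random.default_rng(3)
    theta = 0.3 * rng.standard_normal(pk.dim)
    lp_a = bm.log_posterior(theta, design)
    lp_b = bm.log_posterior(theta, _swapped_roles(design))
    assert lp_a == pytest.approx(lp_b, rel=1e-12)


def test_gradient_matches_finite_differences(tiny_fit):
    design, _, _ = tiny_fit
    pk = _Packer(design.n_sites, design.n_basins)
    prep = _PreparedDesign(design)
    rng = np.random.default_rng(4)
    theta = 0.3 * rng.standard_normal(pk.dim)
    theta[pk.log_kappa] = np.log(15.0)
    _, grad = _logp_and_grad(theta, pk, prep)
    h = 1e-6
    for i in range(pk.dim):
        up, down = theta.copy(), theta.copy()
        up[i] += h
        down[i] -= h
        fd = (_logp_and_grad(up, pk, prep)[0] - _logp_and_grad(down, pk, prep)[0]) / (
            2 * h
        )
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_boundary_observations_rejected_or_squeezed(small_pipeline):
    design = small_pipeline["design"]
    bad = _swapped_roles(design)  # cheap structural copy
    bad.y = design.y.copy()
    bad.y[0] = 1.0
    with pytest.raises(ValueError, match="boundary|squeeze"):
        rd.fit(bad, chains=1, warmup=10, sampling=5, seed=0)
    prep = _PreparedDesign(bad, boundary="squeeze")
    assert 0.0 < prep.y[0] < 1.0


# ---- prior predictive ----------------------------------------------------


def test_prior_predictive_determinism_and_summary(small_pipeline):
    design = small_pipeline["design"]
    a = rd.prior_predictive(design, n_draws=50, seed=6)
    b = rd.prior_predictive(design, n_draws=50, seed=6)
    assert np.array_equal(a.draws, b.draws)
    assert a.draws.shape == (50, design.n_dyads)
    assert np.all((a.draws > 0) & (a.draws < 1))
    assert np.all((a.mass_in_band >= 0) & (a.mass_in_band <= 1))


def test_degenerate_prior_limit_concentrates_at_half(small_pipeline):
    """Scales near zero and a huge kappa collapse similarities onto 0.5."""
    design = small_pipeline["design"]
    params = _zero_params(design.n_sites, design.n_basins, kappa=1e8)
    y = bm.simulate_similarities(params, design, np.random.default_rng(7))
    assert np.all(np.abs(y - 0.5) < 1e-3)


# ---- NUTS sampler --------------------------------------------------------


def test_nuts_recovers_gaussian_moments():
    """Standard 10-d normal: draws match known mean and variance."""
    dim = 10

    def logp_grad(q):
        return -0.5 * float(q @ q), -q

    res = sample_nuts(
        logp_grad, np.zeros(dim), n_warmup=500, n_draws=2000,
        rng=np.random.default_rng(8),
    )
    assert res.draws.shape == (2000, dim)
    assert not res.diverging.any()
    assert np.all(np.abs(res.draws.mean(axis=0)) < 0.15)
    assert np.all(np.abs(res.draws.std(axis=0) - 1.0) < 0.15)


def test_nuts_handles_correlated_target():
    cov = np.array([[1.0, 0.9], [0.9, 1.0]])
    prec = np.linalg.inv(cov)

    def logp_grad(q):
        g = -prec @ q
        return 0.5 * float(q @ g), g

    res = sample_nuts(
        logp_grad, np.zeros(2), n_warmup=500, n_draws=3000,
        rng=np.random.default_rng(9),
    )
    sample_cov = np.cov(res.draws.T)
    assert np.allclose(sample_cov, cov, atol=0.2)


def test_fit_is_deterministic_given_seed(tiny_fit):
    design, _, _ = tiny_fit
    a = rd.fit(design, chains=1, warmup=100, sampling=50, seed=42)
    b = rd.fit(design, chains=1, warmup=100, sampling=50, seed=42)
    for key in a.posterior:
        assert np.array_equal(a.posterior[key], b.posterior[key])


def test_fit_recovers_negative_distance_slope(tiny_fit):
    """Data simulated with mu_distance < 0 yield a negative posterior mean."""
    design, truth, draws = tiny_fit
    assert truth.mu_distance == -0.4
    assert draws.flat("mu_distance").mean() < 0


def test_posterior_contraction_with_more_dyads(tiny_fit):
    """Doubling the dyad count must not widen the mu_distance interval."""
    from conftest import build_pipeline

    design_small, _, _ = tiny_fit
    pipe_big = build_pipeline(n_basins=2, sites_per_basin=15, n_leaves=16, seed=11)
    design_big = pipe_big["design"]
    assert design_big.n_dyads >= 1.8 * design_small.n_dyads
    truth_big = rd.make_true_parameters(
        design_big.n_sites, design_big.n_basins, seed=21
    )
    design_big.y = rd.simulate_sorensen_from_model(design_big, truth_big, seed=22)
    fit_small = rd.fit(design_small, chains=2, warmup=300, sampling=300, seed=31)
    fit_big = rd.fit(design_big, chains=2, warmup=300, sampling=300, seed=31)

    def width(fit):
        lo, hi = np.quantile(fit.flat("mu_distance"), [0.025, 0.975])
        return hi - lo

    assert width(fit_big) <= 1.1 * width(fit_small)  # 10% Monte-Carlo slack


def test_posterior_agrees_with_independent_ensemble_sampler():
    """Cross-check NUTS against emcee on the same small log posterior."""
    emcee = pytest.importorskip("emcee")
    from conftest import build_pipeline

    pipe = build_pipeline(n_basins=1, sites_per_basin=6, n_leaves=12, seed=51)
    design = pipe["design"]
    truth = rd.make_true_parameters(design.n_sites, design.n_basins, seed=52)
    design.y = rd.simulate_sorensen_from_model(design, truth, seed=53)
    draws = rd.fit(design, chains=2, warmup=400, sampling=600, seed=54,
                   target_accept=0.9)

    pk = _Packer(design.n_sites, design.n_basins)
    prep = _PreparedDesign(design)

    def logp(theta):
        return _logp_and_grad(theta, pk, prep)[0]

    rng = np.random.default_rng(12)
    n_walkers = 4 * pk.dim
    p0 = 0.05 * rng.standard_normal((n_walkers, pk.dim))
    p0[:, pk.log_kappa.start] = np.log(10.0) + 0.05 * rng.standard_normal(n_walkers)
    sampler = emcee.EnsembleSampler(n_walkers, pk.dim, logp)
    state = sampler.run_mcmc(p0, 6000, progress=False)
    assert state is not None
    flat = sampler.get_chain(discard=3000, thin=10, flat=True)
    ens_mu = np.array([pk.constrain(t).mu_distance for t in flat])
    ens_log_kappa = flat[:, pk.log_kappa.start]
    assert draws.flat("mu_distance").mean() == pytest.approx(
        ens_mu.mean(), abs=0.08
    )
    assert np.log(draws.flat("kappa")).mean() == pytest.approx(
        ens_log_kappa.mean(), abs=0.15
    )


# ---- diagnostics ---------------------------------------------------------


def _pseudo_draws(arr, diverging=None, deep=None):
    c, d = arr.shape[:2]
    stats_ = {
        "diverging": np.zeros((c, d), bool) if diverging is None else diverging,
        "treedepth": np.full((c, d), 3),
        "max_treedepth_hit": np.zeros((c, d), bool) if deep is None else deep,
        "accept_stat": np.full((c, d), 0.9),
        "energy": np.zeros((c, d)),
    }
    return rd.PosteriorDraws(posterior={"theta": arr}, sample_stats=stats_)


def test_rhat_near_one_for_well_mixed_chains():
    rng = np.random.default_rng(13)
    draws = _pseudo_draws(rng.standard_normal((4, 2000)))
    report = rd.diagnostics(draws)
    assert 0.999 <= report.rhat["theta"] <= 1.01
    assert report.rhat_ok is True


def test_constant_chains_flagged():
    draws = _pseudo_draws(np.ones((4, 100)))
    report = rd.diagnostics(draws)
    assert np.isnan(report.rhat["theta"])
    assert report.rhat_ok is False


def test_injected_divergences_counted_exactly():
    rng = np.random.default_rng(14)
    div = np.zeros((4, 100), bool)
    div[1, [3, 40, 77]] = True
    div[3, 9] = True
    deep = np.zeros((4, 100), bool)
    deep[0, :2] = True
    draws = _pseudo_draws(rng.standard_normal((4, 100)), diverging=div, deep=deep)
    report = rd.diagnostics(draws)
    assert report.n_divergent == 4
    assert report.n_max_treedepth == 2
    assert report.no_divergences is False


def test_single_chain_rhat_unavailable():
    rng = np.random.default_rng(15)
    draws = _pseudo_draws(rng.standard_normal((1, 500)))
    report = rd.diagnostics(draws)
    assert report.rhat_ok is None
    assert np.isnan(report.rhat["theta"])
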