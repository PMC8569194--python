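"""Hierarchical Bayesian beta regression for pairwise community similarity.

Likelihood
----------
Each within-basin dyad's Sorensen index y is Beta-distributed under the
mean/sample-size parameterisation, ``y ~ Beta(mu * kappa, (1 - mu) * kappa)``,
with

    logit(mu) = alpha_baseline
              + alpha_s[site 1] + alpha_s[site 2]        (dyadic intercepts)
              + alpha_c[basin]                           (basin intercept)
              + alpha_o[strahler level]                  (order-difference level)
              + beta_distance[basin] * x_distance
              + beta_flow[basin]     * flow
              + beta_precip[basin]   * x_precip

The two additive site intercepts capture the dependence among all dyads that
share a census (a social-relations-style dyadic structure); the per-basin
slopes are partially pooled through Normal hyperpriors whose means
(mu_distance, mu_flow, mu_precipitation) are the quantities of headline
interest: the expected covariate effect in a new, unsampled basin.

Priors
------
    alpha_baseline ~ Normal(0, 0.3)
    alpha_s ~ Normal(0, sigma_s),            sigma_s ~ Exponential(1)
    alpha_c ~ Normal(0, 0.3)
    alpha_o ~ Normal(0, sigma_strahler),     sigma_strahler ~ Exponential(2)
    beta_*[basin] ~ Normal(mu_*, sigma_*)
    mu_* ~ Normal(0, 0.3),                   sigma_* ~ Exponential(2)
    kappa ~ half-Normal(50)     (positive support required by the Beta)

Fitting uses the package's NUTS sampler on the unconstrained scale with a
non-centered parameterisation for every hierarchical vector (site and
Strahler intercepts, the three slope families), log transforms for scales and
kappa, and analytic gradients throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from ._nuts import sample_nuts

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParameters",
    "PosteriorDraws",
    "DiagnosticsReport",
    "PriorPredictive",
    "linear_predictor",
    "beta_log_density",
    "squeeze_boundary",
    "sample_prior",
    "simulate_similarities",
    "prior_predictive",
    "fit",
    "diagnostics",
    "log_posterior",
]

# fixed prior constants, as printed in the model definition
SD_BASELINE = 0.3
SD_BASIN = 0.3
SD_HYPER_MEAN = 0.3
RATE_SIGMA_S = 1.0
RATE_SIGMA_STRAHLER = 2.0
RATE_SIGMA_SLOPE = 2.0
SD_KAPPA = 50.0


@dataclass
class ModelParameters:
    """One complete draw of the model: every symbol of the likelihood/priors."""

    alpha_baseline: float
    alpha_s: np.ndarray          # one per site (pooled across basins)
    sigma_s: float
    alpha_c: np.ndarray          # one per basin
    alpha_o: np.ndarray          # 7 Strahler-difference levels
    sigma_strahler: float
    beta_distance: np.ndarray    # per-basin slopes
    beta_flow: np.ndarray
    beta_precip: np.ndarray
    mu_distance: float
    mu_flow: float
    mu_precipitation: float
    sigma_distance: float
    sigma_flow: float
    sigma_precipitation: float
    kappa: float

    def __post_init__(self) -> None:
        for name in ("sigma_s", "sigma_strahler", "sigma_distance",
                     "sigma_flow", "sigma_precipitation", "kappa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        b = len(self.alpha_c)
        for name in ("beta_distance", "beta_flow", "beta_precip"):
            if len(getattr(self, name)) != b:
                raise ValueError(f"{name} length must match alpha_c")

    @property
    def n_sites(self) -> int:
        return len(self.alpha_s)

    @property
    def n_basins(self) -> int:
        return len(self.alpha_c)


def linear_predictor(params: ModelParameters, design) -> np.ndarray:
    """Logit-scale mean similarity for every dyad of a design table.

    Symmetric in the two site roles: the dyadic intercepts enter additively.
    """
    for idx, bound in (
        (design.site1, params.n_sites),
        (design.site2, params.n_sites),
        (design.basin, params.n_basins),
        (design.strahler_level, len(params.alpha_o)),
    ):
        if len(idx) and (idx.min() < 0 or idx.max() >= bound):
            raise IndexError("design index out of range for parameter vector")
    return (
        params.alpha_baseline
        + params.alpha_s[design.site1]
        + params.alpha_s[design.site2]
        + params.alpha_c[design.basin]
        + params.alpha_o[design.strahler_level]
        + params.beta_distance[design.basin] * design.x_distance
        + params.beta_flow[design.basin] * design.flow
        + params.beta_precip[design.basin] * design.x_precip
    )


def beta_log_density(y, mu, kappa) -> np.ndarray | float:
    """Log density of Beta(mu * kappa, (1 - mu) * kappa) at y.

    All of ``y`` must lie strictly inside (0, 1); boundary observations make
    the Beta likelihood improper and raise instead (see
    :func:`squeeze_boundary` for the documented adjustment).
    """
    y_arr, mu_arr = np.asarray(y, float), np.asarray(mu, float)
    if np.any(y_arr <= 0) or np.any(y_arr >= 1):
        raise ValueError(
            "similarity values on the boundary {0,1}; apply squeeze_boundary "
            "or drop the offending dyads before evaluating the likelihood"
        )
    if np.any(mu_arr <= 0) or np.any(mu_arr >= 1) or not np.all(np.asarray(kappa) > 0):
        raise ValueError("require 0 < mu < 1 and kappa > 0")
    a = mu_arr * kappa
    b = (1.0 - mu_arr) * kappa
    out = (
        gammaln(a + b) - gammaln(a) - gammaln(b)
        + (a - 1.0) * np.log(y_arr)
        + (b - 1.0) * np.log1p(-y_arr)
    )
    return float(out) if np.isscalar(y) and np.isscalar(mu) else out


def squeeze_boundary(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress observations from [0,1] into (0,1): ``(y*(n-1) + 0.5) / n``.

    ``n`` defaults to the number of observations.  The adjustment is the
    standard one for beta-likelihood models whose data can touch the
    boundary; it is opt-in and leaves interior values almost unchanged.
    """
    y = np.asarray(y, dtype=float)
    if n is None:
        n = len(y)
    if n < 2:
        raise ValueError("need n >= 2 to squeeze")
    return (y * (n - 1) + 0.5) / n


# ---------------------------------------------------------------------------
# unconstrained parameter vector packing
# ---------------------------------------------------------------------------


class _Packer:
    """Slices of the unconstrained vector for S sites and B basins.

    Layout: [alpha_baseline, z_s (S), log sigma_s, alpha_c (B), z_o (7),
    log sigma_strahler, z_d (B), z_f (B), z_p (B), mu_d, mu_f, mu_p,
    log sigma_d, log sigma_f, log sigma_p, log kappa].
    """

    def __init__(self, n_sites: int, n_basins: int, n_levels: int = 7):
        self.S, self.B, self.O = n_sites, n_basins, n_levels
        i = 0

        def block(k):
            nonlocal i
            s = slice(i, i + k)
            i += k
            return s

        self.alpha_baseline = block(1)
        self.z_s = block(n_sites)
        self.log_sigma_s = block(1)
        self.alpha_c = block(n_basins)
        self.z_o = block(n_levels)
        self.log_sigma_strahler = block(1)
        self.z_d = block(n_basins)
        self.z_f = block(n_basins)
        self.z_p = block(n_basins)
        self.mu = block(3)
        self.log_sigma_slopes = block(3)
        self.log_kappa = block(1)
        self.dim = i

    def constrain(self, theta: np.ndarray) -> ModelParameters:
        sigma_s = float(np.exp(theta[self.log_sigma_s][0]))
        sigma_o = float(np.exp(theta[self.log_sigma_strahler][0]))
        sd, sf, sp = np.exp(theta[self.log_sigma_slopes])
        mu_d, mu_f, mu_p = theta[self.mu]
        return ModelParameters(
            alpha_baseline=float(theta[self.alpha_baseline][0]),
            alpha_s=sigma_s * theta[self.z_s],
            sigma_s=sigma_s,
            alpha_c=theta[self.alpha_c].copy(),
            alpha_o=sigma_o * theta[self.z_o],
            sigma_strahler=sigma_o,
            beta_distance=mu_d + sd * theta[self.z_d],
            beta_flow=mu_f + sf * theta[self.z_f],
            beta_precip=mu_p + sp * theta[self.z_p],
            mu_distance=float(mu_d),
            mu_flow=float(mu_f),
            mu_precipitation=float(mu_p),
            sigma_distance=float(sd),
            sigma_flow=float(sf),
            sigma_precipitation=float(sp),
            kappa=float(np.exp(theta[self.log_kappa][0])),
        )

    def unconstrain(self, p: ModelParameters) -> np.ndarray:
        theta = np.empty(self.dim)
        theta[self.alpha_baseline] = p.alpha_baseline
        theta[self.z_s] = p.alpha_s / p.sigma_s
        theta[self.log_sigma_s] = np.log(p.sigma_s)
        theta[self.alpha_c] = p.alpha_c
        theta[self.z_o] = p.alpha_o / p.sigma_strahler
        theta[self.log_sigma_strahler] = np.log(p.sigma_strahler)
        theta[self.z_d] = (p.beta_distance - p.mu_distance) / p.sigma_distance
        theta[self.z_f] = (p.beta_flow - p.mu_flow) / p.sigma_flow
        theta[self.z_p] = (p.beta_precip - p.mu_precipitation) / p.sigma_precipitation
        theta[self.mu] = [p.mu_distance, p.mu_flow, p.mu_precipitation]
        theta[self.log_sigma_slopes] = np.log(
            [p.sigma_distance, p.sigma_flow, p.sigma_precipitation]
        )
        theta[self.log_kappa] = np.log(p.kappa)
        return theta


class _PreparedDesign:
    """Design arrays plus cached log(y), log(1-y) for fast likelihood calls."""

    def __init__(self, design, boundary: str = "error"):
        y = np.asarray(design.y, dtype=float)
        if np.any(y <= 0) or np.any(y >= 1):
            if boundary == "squeeze":
                logger.warning(
                    "boundary Sorensen values squeezed into (0,1) before fitting"
                )
                y = squeeze_boundary(y)
            else:
                raise ValueError(
                    "Sorensen values exactly 0 or 1 are outside the support of "
                    "the Beta likelihood; refit with boundary='squeeze' to apply "
                    "the documented compression, or drop those dyads"
                )
        self.y = y
        self.log_y = np.log(y)
        self.log_1my = np.log1p(-y)
        self.site1 = np.asarray(design.site1, int)
        self.site2 = np.asarray(design.site2, int)
        self.basin = np.asarray(design.basin, int)
        self.level = np.asarray(design.strahler_level, int)
        self.x_d = np.asarray(design.x_distance, float)
        self.x_f = np.asarray(design.flow, float)
        self.x_p = np.asarray(design.x_precip, float)
        self.n_sites = design.n_sites
        self.n_basins = design.n_basins
        self.n_levels = design.n_strahler_levels


_LOG_HALF_NORMAL_CONST = 0.5 * np.log(2.0 / np.pi)


def _logp_and_grad(theta: np.ndarray, pk: _Packer, d: _PreparedDesign):
    """Log posterior density and gradient on the unconstrained scale.

    Includes the Jacobian terms of the log transforms for the scale
    parameters and kappa.  Returns (-inf, zeros) off the numerical support.
    """
    S, B, O = pk.S, pk.B, pk.O
    ab = theta[pk.alpha_baseline][0]
    z_s = theta[pk.z_s]
    ls = theta[pk.log_sigma_s][0]
    ac = theta[pk.alpha_c]
    z_o = theta[pk.z_o]
    lo = theta[pk.log_sigma_strahler][0]
    z_d, z_f, z_p = theta[pk.z_d], theta[pk.z_f], theta[pk.z_p]
    mu_d, mu_f, mu_p = theta[pk.mu]
    ld, lf, lp = theta[pk.log_sigma_slopes]
    lk = theta[pk.log_kappa][0]

    with np.errstate(over="ignore"):
        sigma_s, sigma_o = np.exp(ls), np.exp(lo)
        sd, sf, sp = np.exp(ld), np.exp(lf), np.exp(lp)
        kappa = np.exp(lk)
    if not np.all(np.isfinite([sigma_s, sigma_o, sd, sf, sp, kappa])):
        return -np.inf, np.zeros(pk.dim)

    alpha_s = sigma_s * z_s
    alpha_o = sigma_o * z_o
    b1 = mu_d + sd * z_d
    b2 = mu_f + sf * z_f
    b3 = mu_p + sp * z_p

    eta = (
        ab
        + alpha_s[d.site1] + alpha_s[d.site2]
        + ac[d.basin] + alpha_o[d.level]
        + b1[d.basin] * d.x_d + b2[d.basin] * d.x_f + b3[d.basin] * d.x_p
    )
    mu = expit(eta)
    eps = 1e-12
    mu = np.clip(mu, eps, 1.0 - eps)
    a_sh = mu * kappa
    b_sh = (1.0 - mu) * kappa

    with np.errstate(all="ignore"):  # off-support values handled below
        loglik = np.sum(
            gammaln(kappa) - gammaln(a_sh) - gammaln(b_sh)
            + (a_sh - 1.0) * d.log_y + (b_sh - 1.0) * d.log_1my
        )
    if not np.isfinite(loglik):
        return -np.inf, np.zeros(pk.dim)

    # log priors (constants dropped) + log-Jacobians of the transforms
    logp = loglik
    logp += -0.5 * ab**2 / SD_BASELINE**2
    logp += -0.5 * np.sum(z_s**2) - 0.5 * np.sum(z_o**2)
    logp += -0.5 * np.sum(ac**2) / SD_BASIN**2
    logp += -0.5 * (np.sum(z_d**2) + np.sum(z_f**2) + np.sum(z_p**2))
    logp += -0.5 * (mu_d**2 + mu_f**2 + mu_p**2) / SD_HYPER_MEAN**2
    logp += -RATE_SIGMA_S * sigma_s + ls
    logp += -RATE_SIGMA_STRAHLER * sigma_o + lo
    logp += -RATE_SIGMA_SLOPE * (sd + sf + sp) + ld + lf + lp
    logp += -0.5 * kappa**2 / SD_KAPPA**2 + lk  # half-normal, kappa > 0

    # gradient of the likelihood wrt eta and kappa
    dg_a, dg_b = digamma(a_sh), digamma(b_sh)
    g_mu = kappa * (d.log_y - d.log_1my - dg_a + dg_b)
    w = g_mu * mu * (1.0 - mu)                       # dloglik / deta per dyad
    dkap = np.sum(
        digamma(kappa) - mu * dg_a - (1.0 - mu) * dg_b
        + mu * d.log_y + (1.0 - mu) * d.log_1my
    )

    grad = np.zeros(pk.dim)
    grad[pk.alpha_baseline] = np.sum(w) - ab / SD_BASELINE**2
    g_as = np.bincount(d.site1, w, minlength=S) + np.bincount(d.site2, w, minlength=S)
    grad[pk.z_s] = g_as * sigma_s - z_s
    grad[pk.log_sigma_s] = np.dot(g_as, z_s) * sigma_s - RATE_SIGMA_S * sigma_s + 1.0
    grad[pk.alpha_c] = np.bincount(d.basin, w, minlength=B) - ac / SD_BASIN**2
    g_ao = np.bincount(d.level, w, minlength=O)
    grad[pk.z_o] = g_ao * sigma_o - z_o
    grad[pk.log_sigma_strahler] = (
        np.dot(g_ao, z_o) * sigma_o - RATE_SIGMA_STRAHLER * sigma_o + 1.0
    )
    g_b1 = np.bincount(d.basin, w * d.x_d, minlength=B)
    g_b2 = np.bincount(d.basin, w * d.x_f, minlength=B)
    g_b3 = np.bincount(d.basin, w * d.x_p, minlength=B)
    grad[pk.z_d] = g_b1 * sd - z_d
    grad[pk.z_f] = g_b2 * sf - z_f
    grad[pk.z_p] = g_b3 * sp - z_p
    grad[pk.mu] = [
        np.sum(g_b1) - mu_d / SD_HYPER_MEAN**2,
        np.sum(g_b2) - mu_f / SD_HYPER_MEAN**2,
        np.sum(g_b3) - mu_p / SD_HYPER_MEAN**2,
    ]
    grad[pk.log_sigma_slopes] = [
        np.dot(g_b1, z_d) * sd - RATE_SIGMA_SLOPE * sd + 1.0,
        np.dot(g_b2, z_f) * sf - RATE_SIGMA_SLOPE * sf + 1.0,
        np.dot(g_b3, z_p) * sp - RATE_SIGMA_SLOPE * sp + 1.0,
    ]
    grad[pk.log_kappa] = (dkap - kappa / SD_KAPPA**2) * kappa + 1.0
    return float(logp), grad


def log_posterior(theta: np.ndarray, design, boundary: str = "error") -> float:
    """Unnormalised log posterior on the unconstrained scale (for testing)."""
    pk = _Packer(design.n_sites, design.n_basins, design.n_strahler_levels)
    return _logp_and_grad(np.asarray(theta, float), pk, _PreparedDesign(design, boundary))[0]


# ---------------------------------------------------------------------------
# prior sampling and simulation
# ---------------------------------------------------------------------------


def sample_prior(
    rng: np.random.Generator, n_sites: int, n_basins: int, n_levels: int = 7
) -> ModelParameters:
    """One joint draw of every parameter from the Priors block."""
    sigma_s = rng.exponential(1.0 / RATE_SIGMA_S)
    sigma_o = rng.exponential(1.0 / RATE_SIGMA_STRAHLER)
    sd, sf, sp = rng.exponential(1.0 / RATE_SIGMA_SLOPE, size=3)
    mu_d, mu_f, mu_p = rng.normal(0.0, SD_HYPER_MEAN, size=3)
    kappa = abs(rng.normal(0.0, SD_KAPPA))
    while kappa == 0.0:  # guard the measure-zero boundary
        kappa = abs(rng.normal(0.0, SD_KAPPA))
    return ModelParameters(
        alpha_baseline=rng.normal(0.0, SD_BASELINE),
        alpha_s=rng.normal(0.0, sigma_s, size=n_sites),
        sigma_s=sigma_s,
        alpha_c=rng.normal(0.0, SD_BASIN, size=n_basins),
        alpha_o=rng.normal(0.0, sigma_o, size=n_levels),
        sigma_strahler=sigma_o,
        beta_distance=rng.normal(mu_d, sd, size=n_basins),
        beta_flow=rng.normal(mu_f, sf, size=n_basins),
        beta_precip=rng.normal(mu_p, sp, size=n_basins),
        mu_distance=mu_d,
        mu_flow=mu_f,
        mu_precipitation=mu_p,
        sigma_distance=sd,
        sigma_flow=sf,
        sigma_precipitation=sp,
        kappa=kappa,
    )


def simulate_similarities(
    params: ModelParameters, design, rng: np.random.Generator
) -> np.ndarray:
    """Draw one Sorensen value per dyad from the likelihood at ``params``."""
    if not params.kappa > 0:
        raise ValueError("kappa must be strictly positive")
    mu = expit(linear_predictor(params, design))
    eps = 1e-12
    mu = np.clip(mu, eps, 1.0 - eps)
    y = rng.beta(mu * params.kappa, (1.0 - mu) * params.kappa)
    return np.clip(y, 1e-9, 1.0 - 1e-9)  # keep strictly inside (0,1)


@dataclass
class PriorPredictive:
    """Prior predictive draws plus the band-mass summary used to vet priors."""

    draws: np.ndarray          # (n_draws, n_dyads)
    mass_in_band: np.ndarray   # (n_draws,) fraction of each draw in the band
    band: tuple[float, float]

    @property
    def median_mass(self) -> float:
        return float(np.median(self.mass_in_band))


def prior_predictive(
    design,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] = (0.25, 0.65),
) -> PriorPredictive:
    """Simulate Sorensen distributions from the prior model.

    Each draw samples every parameter from the Priors block, then one
    similarity per dyad from the likelihood.  The summary records, per draw,
    the fraction of simulated similarities inside ``band`` — the prior was
    designed to put most samples between 25% and 65% shared species.
    """
    if design.n_dyads == 0:
        raise ValueError("design table is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.empty((n_draws, design.n_dyads))
    for i in range(n_draws):
        params = sample_prior(rng, design.n_sites, design.n_basins,
                              design.n_strahler_levels)
        draws[i] = simulate_similarities(params, design, rng)
    lo, hi = band
    mass = np.mean((draws >= lo) & (draws <= hi), axis=1)
    return PriorPredictive(draws=draws, mass_in_band=mass, band=band)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Posterior draws indexed by (chain, iteration) plus sampler metadata."""

    posterior: dict            # name -> array (chain, draw, *shape)
    sample_stats: dict         # diverging, treedepth, ... -> (chain, draw)
    config: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.posterior.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.posterior.values())).shape[1]

    def parameters(self, chain: int, draw: int) -> ModelParameters:
        p = self.posterior
        return ModelParameters(
            **{
                f.name: (
                    np.asarray(p[f.name][chain, draw])
                    if p[f.name].ndim == 3
                    else float(p[f.name][chain, draw])
                )
                for f in dataclass_fields(ModelParameters)
            }
        )

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains stacked: (chain*draw, *shape)."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={k: v for k, v in self.posterior.items()},
            sample_stats={
                "diverging": self.sample_stats["diverging"].astype(bool),
                "treedepth": self.sample_stats["treedepth"],
                "acceptance_rate": self.sample_stats["accept_stat"],
                "energy": self.sample_stats["energy"],
            },
        )

    # ---- tidy CSV I/O ---------------------------------------------------

    def scalar_names(self) -> list[str]:
        """Flattened parameter names, vectors expanded as name[i]."""
        names = []
        for key, arr in self.posterior.items():
            if arr.ndim == 2:
                names.append(key)
            else:
                names.extend(f"{key}[{i}]" for i in range(arr.shape[2]))
        return names

    def scalar_draws(self, name: str) -> np.ndarray:
        """(chain, draw) array for one flattened parameter name."""
        if "[" in name:
            base, idx = name[:-1].split("[")
            return self.posterior[base][:, :, int(idx)]
        return self.posterior[name]

    def to_csv(self, path: str | Path) -> None:
        """Tidy CSV: one row per (chain, iteration, parameter, value)."""
        frames = []
        for name in self.scalar_names():
            arr = self.scalar_draws(name)
            c, d = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "iteration": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorDraws":
        tidy = pd.read_csv(path)
        n_chains = tidy["chain"].max() + 1
        n_draws = tidy["iteration"].max() + 1
        posterior: dict = {}
        vectors: dict = {}
        for name, group in tidy.groupby("parameter", sort=False):
            arr = group.sort_values(["chain", "iteration"])["value"].to_numpy()
            arr = arr.reshape(n_chains, n_draws)
            if "[" in name:
                base, idx = name[:-1].split("[")
                vectors.setdefault(base, {})[int(idx)] = arr
            else:
                posterior[name] = arr
        for base, parts in vectors.items():
            posterior[base] = np.stack(
                [parts[i] for i in range(len(parts))], axis=2
            )
        stats = {
            "diverging": np.zeros((n_chains, n_draws), dtype=bool),
            "treedepth": np.zeros((n_chains, n_draws), dtype=int),
            "max_treedepth_hit": np.zeros((n_chains, n_draws), dtype=bool),
            "accept_stat": np.full((n_chains, n_draws), np.nan),
            "energy": np.full((n_chains, n_draws), np.nan),
        }
        return cls(posterior=posterior, sample_stats=stats,
                   config={"source": str(path)})


def fit(
    design,
    chains: int = 4,
    warmup: int = 1000,
    sampling: int = 2000,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    boundary: str = "error",
) -> PosteriorDraws:
    """Sample the posterior with NUTS.

    Chains are run sequentially with independent streams spawned from
    ``seed``; each is initialised from a mildly jittered prior-scale point.
    Divergent transitions are reported in ``sample_stats``, never discarded.
    ``boundary`` controls similarity values at exactly 0/1: ``"error"``
    (default) raises, ``"squeeze"`` applies :func:`squeeze_boundary`.
    """
    pk = _Packer(design.n_sites, design.n_basins, design.n_strahler_levels)
    prepared = _PreparedDesign(design, boundary)

    def logp_grad(theta):
        return _logp_and_grad(theta, pk, prepared)

    streams = np.random.SeedSequence(seed).spawn(chains)
    results = []
    for chain, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        theta0 = 0.1 * rng.standard_normal(pk.dim)
        theta0[pk.log_kappa] = np.log(10.0) + 0.1 * rng.standard_normal()
        res = sample_nuts(
            logp_grad,
            theta0,
            n_warmup=warmup,
            n_draws=sampling,
            rng=rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        n_div = int(res.diverging.sum())
        if n_div:
            logger.warning("chain %d: %d divergent transition(s)", chain, n_div)
        results.append(res)

    # constrain every draw into named parameter arrays
    names_vec = {
        "alpha_s": pk.S, "alpha_c": pk.B, "alpha_o": pk.O,
        "beta_distance": pk.B, "beta_flow": pk.B, "beta_precip": pk.B,
    }
    names_scalar = [
        "alpha_baseline", "sigma_s", "sigma_strahler",
        "mu_distance", "mu_flow", "mu_precipitation",
        "sigma_distance", "sigma_flow", "sigma_precipitation", "kappa",
    ]
    posterior = {k: np.empty((chains, sampling, n)) for k, n in names_vec.items()}
    posterior.update({k: np.empty((chains, sampling)) for k in names_scalar})
    for c, res in enumerate(results):
        for i in range(sampling):
            p = pk.constrain(res.draws[i])
            for k in names_vec:
                posterior[k][c, i] = getattr(p, k)
            for k in names_scalar:
                posterior[k][c, i] = getattr(p, k)
    sample_stats = {
        "diverging": np.stack([r.diverging for r in results]),
        "treedepth": np.stack([r.treedepth for r in results]),
        "max_treedepth_hit": np.stack([r.max_treedepth_hit for r in results]),
        "accept_stat": np.stack([r.accept_stat for r in results]),
        "energy": np.stack([r.energy for r in results]),
    }
    config = {
        "chains": chains, "warmup": warmup, "sampling": sampling, "seed": seed,
        "target_accept": target_accept, "max_treedepth": max_treedepth,
        "boundary": boundary,
        "step_sizes": [float(r.step_size) for r in results],
    }
    return PosteriorDraws(posterior=posterior, sample_stats=sample_stats,
                          config=config)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Split-Rhat/ESS per parameter plus divergence and treedepth counts."""

    rhat: pd.Series
    ess_bulk: pd.Series
    n_divergent: int
    n_max_treedepth: int
    rhat_threshold: float
    rhat_ok: bool | None
    no_divergences: bool
    no_treedepth_saturation: bool

    @property
    def passed(self) -> bool:
        return bool(self.rhat_ok) and self.no_divergences and \
            self.no_treedepth_saturation

    def to_dict(self) -> dict:
        with np.errstate(all="ignore"):
            rhat_max = np.nan if self.rhat.empty else np.nanmax(self.rhat)
        return {
            "rhat_max": float(rhat_max) if np.isfinite(rhat_max) else None,
            "rhat_threshold": self.rhat_threshold,
            "rhat_ok": self.rhat_ok,
            "n_divergent": self.n_divergent,
            "n_max_treedepth": self.n_max_treedepth,
            "no_divergences": self.no_divergences,
            "no_treedepth_saturation": self.no_treedepth_saturation,
            "passed": self.passed,
        }


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.01) -> DiagnosticsReport:
    """Sampler health report: split-Rhat, bulk ESS, divergences, treedepth.

    Rhat is computed per flattened parameter on split chains (via arviz).
    With a single chain, Rhat is reported as unavailable (all-NaN) and the
    overall pass flag is None for that component.  Zero-variance chains
    yield NaN Rhat and are flagged rather than passed.
    """
    import arviz as az

    names = draws.scalar_names()
    rhat_vals, ess_vals = {}, {}
    single_chain = draws.n_chains < 2
    for name in names:
        arr = draws.scalar_draws(name)
        if single_chain:
            rhat_vals[name] = np.nan
            ess_vals[name] = float(az.ess(az.convert_to_dataset(arr))["x"])
            continue
        ds = az.convert_to_dataset(arr)
        rhat_vals[name] = float(az.rhat(ds)["x"])
        ess_vals[name] = float(az.ess(ds)["x"])
    rhat = pd.Series(rhat_vals, dtype=float)
    ess = pd.Series(ess_vals, dtype=float)
    if single_chain:
        rhat_ok = None
    elif rhat.isna().any():
        rhat_ok = False  # undefined Rhat (e.g. constant chains) is a red flag
    else:
        rhat_ok = bool((rhat < rhat_threshold).all())
    n_div = int(draws.sample_stats["diverging"].sum())
    n_deep = int(draws.sample_stats["max_treedepth_hit"].sum())
    return DiagnosticsReport(
        rhat=rhat,
        ess_bulk=ess,
        n_divergent=n_div,
        n_max_treedepth=n_deep,
        rhat_threshold=rhat_threshold,
        rhat_ok=rhat_ok,
        no_divergences=n_div == 0,
        no_treedepth_saturation=n_deep == 0,
    )
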