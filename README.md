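# riverddcs

Tools for studying the **distance decay of community similarity (DDCS)** in
river networks: how quickly riparian plant communities become dissimilar as
the river distance between them grows, and how much of that decay is carried
by neutral factors (network distance, flow connection) versus niche factors
(Strahler-order difference, precipitation difference).

The package is aimed at community ecologists working with dyadic similarity
data on dendritic networks. It provides the full analysis chain as a tested
library plus a thin CLI: Sorensen similarity between within-basin census
pairs, river-network covariates, the covariate transforms, a hierarchical
Bayesian beta regression with dyadic varying intercepts, and the
prior/posterior predictive checking workflow. Because real survey campaigns
of this kind are rarely redistributable, a synthetic generator produces
dendritic networks, censuses and similarities with exactly the statistical
structure the model assumes, so the whole pipeline — including parameter
recovery and simulation-based calibration — runs end-to-end from nothing.

## The model

For sites *i*, *j* in the same basin, the Sorensen index
`S = 2a / (2a + b + c)` (with `a` shared species and `b`, `c` the species
unique to each site) is modelled as

```
S_ij ~ Beta(mu_ij * kappa, (1 - mu_ij) * kappa)

logit(mu_ij) = alpha_baseline + alpha_s[i] + alpha_s[j] + alpha_c[basin]
             + alpha_o[strahler level]
             + beta1[basin] * x_dist + beta2[basin] * flow + beta3[basin] * x_prec
```

with `x_dist = (d_km - 100) / 100`, `x_prec = (log(dp_mm + 1) - log 301) / log 301`,
and flow connection an untransformed 0/1 indicator. The additive site
intercepts `alpha_s` absorb the dependence among all dyads sharing a census;
per-basin slopes are partially pooled through `betaK[basin] ~ Normal(mu_K,
sigma_K)`, and the hyper-means `mu_distance`, `mu_flow`,
`mu_precipitation` — the expected covariate effect in a new basin — are the
headline estimands. Pairs whose network/Euclidean distance ratio is ≤ 2 are
excluded beforehand so overland proximity does not confound the
network-distance signal.

Priors: `alpha_baseline, alpha_c, mu_K ~ Normal(0, 0.3)`;
`alpha_s ~ Normal(0, sigma_s)` with `sigma_s ~ Exponential(1)`;
`alpha_o ~ Normal(0, sigma_strahler)`, `sigma_strahler ~ Exponential(2)`;
`sigma_K ~ Exponential(2)`; `kappa ~ half-Normal(50)`.

Posterior sampling uses a built-in No-U-Turn sampler (multinomial NUTS with
dual-averaging step size and diagonal mass adaptation) on the unconstrained
scale with a non-centered parameterisation of all hierarchical vectors and
analytic gradients; divergences and treedepth saturations are reported,
split-Rhat/ESS come from `arviz`.

## Worked example

```python
import numpy as np
import riverddcs as rd

networks, sites = rd.generate_basins(n_basins=4, sites_per_basin=15, seed=1)
matrix = rd.simulate_communities(sites, networks, seed=2)
sims   = rd.pairwise_sorensen(matrix, dict(zip(sites.site_id, sites.basin_id)))
pairs  = rd.build_pairs(sites, networks, sims)
kept, filt = rd.ratio_filter(pairs)
design = rd.build_design(kept)
print(f"{filt.n_before} pairs -> {filt.n_after} after ratio filter")

truth    = rd.make_true_parameters(design.n_sites, design.n_basins, seed=3)
design.y = rd.simulate_sorensen_from_model(design, truth, seed=4)
draws    = rd.fit(design, chains=2, warmup=400, sampling=400, seed=5,
                  target_accept=0.9)
print(rd.summarize(draws).hyperparameters[["mean", "q2.5", "q97.5"]].round(3))
```

prints

```
420 pairs -> 236 after ratio filter
                   mean   q2.5  q97.5
mu_distance      -0.384 -0.741  0.099
mu_flow           0.081 -0.261  0.350
mu_precipitation -0.071 -0.432  0.257
```

The truth used to simulate had `mu_distance = -0.4`, `mu_flow = 0.05`,
`mu_precipitation = -0.3`: each 95% credibility interval covers its true
value, and the distance-decay effect (similarity falls with network
distance, per transformed 100 km unit on the logit scale) is recovered with
the expected sign. At this reduced problem size the intervals are wide —
four basins and 236 dyads carry limited information about hyper-means under
partial pooling.

The same analysis is available from the shell:

```
riverddcs simulate --out run/ --seed 1
riverddcs prepare  --out run/
riverddcs fit      --out run/ --seed 1
riverddcs check    --out run/ --seed 1
riverddcs report   --out run/
```

## Layout

- `src/riverddcs/similarity.py` — Sorensen index, community matrices
- `src/riverddcs/network_metrics.py` — drainage trees, Strahler orders,
  network/Euclidean distances, flow connection, ratio filter, covariate screen
- `src/riverddcs/design_matrix.py` — covariate transforms and index maps
- `src/riverddcs/bayes_model.py` — likelihood, priors, NUTS fitting, diagnostics
- `src/riverddcs/_nuts.py` — the sampler itself
- `src/riverddcs/synthetic_data.py` — network/census/similarity generators
- `src/riverddcs/checks_report.py` — retrodictive checks, summaries, reports
- `docs/methods.md` — modelling and design notes
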