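# Methods notes

## Scope and data model

The package analyses dyadic community similarity on dendritic river
networks. Its observational unit is the *within-basin site pair*: a Sorensen
index `2a/(2a+b+c)` computed from two presence/absence censuses, together
with four raw covariates — network distance (km along the tree path),
Euclidean distance (km, used only by the pair filter), flow connection
(whether one site lies on the other's downstream path to the outlet), the
absolute Strahler-order difference, and the absolute annual-precipitation
difference (mm). Cross-basin pairs are never formed: each basin is treated
as an independent replicate of the decay process, entering the model as one
level of a varying intercept and one level of each slope family.

Abundance data are binarized on input; the Sorensen index is incidence
based. Unordered dyads get a canonical role assignment (lexicographic site
order). The likelihood is symmetric in the two roles — the dyadic
intercepts are additive — so this choice affects reproducibility only, not
inference; a dedicated test asserts the symmetry of the log posterior under
a global role swap.

## Pair filter

Dyads with network/Euclidean distance ratio ≤ 2 are removed before
modelling: for such pairs overland dispersal (wind, animals) can plausibly
bridge what the network metric reports as far apart, confounding the
distance-decay signal. Retention is strictly greater-than-2; a pair at
exactly the threshold is excluded. Coincident coordinates (Euclidean 0)
make the ratio undefined; such degenerate dyads are excluded with a logged
warning rather than silently retained as "infinite ratio". Covariates are
computed before filtering — the order cannot change the retained values —
and the filter is idempotent.

## Covariate transforms

* network distance: `x = (d - 100) / 100`. The 100 km anchor marks a scale
  beyond which drift-driven turnover is expected to dominate; slopes are
  "per 100 km beyond 100 km" on the logit scale.
* precipitation difference: `x = (log(dp + 1) - log 301) / log 301`. The log
  tames the skewed raw differences; 300 mm is a typical minimum annual
  precipitation for Mediterranean climates. The exact constant `log 301 ≈
  5.7071` is used internally (it is conventionally printed as 5.71); using
  the rounded value instead would shift every transformed covariate by a
  spurious ~0.02%.
* flow connection enters untransformed as 0/1.
* Strahler-order difference is not a slope but a 7-level varying intercept
  (differences 0–6), letting the similarity response be nonlinear in order
  difference. Differences above 6 — possible on synthetic networks — are
  clamped to the top level with a warning. No reference level is needed:
  the levels are exchangeable under their zero-centered prior.

Both anchors (100 km, 300 mm) are configurable in `build_design` for
sensitivity analyses; the defaults above are used everywhere else.

## Likelihood and priors

`S_ij ~ Beta(mu*kappa, (1-mu)*kappa)` — the mean/sample-size
parameterisation, with `logit(mu)` the linear predictor described in the
README. Priors:

```
alpha_baseline ~ Normal(0, 0.3)         alpha_c[basin] ~ Normal(0, 0.3)
alpha_s[site]  ~ Normal(0, sigma_s)     sigma_s ~ Exponential(1)
alpha_o[level] ~ Normal(0, sigma_o)     sigma_o ~ Exponential(2)
betaK[basin]   ~ Normal(mu_K, sigma_K)  mu_K ~ Normal(0, 0.3)
sigma_K ~ Exponential(2)                kappa ~ half-Normal(50)
```

Two deliberate readings of the prior block:

* `kappa` must be positive in this parameterisation, so its Normal(0, 50)
  prior is implemented as a half-normal truncated at zero.
* the slope-family priors name three distinct families (distance, flow,
  precipitation) because the likelihood has three distinct slopes; the
  per-basin flow and precipitation slopes each get their own hyper-mean and
  hyper-scale.
* `alpha_s` is one pooled vector across all sites of all basins with a
  single global `sigma_s`; basin-level structure is already carried by
  `alpha_c`.
* `alpha_c` keeps its fixed 0.3 scale (no hyperprior), exactly as the prior
  block states.

Boundary observations (Sorensen exactly 0 or 1) are outside the Beta
support. The default fitting behaviour is a hard error with guidance; an
opt-in compression `y' = (y(n-1) + 0.5)/n` (`boundary="squeeze"`, the
standard adjustment for boundary-touching beta-likelihood data) is provided
and is the CLI default, since mechanistically generated communities can
produce identical or disjoint censuses.

## Sampler

No probabilistic-programming backend is required: the log posterior and its
gradient are written out analytically (Beta likelihood via `gammaln` /
`digamma`, priors in closed form) on an unconstrained vector — log
transforms with Jacobians for all scales and `kappa`, non-centered
parameterisation for every hierarchical vector (`alpha_s`, `alpha_o`, the
three slope families). Non-centering removes the funnel geometry that
hierarchical scales induce when group-level data are modest, which is what
keeps the sampler divergence-free in the recovery experiments. The
gradient is verified against central finite differences to ~1e-9 relative
error in the tests.

Sampling is multinomial NUTS in the style of Stan's adaptive HMC: dynamic
trajectory doubling with the no-U-turn criterion on subtree momentum sums,
biased progressive proposal sampling, dual-averaging step-size adaptation
to a target acceptance statistic (default 0.8; recovery/SBC experiments use
0.9), and Stan-style windowed estimation of a diagonal mass matrix during
warmup (15% initial step-size-only buffer, doubling variance windows, 10%
terminal buffer, variance regularised toward the unit metric). A leapfrog
step whose energy error exceeds 1000 nats (or goes non-finite) is a
divergence; trajectories that reach `max_treedepth` (default 10) without
u-turning are flagged as saturated. Both counts are carried into the
diagnostics report, never discarded. Chains run sequentially from
independent `SeedSequence` streams; results are bitwise reproducible given
the seed.

The default configuration mirrors the conventional 4 chains × (1000
warmup + 2000 sampling); the test suite uses shorter chains and smaller
designs, sized so each experiment still answers its question (coverage,
calibration, sign) with Monte-Carlo error well inside the asserted
tolerances.

Diagnostics: split-Rhat and bulk ESS per flattened parameter via `arviz`,
pass threshold Rhat < 1.01 ("consistent with 1" needs an operational
cutoff); divergence and treedepth-saturation counts with exact injected-flag
bookkeeping. Constant chains yield undefined Rhat and are flagged as
failures, not passes; a single chain reports Rhat as unavailable.

The sampler is cross-checked two ways: against closed-form moments of
Gaussian targets, and against `emcee` (an unrelated affine-invariant
ensemble sampler) run on the identical log-posterior of a small fitted
model, agreeing on posterior means of the headline parameters.

## Synthetic data: what it emulates, what it does not

`generate_network` grows a drainage tree by random binary merging of
headwater branches — gamma-distributed reach lengths (shape 4) around a
mean of 6 km, coordinates laid out outlet-first with per-edge meander
factors in [1.15, 1.6], so chord length ≤ channel length and network ≥
Euclidean distance by construction. With the default 64 leaves per basin
this yields within-basin network distances straddling the 100 km transform
anchor and Strahler orders 1–5 (order-difference levels 0–4 populated;
level 6 would need ≥ 64 equal-order confluences, rare under random
merging). Sites sit exactly on nodes, stratified across Strahler orders so
order-difference levels are occupied; within-basin spacing is not a fitted
quantity and is exposed through the generator parameters rather than
hard-coded.

Precipitation is a linear function of coordinates (default 3000 mm at the
origin, −1.2 mm/km west-east plus a weaker north-south term, basins 100 km
apart) with Gaussian noise (sd 30 mm), clipped at zero — a smooth regional
gradient like the Iberian one, with within-basin differences of the order
of the 300 mm anchor.

Two similarity generators exist because they answer different questions.
The model-faithful generator draws dyad similarities from the likelihood at
known parameters: recovery and calibration experiments require the fitted
model to be the true model. The mechanistic generator spreads species from
random core sites with occupancy probability `logistic(a0 - a1*d_network -
a2*|dprecip|)` (defaults 2.0, 0.08/km, 0.01/mm), guaranteeing at least one
species per site; it produces genuine presence/absence matrices whose
Sorensen indices decay with network distance, exercising the similarity
stage end-to-end.

Neither generator attempts hydrological realism: no discharge, elevation,
braiding, mid-edge sites, or spatially autocorrelated rasters. Passing
tests therefore demonstrate the *statistical* machinery — formulas,
filters, sampler correctness, calibration — not that real riparian data
satisfy the model's assumptions.

## Checking workflow

* Prior predictive: 1000 joint prior draws, each simulating a full
  similarity vector; summarised by the fraction of mass each draw places in
  [0.25, 0.65] (the band the weakly-informative prior was designed around).
  Measured on the default synthetic design, the median band mass under the
  priors above is ≈ 0.40 — close to the uniform-distribution reference
  value, with the dyadic site intercepts (two per dyad,
  `sigma_s ~ Exponential(1)`) contributing most of the logit-scale spread.
  A markedly more concentrated prior predictive would require re-centering
  or tightening the printed priors; the package reports the statistic
  rather than adjusting them.
* Posterior retrodictive: replicate similarity vectors from a posterior
  subsample; density overlay against the observed distribution, plus
  binned observed-vs-replicate mean similarity conditional on each
  covariate with central 95% replicate bands. A systematic deviation is
  flagged when the observed mean leaves the band in ≥ 2 contiguous bins of
  any covariate (single-bin excursions at the ~5% rate are expected by
  construction).
* Recovery: fresh basins and similarities simulated at known hyper-means
  (`mu_distance = -0.4`, `mu_flow = 0.05`, `mu_precipitation = -0.3`,
  `kappa = 30`), refit, 95% interval coverage counted across replicates.
* Simulation-based calibration at reduced scale (2 basins × 8 sites): truth
  drawn from the prior, data simulated, refit, rank of the truth among
  thinned posterior draws; rank histograms of `mu_distance`, `sigma_s`,
  `kappa` tested for uniformity (chi-squared, alpha = 0.01).

## Known limitations

* Slopes are reported per transformed covariate unit on the logit scale.
  A slope of −0.37 is *not* a "37% decrease in similarity per km"; no
  percentage reinterpretation is provided.
* The NUTS implementation is single-threaded and in pure numpy; it is
  sized for designs of order 10³ dyads and 10² parameters, not for
  large-scale reuse.
* `emcee`-based cross-checks and the hierarchical posterior generally are
  only meaningful at small dimension; the ensemble sampler mixes too slowly
  beyond a few dozen dimensions to serve as an oracle there.
* The basin intercept `alpha_c` and baseline are weakly separated (only B
  basins inform B+1 intercept parameters); this is inherited from the model
  definition and handled by the fixed 0.3 prior scales.
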