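# Methods

This note records the models implemented in `swarmnet`, the numerical
choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Network construction

A network is the group of birds following one ant swarm on one day.
Windows are five-minute censuses; under the gambit of the group every
unordered species pair within a window gains one unit of edge weight,
so a window with k species contributes C(k, 2) weight units. The binary
network is the support of the weight map. Two deliberate choices:

* **Isolated nodes are kept.** Network size is defined as the species
  richness at the swarm, so a species that never co-occurs with another
  still counts, and carries degree 0 into the skewness distribution.
* **No minimum-window filter.** One-window networks are legal (one site
  contributed a single swarm-day); downstream metrics decide usability
  through their own degeneracy rules.

Swarm identity is never merged across days: the same swarm followed on
three consecutive days yields three networks, and the day-to-day
dependence is instead absorbed by the swarm-identity random intercept
in the models.

## Metrics and degenerate cases

Weighted information enters only the mean weighted degree; clustering
is computed on the binary graph. Skewness is the moment estimator
g₁ = m₃/m₂^{3/2} with population moments (no small-sample correction),
matching the conventional moments-style estimator; a toggleable
bias-corrected variant was considered and rejected as the default to
keep the estimator simple and conventional.

Degenerate rules: size-1 networks have all four degree-based metrics
undefined; skewness needs ≥3 species; clustering is undefined when no
connected triple exists; a zero-variance degree distribution (complete
network) gets skewness 0 rather than NaN, because fully connected
groups are common at small swarms and dropping them would censor
exactly the most cohesive networks. Undefined cells propagate as NaN
and are dropped listwise per response when modelling.

## Dissimilarity partition

Interactions are binary edges; weights never enter the dissimilarity.
β_WN uses the Whittaker form over the two edge sets; β_OS applies the
same form to the sub-edge sets induced by the species present in both
networks (an edge counts only if *both* endpoints are shared); β_ST is
the difference. When neither induced set has an edge, β_OS := 0 and all
dissimilarity is attributed to turnover. Edgeless networks (isolated
nodes only) cannot be compared and are dropped with a logged reason.
Same-site swarm pairs stay in the pairwise set (n networks give exactly
n(n−1)/2 comparisons) with zero environmental difference. Additivity
β_WN = β_ST + β_OS holds to better than 1e−12 in floating point and is
asserted by property tests.

The models can take either the raw components (default, z-scored for
the Gaussian responses) or the β_WN-normalized proportions
(`dissimilarity_scale: proportions`); both are emitted, since either
reading of "these values were then used in our models" is defensible.

## Metric GLMMs

Each metric is regressed on standardized (sample-sd, ddof = 1) rainfall
and suitability with a random intercept for swarm identity. Families
match support: Poisson/log (size), beta/logit (mean normalized degree,
clustering), Gaussian/identity (mean weighted degree, skewness). Beta
responses attaining the boundary are squeezed by y′ = (y(n−1)+½)/n.

Estimation is maximum likelihood with a Laplace approximation: the
random effect is scalar per group, so each group's mode is found by a
damped one-dimensional Newton iteration, vectorized across groups, and
the outer optimization over fixed effects and log-scale variance
parameters uses L-BFGS-B. The approximation is exact for the Gaussian
family, which gives a sharp cross-check: the fit reproduces statsmodels
MixedLM (ML) estimates, variance components and log-likelihood to four
decimals, and the Poisson/beta routes without a random effect reproduce
statsmodels GLM and BetaModel. Wald 95% CIs throughout (profile CIs not
implemented). AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) counts every estimated
parameter, including variance/dispersion terms; the linear-rainfall
model competes against the quadratic one and ties break toward fewer
parameters. The random-effects screening reported for the original
analysis (site, month, observer, …) is not re-implemented; the
swarm-identity intercept is taken as given.

When the true group variance is zero the log-sd parameter runs to its
lower bound (σ ≈ e⁻⁶); the fit reports σ_re = 0 in that case.

## Dissimilarity GAMMs

Each dissimilarity response is modelled with smooth functions of
|Δrainfall| and |Δsuitability| (both standardized) and a random
intercept for the unordered site pair. Smooths are cubic regression
splines with k = 3 knots at the covariate's min/median/max, sum-to-zero
constrained, with a shrinkage penalty: the penalty's null-space
eigenvalue is set to 0.1× the smallest positive eigenvalue, so heavy
smoothing can flatten a term entirely (e.d.f. → 0) instead of stopping
at a straight line. Smoothing parameters and variance components are
selected by REML (the smoothness-selection criterion is not fixed by
the source analysis; REML is this package's default, GCV is not
offered), computed through the Woodbury identity on the low-rank random
blocks. The β_WN response (beta/logit) is fitted by penalized
quasi-likelihood: iteratively reweighted Gaussian REML fits on the
working response, with the precision φ updated by Pearson moments each
cycle, outer tolerance 1e−3 on the linear predictor (smoothing
re-selection leaves a small limit cycle below that scale).

Per-smooth p-values are approximate Wald statistics on the Bayesian
posterior covariance referred to a χ² with the term's e.d.f. — the same
flavour of approximation mgcv prints, not an exact test.

**A property worth knowing:** with a single smoothing parameter per
shrinkage smooth, the e.d.f. recovered for a *truly linear* effect
depends on its strength. Moderate effects (≈0.2 SD response per SD
covariate) come back with e.d.f. ≈ 1; strong effects inflate the
block's variance and release the wiggle component, giving e.d.f.
1.5–1.9. This is not an artifact of this implementation — mgcv's `cs`
basis behaves identically (verified head-to-head; the two agree within
≈0.1 e.d.f. across effect sizes, and one regression test pins that
agreement on a frozen dataset). The linearity-recovery tests therefore
generate effects in the moderate regime where the diagnostic is
informative.

## Habitat suitability

Grid-native: the buffer is the set of non-fragment cells whose center
lies within the buffer distance (default 200 m) of the nearest
fragment-cell center, via an exact Euclidean distance transform — no
vector geometry, since NDVI is a raster product and no polygon
machinery is defined. Percentiles use linear interpolation between
order statistics (conventions differ at small n, so this is pinned);
the envelope is inclusive at both bounds; masked (cloud/water) cells
are excluded from the denominator. The module is resolution-agnostic;
raster I/O is plain-text ESRI ASCII grid plus in-memory arrays.

## Synthetic-data generator

Defaults emulate the sampling design: 7 sites with rainfall spanning
2103–2862 mm/yr and suitability 0.31–0.99 (extremes pinned to the
endpoints, suitability order shuffled against rainfall), 1–27
swarm-days per site grouped into swarms of up to 3 consecutive days,
2–6 windows per swarm-day (an option matches the observed 73%/20%
three/four-window mix instead), and a 110-species regional pool.

Species occupancy decays with squared z-rainfall distance from a
per-species niche center, occupancy ∝ exp(−κ·d²); κ = 2.0 makes ≈59% of
occurring species occupy ≤2 of the 7 sites, the turnover structure the
analysis assumes (κ = 0 puts every species everywhere). Each species
also gets a persistent regional abundance (lognormal, sd 1.5) used as
its sampling weight at every swarm, producing the few-common,
many-rare attendance pattern.

Two linear predictors drive structure, both on the observation-level
standardized scale the fitted models use (so generating and fitted
coefficients are directly comparable):

* richness: log λ = 2.065 − 0.176·zR + 0.093·zH, swarm-day richness
  ~ Poisson(λ) truncated at the site pool (truncation is logged);
  zero richness is a birdless swarm that yields no network.
* cohesion: logit q = 1.0 + 0.3·zR + 0.3·zH, the probability that an
  attending species is present in any given window, conditioned on
  ≥1 window; q jointly drives weighted degree, clustering and skewness.
  The intercept puts simulated clustering near 0.95 and skewness mildly
  negative, and the positive γ coefficients reproduce the observed sign
  structure (cohesion rising with suitability; clustering rising and
  skewness flattening with rainfall).

What the generator does **not** emulate: there is no per-species
attendance heterogeneity beyond abundance, so shared species almost
always reconnect and simulated dissimilarity is turnover-dominated
(β_OS ≈ 0.02–0.04 rather than the field's ≈0.3); no observer error or
detection bias; no obligate/facultative trait structure; no ant-colony
phase cycle. Passing tests therefore certify the pipeline's arithmetic
and its estimators' calibration on data of this structure — not that
field data will show the same β partition.

Determinism: one seed drives every draw; identical seeds give
byte-identical written datasets.

## Problem sizes used by the tests and acceptance script

The recovery experiment uses ~500 swarm-days per replicate
(days-per-site 70–73) and 100 replicates — large enough that the 2-SE
recovery criterion has ≈95% per-replicate coverage. GAMM behavior is
checked at n = 1000 pairs over 10 replicates. The default-conditions
run (≈130 networks, ≈9000 pairs) matches the scale of the field design.

## Known limitations

* GLMM CIs are Wald; near-boundary variance components make them
  approximate.
* The beta GAMM route is PQL, which is known to bias variance
  components slightly for extreme means; e.d.f. values are those of the
  final working model.
* The GAMM smooth p-values are approximate (see above).
* Whittaker counts treat interactions as unweighted; no
  nestedness-vs-replacement decomposition of turnover is offered.
* The rainfall-interpolation model that produced the original site
  rainfall values is out of scope; rainfall is an input here.
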