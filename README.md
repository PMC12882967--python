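# swarmnet

Co-occurrence networks of birds attending army-ant swarms: build the
networks, measure their structure, partition their dissimilarity into
species turnover and interaction rewiring, and relate everything to
rainfall and habitat-suitability gradients.

Mixed-species groups of ant-following birds form around raiding swarms
of *Eciton burchellii*. A field census of such a group is a series of
five-minute observation windows listing the species present; under the
*gambit of the group*, all species seen together in one window are
taken to associate reciprocally. `swarmnet` is for ecologists who have
(or want to simulate) such window records and need the full analysis
chain as tested, reusable code.

## What it computes

**Networks.** One network per swarm per day. Each window contributes a
clique on its species set; edge weights count co-shared windows; species
that never co-occur remain as isolated nodes.

**Five structural metrics** per network: size (species richness), mean
normalized degree (mean of kᵢ/(n−1)), mean weighted degree (mean node
strength), global clustering (transitivity, 3×triangles / connected
triples), and the moment skewness g₁ of the normalized-degree
distribution.

**Dissimilarity partition.** For two networks with interaction sets
E₁, E₂ and a = |E₁∩E₂|, b = |E₁\E₂|, c = |E₂\E₁|, the Whittaker
dissimilarity

    β_WN = (a + b + c) / ((2a + b + c)/2) − 1  =  (b + c) / (2a + b + c)

is split additively into rewiring β_OS (the same index on the sub-edge
sets induced by species present in both networks) and turnover
β_ST = β_WN − β_OS.

**Gradient models.** GLMMs of each metric on standardized rainfall and
suitability (Poisson/log for size, beta/logit for the proportion
metrics, Gaussian otherwise; random intercept for swarm identity; AICc
choice between linear and quadratic rainfall), and GAMMs of the
pairwise dissimilarities on |Δrainfall| and |Δsuitability| (shrinkage
cubic splines, ≤3 knots, site-pair random intercept; e.d.f. = 1 marks a
linear effect, e.d.f. → 0 a shrunk-away one).

**Habitat suitability.** The proportion of raster cells in a 200 m
buffer around a forest fragment whose NDVI falls inside the fragment's
own 10th–90th percentile NDVI envelope.

**Synthetic data.** A generator that emulates the sampling design
(7 sites spanning 2103–2862 mm/yr and 0.31–0.99 suitability, 1–27
swarm-days per site, 2–6 windows per swarm-day, a 110-species pool with
high among-site turnover) with known coefficients, so every stage is
testable end to end. See `docs/methods.md` for the generating model.

## Worked example

```python
from swarmnet import (simulate_dataset, group_by_swarm, build_all,
                      metrics_table, all_pairs, site_pair_summary)
import numpy as np

sites, windows, truth = simulate_dataset(seed=1)
nets = build_all(group_by_swarm(windows))
print(f"{len(windows)} observation windows -> {len(nets)} swarm-day networks")

metrics = metrics_table(nets)
print(metrics[["size", "mean_norm_degree", "clustering", "skewness"]].mean().round(3))

pairs = all_pairs(nets)
between = [s for s in site_pair_summary(pairs) if s.site_1 != s.site_2]
print(f"{len(pairs)} pairwise comparisons, {len(between)} between-site pairs")
print("mean beta_WN =", round(np.mean([s.mean_beta_wn for s in between]), 3))
```

prints

```
538 observation windows -> 136 swarm-day networks
size                8.221
mean_norm_degree    0.938
clustering          0.939
skewness           -0.300
dtype: float64
9180 pairwise comparisons, 21 between-site pairs
mean beta_WN = 0.972
```

Read: the simulated groups average ~8 species, are nearly complete
(mean normalized degree 0.94) and highly clustered, with mildly
negative degree skew; 136 networks give 136·135/2 = 9180 pairwise
comparisons and, with 7 sites, 21 between-site summaries; between-site
interaction dissimilarity is very high (β_WN ≈ 0.97), dominated by
species turnover.

The same stages run from the shell:

```sh
swarmnet simulate --seed 1 --out data/
swarmnet all --simulate --seed 1 --out run1/   # full pipeline + manifest
swarmnet suitability --ndvi ndvi.asc --fragment frag.asc --buffer-m 200
```

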