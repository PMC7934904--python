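# traitdiv

Occupancy-weighted functional diversity of tropical forest mammal
communities, and what drives it.

`traitdiv` is for community ecologists analysing standardized
camera-trap monitoring data at the protected-area level. It answers two
questions: *how functionally diverse is each mammal community, once
species' occupancies are taken into account?* and *which site properties
— species pool, habitat heterogeneity, productivity, human disturbance —
explain that diversity?*

## What it computes

All species that occur in any realized community, species pool or recent
extirpation list are placed in **one shared trait space**: six trait
groups (body mass; five diet binaries; sociality; substrate use; three
activity-period binaries; litter size) are combined in a group-weighted
Gower dissimilarity (each group contributes 1/6) and ordinated by
principal coordinates analysis with a negative-eigenvalue correction.
Per site, with occupancy estimates aᵢ ∈ (0, 1] as abundance proxies:

* **FDis** — occupancy-weighted dispersion, FDis = Σ aᵢ‖xᵢ − c‖ / Σ aᵢ
  with centroid c = Σ aᵢxᵢ / Σ aᵢ, plus presence-only variants for the
  realized community and the species pool;
* **FRic** — convex-hull volume on the first three ordination axes
  (presence-based by construction), for the community and its pool;
* **extinction impact** — ΔFRic between the community including its
  recently extirpated species and the current community, and the
  corresponding percent loss of hull volume;
* **Bayesian Weibull regression** — each diversity response y > 0 is
  modelled as y ~ Weibull(k, λ) with mean exp(α + x'β), standardized
  predictors (pool FRic, habitat Shannon diversity, NDVI, human density,
  ΔFRic) and a biogeographic-region factor; coefficients are summarized
  by posterior medians, 50%/95% credible intervals, split-Rhat
  convergence (< 1.05) and strict 95%-interval significance.

A synthetic-study generator produces complete trait/community/covariate
bundles with known regression coefficients, so the entire pipeline is
testable without any external data. See `docs/methods.md` for model
details and limitations.

## Worked example

Simulate a 15-site study, compute per-site functional diversity, and run
the full pipeline:

```sh
traitdivpipe simulate --n-sites 15 --n-species 80 --seed 42 --out demo/bundle
traitdivpipe fd --traits demo/bundle/traits.csv \
    --communities demo/bundle/communities.csv \
    --pools demo/bundle/pools.csv \
    --extirpations demo/bundle/extirpations.csv \
    --out demo/fd.csv
```

The FD table begins:

```
             region  fdis_weighted    fric  pool_fric  delta_fric  percent_loss
site_id
site001  Neotropics         0.4113  0.0797     0.0880      0.0000        0.0000
site002  Neotropics         0.4270  0.0512     0.0556      0.0000        0.0000
site003      Africa         0.3933  0.0562     0.0828      0.0065       10.3955
```

`fdis_weighted` is the occupancy-weighted dispersion in ordination
units; `fric` and `pool_fric` are hull volumes (raw ordination units) of
the realized community and its species pool; site003 lost hull-vertex
species to recent extirpations, costing 10.4% of its pre-extirpation
trait volume (`delta_fric` = 0.0065 units).

```sh
traitdivpipe run --seed 42 --out demo/run
```

```
pipeline complete -> demo/run
  fdis_weighted: significant predictors ['pool_fric', 'extinction_delta']
  fdis_unweighted_realized: significant predictors ['pool_fric', 'extinction_delta']
  fdis_unweighted_pool: significant predictors ['pool_fric']
  fric: significant predictors ['pool_fric', 'habitat_H', 'ndvi', 'region_Africa']
```

This fits all four responses on the simulated bundle and writes the
ordination, FD table, standardized design, per-response posterior
summaries and draws, credible-interval and posterior-predictive plots,
and a manifest (seed + config hash) that makes the run exactly
repeatable. A coefficient excerpt from `demo/run/summary.json`
(`fdis_weighted`):

```
intercept            median -0.876  95% CI (-0.920, -0.834)  Rhat 1.006
extinction_delta     median -0.049  95% CI (-0.073, -0.016)  Rhat 1.004
region_Madagascar    median -0.081  95% CI (-0.315, +0.145)  Rhat 1.005
```

The intercept is the log diversity of a Neotropical site with all
covariates at zero; the negative `extinction_delta` effect says sites
whose extirpations removed more trait volume have lower
occupancy-weighted dispersion. Real studies replace the `simulate` step
with their own CSVs (`traitdivpipe run --config my_run.yaml`); the
`--no-equalize-traits` flag reruns everything under uniform per-column
trait weights as a sensitivity analysis.

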