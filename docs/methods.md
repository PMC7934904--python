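# Methods

`traitdiv` computes occupancy-weighted functional diversity for a set of
tropical forest mammal communities monitored at the protected-area level
and regresses it on environmental and anthropogenic site predictors.
This note documents the model choices, numerical details and
limitations; the README shows the user-facing workflow.

## Trait coding

Each species carries six trait groups encoded into 12 columns: body
mass (kg, continuous), five diet binaries (graze, browse, fruit/seed,
invertebrates, vertebrates; 1 iff the category exceeds 25% of the
average diet — strictly, so a category at exactly 25% encodes 0 with a
warning), sociality (1 if social, 0 if solitary or in pairs), substrate
use (1 if able to climb), three activity-period binaries (diurnal,
crepuscular, nocturnal; at least one is expected), and average litter
size (continuous). Traits are species-level; no intraspecific variation
or imputation of missing values is supported — records with missing
fields are rejected by name.

Gower column weights default to the *equal-group* scheme: each of the
six groups receives total weight 1/6, split evenly within the group
(each diet column 1/30, each activity column 1/18, singletons 1/6).
The sensitivity variant (`equalize_traits=False`, or
`--no-equalize-traits` on the CLI) weights all 12 columns uniformly at
1/12. Body mass enters untransformed by default; `log_mass=True`
switches to log10(kg), which compresses the influence of megafauna on
the mass axis (the trait-space configuration changes, so all downstream
metrics change; the toggle exists to check that conclusions do not hinge
on this choice).

## Shared trait space

Gower dissimilarities are computed once over the union of all species
appearing in any realized community, species pool or extirpation list.
Continuous ranges are taken over that full union (not per community), so
subsetting a community from the shared matrix and computing distances
commute. Binary columns use the symmetric mismatch |x−y| by default; an
asymmetric (double-zero-excluded) mode is configurable.

The dissimilarities are embedded by principal coordinates analysis.
Mixed-trait Gower matrices are generally non-Euclidean; the default
correction ordinates the elementwise square root of the dissimilarities
(sqrt-Gower is Euclidean for most mixed tables and is the common default
of distance-based FD software). Cailliez and Lingoes additive
corrections and an uncorrected mode (keeping only non-negative
eigenvalues) are selectable; the additive constants are applied only
when a genuinely negative eigenvalue is present. Axes with eigenvalue
below 1e-9 of the leading eigenvalue are dropped as numerically null.
Coordinates are scaled as V·sqrt(λ), so Euclidean distances across *all*
retained axes reproduce the corrected dissimilarities.

Functional dispersion is computed over all retained axes; functional
richness uses the first `m_fric` axes, default 3. Because the number of
PCoA axes retained by the original distance-based FD software is not
fixed a priori, both the correction and `m_fric` are configuration
options rather than hard-coded choices. `m_fric` is additionally capped
at community size − 1 at hull time: an m-volume needs at least m+1
affinely independent points.

## Diversity metrics

* **FDis** (occupancy-weighted): centroid c = Σ aᵢxᵢ/Σ aᵢ and
  FDis = Σ aᵢ‖xᵢ − c‖/Σ aᵢ, with occupancy estimates aᵢ ∈ (0, 1] as
  abundance proxies. Unweighted variants (all aᵢ = 1) are computed for
  the realized community and for the species pool; these are the
  presence-only comparisons. Weights are relative (scaling all aᵢ by a
  constant changes nothing); a single-member community has FDis 0 with
  a warning.
* **FRic**: quickhull volume of the community's points on the first
  `m_fric` axes. FRic is never occupancy-weighted (a hull volume cannot
  use abundances). Exact duplicate coordinates are collapsed before the
  hull; degenerate (flat) point sets report 0 with a warning rather than
  aborting a batch run, and the condition is recorded in the output
  `flags` column. Volumes are reported in raw ordination units; no
  standardization by the pool hull volume is applied by default.
* **Extinction impact**: ΔFRic = FRic(members ∪ extirpated) −
  FRic(members), clipped at 0 against floating-point noise, and
  percent loss = 100·ΔFRic / FRic(members ∪ extirpated). Extirpated
  species are used presence-only (they have no current occupancy);
  extirpated species inside the current hull contribute nothing —
  functional redundancy can absorb a local extinction.

## Covariates and design

Predictors per site: species-pool FRic, habitat heterogeneity (Shannon
diversity of landcover-class frequencies, natural log by default, base
configurable), NDVI, human density, and the extinction impact ΔFRic.
Landcover class frequencies, NDVI and human density are taken as given
per site — raster clipping, buffer geometry and zone-of-interaction
delineation are GIS steps outside this package's scope. Continuous
predictors are centred and scaled with the sample sd (n−1), with the
scaling stored for exact inversion; biogeographic region (Neotropics,
Africa, Asia, Madagascar) enters as a dummy-coded factor with the
Neotropics as reference. Pairwise Pearson correlations among predictors
are screened and |r| ≥ 0.6 is warned about, not failed: collinearity
widens posteriors rather than invalidating them.

## Regression model

Each response (occupancy-weighted FDis, the two presence-only FDis
variants, FRic) is fit separately as

y_i ~ Weibull(k, λ_i), λ_i = μ_i / Γ(1 + 1/k), μ_i = exp(α + x_i'β),

the mean-parameterized Weibull with log link: α is the log expected
diversity of a reference-region site at covariate zero, and β are
standardized effects. The Weibull accommodates the left skew of
positive diversity metrics (negative skewness for k ≳ 3.6).

Priors are weakly informative and overridable: β ~ N(0, 5),
α ~ Student-t(3, median(log y), 2.5), k ~ Gamma(0.01, 0.01) (sampled as
log k with the Jacobian). Sampling uses affine-invariant ensemble MCMC:
by default 4 independent ensembles ("chains") of max(2(p+4), 16)
walkers, 1000 warmup + 1000 kept steps each, initialized by jittering a
posterior mode found with L-BFGS (jitter sd 0.1 per coordinate). The
ensembles are fully independent, so the split-Rhat statistic across
them (computed via arviz) is an honest convergence check; a fit with any
Rhat ≥ 1.05 is flagged unconverged and makes **no** significance calls.
A coefficient is "significant" when its 2.5th and 97.5th posterior
percentiles share a strict sign (an interval touching zero is not
significant). Posterior predictive checks simulate replicate datasets
from the joint posterior and report tail probabilities for the mean, sd
and minimum, plus a density-overlay plot.

With ~15 sites and 9 parameters, real-data fits are prior-sensitive and
the posterior is wide; the package's verified surface is synthetic-data
recovery (below), not any particular real-data coefficient table.

## Synthetic studies

The generator emulates the structure of the target data so every stage
is testable offline:

* **Traits** (default 120 species): mass log-normal (median 5 kg,
  log-sd 1.3) truncated above 1 kg — only terrestrial mammals over 1 kg
  are in scope; litter 1 + Poisson(1.2); diet from Dirichlet(0.8)
  compositions thresholded at 25% with the dominant category forced on;
  social ~ Bern(0.35), climbing ~ Bern(0.4); at least one active period.
* **Communities** (default 15 sites; regions drawn 7:4:3:1
  Neotropics:Africa:Asia:Madagascar): each site has a trait-space
  optimum; pool membership is distance-biased and occupancy declines
  logistically with distance from the optimum (clipped to [0.02, 1]);
  realized size is uniform on [5, 31]. Four sites (2 minimum; scaled
  ∝ 4/15 for other study sizes) lose 1–3 species drawn with probability
  ∝ distance⁶ from the community centroid, i.e. preferentially
  hull-vertex species — mimicking the empirical loss of top predators
  and large specialists. A uniform-draw mode exists for contrast, and
  targeted losses demonstrably remove more hull volume than random ones.
* **Occupancies are generated directly**, not via detection histories:
  the analysis consumes occupancy *estimates*, so the generator emulates
  the estimates, not the cameras. Consequences: no estimation error or
  detection-probability structure is present, and passing recovery tests
  says nothing about robustness to occupancy-model misspecification.
* **Responses**: simulated from the same Weibull model the regression
  fits, on the *computed and standardized* design (pool FRic and ΔFRic
  are really computed from the simulated communities). Default truth:
  β = +0.10 (pool FRic), 0 (habitat heterogeneity), +0.07 (NDVI),
  0 (human density), −0.18 (extinction impact); region offsets 0
  (Africa, Asia) and −2.60 (Madagascar); α = −1.4; shape k = 5. The
  non-zero values are the published standardized estimates for this
  system; the zeros correspond to predictors reported non-significant
  with unprinted magnitudes. k = 5 yields the left-skewed response
  distribution that motivates the likelihood (and the Madagascar deficit
  deepens the lower tail).

Because responses are simulated from the fitted model's own likelihood,
recovery tests validate the estimation machinery, not the ecological
model; real diversity responses need not be exactly Weibull.

## Verification sizes and numerical choices

The acceptance script (`scripts/acceptance.py`) and test suite use:
geometry oracle on 200 random 2-D/3-D configurations against
rejection-sampling volumes (4×10⁵/10⁶ uniform draws, tolerance 1%,
membership via Delaunay simplices — independent of the quickhull volume
code); FDis and Gower brute-force oracles at tolerance 1e-10;
calibration with 50 replicate studies of 100 sites fit with 2 chains ×
(400 + 400) steps — posterior-median bias below 0.05 per coefficient,
pooled 95%-interval coverage in [0.85, 0.99], true-zero coefficients
covered ≥ 90%; and byte-identical pipeline reruns at 15 sites. These
problem sizes are the package's verification conditions; larger runs
only sharpen the same checks.

Degenerate-input policy: all-zero dissimilarity matrices and
single-species tables are errors; zero-range continuous trait columns
are dropped from the Gower sum with renormalized weights and a warning;
flat hulls return 0 with a warning and a flag; identical-constant MCMC
chains report Rhat 1.0 (an already-converged degenerate case).

## Known limitations

* One value per protected area: within-area spatial variation is not
  modelled, and n ≈ 15 gives limited power (a positive pool-FRic effect
  of the default magnitude is usually not separable from zero at that
  size).
* No null-model standardized effect sizes, functional evenness or
  divergence, phylogenetic structure, or model comparison (LOO/WAIC).
* Hull-based FRic is sensitive to single outlying species and to
  `m_fric`; comparisons are only meaningful within one shared ordination.
* The extirpation statistic assumes the recorded extirpated species'
  traits are in the trait table and treats extirpation lists as exact.
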