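# Methods

## Observation model

For species *i* at station *j*, detections over `V_j` occasions follow

    Y_ij ~ Binomial(V_j, p_ij),      p_ij = 1 − (1 − r_ij)^Z_ij,
    Z_ij ~ Poisson(λ_ij),

where `r_ij` is the per-individual, per-occasion detection probability and
`Z_ij` the latent number of individuals available for detection — a measure
of habitat-use intensity around the camera, not density, since home ranges
of larger species span several stations. The model assumes demographic
closure over the deployment, correct species identification, and
independent detection of individuals.

Covariates are the intercept, standardized distance to the community,
the hunting-with-dogs stratum dummy (no-dogs bank as reference), and the
distance × stratum product (the raw product of the standardized distance
and the 0/1 dummy, not re-standardized). Two variants keep the parameter
count small for a 20-station design:

- **Model 1 (`variant="abundance"`)** — covariates on `log λ_ij`;
  `r_i = logit⁻¹(a_i)` species-constant.
- **Model 2 (`variant="detection"`)** — covariates on `logit r_ij`;
  `λ_i = exp(b_i)` species-constant.

Log and logit links are used throughout; they keep species coefficients on
an unbounded common scale so the community hyperstructure is meaningful.
Species-level parameters are exchangeable normal draws from community
hyperdistributions; the constant-side parameter is treated the same way at
the species level, because a single shared constant would collapse the
community hierarchy on that side.

### Data augmentation

`n_aug` (default 10) all-zero detection rows are appended, each with an
inclusion indicator `w_i ~ Bernoulli(ω)`. `Z_ij ~ Poisson(λ_ij · w_i)`, so
an excluded species has `Z ≡ 0`; its latent abundance is defined as 0 (not
missing) so derived site summaries are always well defined. Inclusion
indicators are sampled for every all-zero row — augmented rows and any
focal species never recorded — and are fixed at 1 by the data for any
species with a detection.

### Priors

"Noninformative but proper" is made concrete as: hypermeans
`Normal(0, 10)`; community SDs `Uniform(0, 5)`; `ω ~ Uniform(0, 1)`. All
are vague on the link scale.

## Sampler

A purpose-built Metropolis-within-Gibbs cycle, vectorized across species:

- **Latent `Z_ij`** — exact enumeration of the full conditional
  `∝ Poisson(z | λ_ij) · Binomial(Y_ij | V_j, p(z))` over `{0, …, z_max}`.
  `z_max` defaults to 50. During burn-in the support grows (×1.5, capped at
  400) whenever the running estimate of posterior mass in the top bin
  exceeds 1e-6; growth can be disabled (`adapt_z_max=False`) when a fixed
  truncated model is wanted. Post-burn-in hits at the bound trigger a
  warning. Truncation is an implementation necessity — the latent Poisson
  support is unbounded — and the 1e-6 mass bound keeps its effect far below
  Monte-Carlo error.
- **Species coefficients and constants** — per-coordinate adaptive
  random-walk Metropolis, one proposal per coefficient per sweep shared
  across species (the likelihood factorizes over species, so acceptance is
  per-species). Parameters of species whose likelihood is currently flat
  (excluded species; and, in Model 1, detection parameters of species with
  `Z` all zero) are refreshed by a direct draw from their community
  distribution.
- **Hypermeans** — conjugate normal updates.
- **Community SDs** — two complementary moves per sweep: an exact draw from
  the centered full conditional (inverse-gamma in `σ²`, truncated at the
  prior bound) and a non-centered interweaved rescaling that holds the
  standardized species residuals fixed, proposes `σ` on the log scale, and
  moves all species values with it, accepting on the data likelihood.
  A single centered update mixes very slowly when a community SD is small
  (the funnel geometry); the interweaving breaks that coupling and is what
  lets short diagnostic runs reach Rhat ≤ 1.1.
- **`w_i` and `ω`** — Bernoulli and Beta full conditionals.

Proposal scales adapt toward 35% acceptance with a diminishing
Robbins–Monro step during burn-in only, and are frozen afterwards so the
retained draws target the exact posterior. Chains are initialized from
overdispersed random states on independent substreams of one seed; fixing
the seed fixes every draw bit for bit.

Convergence is monitored by the Brooks–Gelman potential scale reduction
factor on all community hyperparameters (and species coefficients in the
full summary), with the conventional Rhat ≤ 1.1 rule. Zero-variance chains
are flagged with a warning rather than returning NaN.

## Detection histories

Records are collapsed to detection/nondetection per 5-day occasion
(multiple photographs within an occasion count once). A 49-day deployment
yields nine full occasions plus a 4-day remainder; the remainder is kept by
default (`V_j = 10`), with a `drop` policy (`V_j = 9`) exposed because
either convention is defensible. All stations share one calendar anchored
at the deployment start. Distances are standardized with the sample SD
(n−1 divisor); standardization is affine, order-preserving and idempotent.

## Derived site summaries

Per retained draw and station: richness `#{i : w_i = 1, Z_ij ≥ 1}`,
aggregated abundance `Σ w_i Z_ij`, aggregated biomass
`Σ w_i Z_ij m_i` (kg) over observed species. Augmented species count toward
richness and abundance but not biomass — no body mass exists for a
hypothetical species; this is the only self-consistent option and implies
reported biomass is a slight lower bound when augmented species carry
posterior mass. Summaries are computed per draw, not on posterior means, so
the downstream stage sees the full estimation uncertainty. Under this
presence definition abundance ≥ richness holds per draw and is asserted in
the tests.

## Linear mixed models

Each summary is regressed on distance and stratum (no interaction; the
community-level interaction is already examined upstream) with a station
random intercept:

    y = Xβ + u_station + ε,   u_j ~ N(0, τ²),   ε ~ N(0, σ²).

Response rows are a thinned subset of posterior draws per station (default
100). With one row per station the random intercept would be confounded
with the residual; the draw-replicate design is what makes the station
variance estimable. Priors: improper flat on β, inverse-gamma(0.001, 0.001)
on both variances. The Gibbs sampler draws (β, u) as one joint Gaussian
block given the variances: because the covariates are station-level, β is
identified only through the shrinkage of u, and one-at-a-time updates
random-walk along the β–u ridge, while the joint block crosses it in a
single draw (Rhat ≈ 1.00 within a few thousand iterations). An effect is
"supported" when the central 95% credible interval of its pooled draws
excludes zero.

## Effect tables and counts

Per coefficient, the table carries one row per observed species plus the
community-level `All.sp` row (the hypermean). Direction is set by the 95%
interval; a row is flagged *marginal* when the 95% interval includes zero
but a weaker interval (default 90%, configurable — the threshold behind
"marginal" labels in this literature is rarely stated) excludes it. Species
are ordered by descending body mass, community row first; species missing
from the trait table sort last and are flagged. Stratified record counts
report the percent surplus of the no-dogs stratum truncated (not rounded)
to an integer percent.

## Synthetic data generator

The generator draws the study design itself: 2 strata × 10 stations with
uniform distances on [0.54, 5.1] km, 29 species (trait rows from the
bundled focal table), 49 days in 5-day occasions, species parameters from
the community hyperdistributions, `Z` and `Y` from the model, and 1–3
timestamped records placed uniformly inside each detected occasion.
Collapsing records by occasion reproduces the generating `Y` exactly, which
is the round-trip the history builder is tested against.

Default hyperparameters describe a moderately detectable community with a
positive distance gradient and a depressed dogs-allowed bank:
`mu_beta = (0.0, 0.5, −0.6, 0.0)`, `sigma_beta = (0.8, 0.4, 0.4, 0.25)`,
`mu_detect = −1.5` (r ≈ 0.18), `sigma_detect = 0.6`, `ω = 0.75`. These give
realized per-species detection frequencies and record totals of the same
order as a real 49-day tropical-forest deployment. The generator does not
emulate animal movement, trap attraction, camera malfunction, staggered
deployments, spatial or temporal autocorrelation, or misidentification —
so passing recovery tests demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness of the model
to real-data violations of them. All stations are assumed to run the full
49 days.

## Problem sizes used in the checks

Diagnostic and recovery runs use deliberately reduced MCMC budgets, chosen
as the smallest sizes at which the checks are statistically meaningful:
convergence of Model 1 on the default survey uses 3 chains × 5,000
iterations (2,500 burn-in, thin 5); the coverage experiment uses 50
replicate surveys fitted with 2 chains × 1,000 iterations under a
strong-signal community (`mu_beta = (0.3, 0.8, −0.8, 0.0)`,
`mu_detect = −1.0`, `ω = 0.8`), pooling the five hypermean interval
indicators; the exact-enumeration consistency check runs a tiny 2-species,
3-station instance with fixed truncation. Production analyses should use
the conventional long protocol (3 chains × 100,000, burn-in 50,000,
thinning 100 — the package defaults).

## Known limitations

- Single-season model: no dynamics, no spatial autocorrelation terms, no
  model selection (WAIC/DIC).
- `λ`–`r` weak identifiability: with few occasions the likelihood has a
  ridge (large `Z`, small `r`); the hierarchical structure and priors
  regularize it, but single-species fits on small data inherit wide,
  correlated posteriors, and the latent support can grow toward its cap on
  the ridge.
- Biomass excludes augmented species by construction.
- The mixed-model stage treats posterior draws as exchangeable response
  replicates; it propagates upstream uncertainty but is not a formal joint
  model of both stages.
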