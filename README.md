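# camsom

Hierarchical multispecies abundance–detection modelling for camera-trap
surveys that compare wildlife communities under contrasting hunting
regimes.

The motivating design is a small Amazonian survey: 20 camera traps split
between the two banks of a river — hunting assisted by dogs allowed on one
bank, not on the other — at varying distances (0.54–5.1 km) from the human
community, running continuously for 49 days. The questions are ecological:
does distance from the settlement, or the hunting-with-dogs stratum, change
site-level species richness, aggregated relative abundance, and aggregated
biomass, and which species drive the change?

## The model

Detections are binned into 5-day occasions. For species *i* at station *j*,
the occasion-level detection probability is induced by latent local
abundance (the Royle–Nichols mechanism):

```
p_ij = 1 − (1 − r_ij)^Z_ij
Y_ij ~ Binomial(V_j, p_ij)          # detected occasions out of V_j
Z_ij ~ Poisson(λ_ij)                # individuals available for detection
```

where `r_ij` is the per-individual, per-occasion detection probability.
`Z` is habitat-use intensity, not absolute density. Covariates (intercept,
standardized distance, stratum dummy, distance × stratum) enter either
`log λ` (Model 1, `r` species-constant) or `logit r` (Model 2, `λ`
species-constant) — two small-parameter variants of the same community
model. Species-level parameters are exchangeable draws from community
normal hyperdistributions (`mu`, `sigma` per coefficient — the "All.sp"
level), which shares strength across rarely detected species. Ten all-zero
augmented species with Bernoulli(ω) inclusion indicators let posterior
richness exceed the observed species count.

Fitting is by a purpose-built Metropolis-within-Gibbs sampler (exact
enumeration for `Z`, conjugate updates for inclusion indicators, ω and
hypermeans, adaptive random-walk Metropolis plus an interweaved rescaling
move for species coefficients and community SDs). Convergence is judged by
the Brooks–Gelman potential scale reduction factor (Rhat ≤ 1.1).

From the Model 1 posterior, per-draw per-site **richness**, **aggregated
abundance** and **aggregated biomass** (abundance × mean body mass, summed
over species) are derived, and each is regressed on distance and stratum in
a Bayesian Gaussian linear mixed model with a station random intercept,
fitted by a conjugate Gibbs sampler. An effect is "supported" when its 95%
posterior credible interval excludes zero.

A synthetic-data generator reproduces exactly this design and generative
structure, so the whole chain is testable by parameter recovery without any
field data. A 29-species trait table (codes, game status, body masses) for
the focal Amazonian community ships with the package.

## Worked example

```python
import camsom

ds = camsom.simulate_dataset(camsom.SimulationScenario(seed=1))
cfg = camsom.MCMCConfig(n_chains=3, n_iter=5000, burn_in=2500, thin=5, seed=2)
draws = camsom.fit_msom(ds.history, ds.stations,
                        camsom.ModelSpec(variant="abundance"), cfg)
print(draws.summary(include_species=False).round(3))
```

```
                    mean     sd   q2.5    q50  q97.5   rhat
parameter
mu_intercept      -0.141  0.219 -0.616 -0.135  0.257  1.008
sigma_intercept    0.979  0.183  0.696  0.953  1.389  1.007
mu_distance        0.653  0.086  0.486  0.650  0.828  1.008
sigma_distance     0.257  0.094  0.075  0.255  0.446  1.000
mu_dogs           -0.446  0.119 -0.688 -0.443 -0.213  1.058
sigma_dogs         0.208  0.145  0.009  0.191  0.526  1.013
mu_dist_x_dogs    -0.199  0.119 -0.439 -0.192  0.019  1.015
sigma_dist_x_dogs  0.286  0.156  0.029  0.277  0.611  1.015
mu_detect         -1.392  0.116 -1.635 -1.389 -1.170  1.054
sigma_detect       0.412  0.132  0.184  0.402  0.689  1.051
omega              0.740  0.069  0.600  0.744  0.865  0.999
```

Every Rhat is below 1.1, so the three chains agree. The community-level
distance effect on log abundance is positive (`mu_distance`: mean 0.65,
95% interval [0.49, 0.83] excluding zero — habitat use rises away from the
settlement) and the hunting-with-dogs stratum effect is negative
(`mu_dogs`: −0.45 [−0.69, −0.21]). This dataset was simulated with
`mu_distance = 0.5` and `mu_dogs = −0.6`, both inside their intervals.

Propagating the posterior into the site summaries and the richness mixed
model:

```python
summ = camsom.site_summaries(draws, ds.traits)
data = camsom.prepare_lmm_data(summ, ds.stations, "richness",
                               draws_per_site=100, seed=3)
post = camsom.fit_lmm(data, camsom.LMMConfig(seed=4))
print(post.summary().round(3))
```

```
             mean     sd    lo95    hi95   rhat   support
effect
intercept  16.789  0.885  15.019  18.569  1.000  positive
distance    4.223  0.646   2.967   5.481  1.000  positive
dogs       -2.937  1.273  -5.469  -0.438  1.001  negative
```

Expected site richness is about 16.8 species at an average-distance
no-dogs station, rises by ~4.2 species per SD of distance, and is ~2.9
species lower on the dogs-allowed bank (all three 95% intervals exclude
zero).

The same chain is available from the shell:

```sh
camsom simulate --seed 1 --outdir run/
camsom build-history --records run/records.csv --stations run/stations.csv \
    --survey-start 2018-06-01 --out run/history.csv
camsom fit --history run/history.csv --stations run/stations.csv \
    --model abundance --seed 2 --outdir run/
camsom derive --draws run/msom_abundance_draws.npz --out run/site_summaries.csv
camsom lmm --response richness --summaries run/site_summaries.csv \
    --stations run/stations.csv --out run/lmm_richness.csv
camsom all --outdir run/   # everything, plus effect tables and a manifest
```

`camsom report` prints stratified record counts, e.g. a survey with 2025
records on the no-dogs bank and 1680 on the dogs bank totals 3705 focal
records, a 20% surplus without dogs.

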