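# Methods

## The problem

In many landbird species an adult in its second calendar year (a
"yearling", banding code SY) can be distinguished in the hand from an older
adult (ASY). The proportion of yearlings among determinate-aged adults,
SY/(SY+ASY), is a demographic signal of habitat quality: if older birds
despotically exclude yearlings from preferred habitat (or yearlings simply
settle in poorer sites), yearling proportion should be elevated in marginal
habitat and depressed in preferred habitat. This package implements the
full analysis chain for that question on constant-effort mist-netting
(MAPS-style) capture data: record curation, aging-quality estimation,
yearling-proportion statistics, remote-sensed greenness covariates, and a
multispecies hierarchical model — plus a forward simulator so every stage
can be tested against known truth without any field data.

## Data model and curation

A capture record is one handling of a banded bird (band id, species,
station, date, age code HY/SY/ASY/AHY). The unit of analysis is the
*year-unique individual*: one bird counted once per calendar year,
recounted if it returns in a later year. Resolution rules:

- A band-year resolves to a determinate age (SY or ASY) if any handling
  that year was determinate; otherwise to AHY (indeterminate adult).
- If both SY and ASY were recorded in one year, the latest call by date
  wins. Later handlings (and photographic review) supersede earlier field
  calls; conflicts are counted and reported.
- Juvenile (HY) birds are excluded at resolution time, not parse time, so
  juvenile counts remain available for diagnostics.
- A bird handled at several stations in one year is attributed to the
  station of its first capture that year — a deterministic convention; the
  choice is essentially arbitrary and is flagged as such.

Target species are those averaging at least 20 adult year-unique
individuals (SY+ASY+AHY) per study year.

## Age-determination error

Recaptured birds are re-aged independently at each handling, so recapture
histories measure aging reliability. A handling is an *eligible comparison*
when both the current call and the most recent prior call on the same bird
are determinate; the prior call is propagated forward (SY becomes ASY after
one year; ASY is absorbing) and a disagreement counts as a *change*. The
per-species change rate is changed/eligible; the community rate is the
unweighted species mean. Comparing against the most recent prior call
(rather than the first ever) localises errors to single handlings.

If each independent determination errs symmetrically with probability
`e`, two same-year determinations of one bird disagree with probability
`2e(1-e)`. A between-year comparison is different: any determinate prior
propagates to ASY one year on, so it contradicts the current call only
when the *current* call errs — probability `e`, not `2e(1-e)`. The
convergence property asserted in the tests therefore uses a generator
configuration with between-year recaptures disabled, where the `2e(1-e)`
limit is exact; with between-year comparisons mixed in, the measured rate
falls between `e` and `2e(1-e)`.

## Yearling proportion

SY/(SY+ASY), with AHY birds excluded from both numerator and denominator
(they are accounted for in the aging-completeness statistic and enter the
model as unknown-age outcomes). Two community summaries are computed and
deliberately kept distinct: the unweighted species mean of proportions
(the community statistic) and the pooled ratio ΣSY/Σ(SY+ASY) (dominated by
abundant species). Proportions are exact ratios internally; presentation
rounding is half-up at 3 decimals.

## Habitat covariates

The remote-sensed covariate is the June Enhanced Vegetation Index (EVI) on
0.25 km cells. A station is summarised by the mean over a 9×9 grid of 81
cells and two June composite dates (up to 162 values per station-year);
missing cells are excluded from the mean and counted, never zero-filled.
Satellite retrieval is out of scope — cell values arrive as a long CSV.
The covariate is centered at zero before modelling; the stored mean maps
intercepts back to the raw scale.

In-situ habitat structure is cover in three strata (understory 0.5–5 m,
midstory 5–15 m, upperstory >15 m) per broad habitat type, combined into
station values weighted by habitat-type proportions (which must sum to 1
within 0.01).

Greenness versus reclamation is summarised by an OLS regression of
station-year EVI on percent natural cover and years since reclamation
(data year minus reclamation start year, clamped at 0; un-reclaimed
stations enter at 0), over the disturbed and reclaimed stations.
Coefficients are standardized — response and predictors scaled to unit
sample (n−1) standard deviation — with normal-theory 95% CIs; a condition
number above 30 triggers a collinearity warning.

## Hierarchical model

For year-unique adult i of species j at station k in year t:

    y_i ~ Bernoulli(p_i),  logit(p_i) = alpha_j + beta_j * evi_kt
    alpha_j ~ Normal(mu_alpha, sigma_alpha)
    beta_j  ~ Normal(mu_beta,  sigma_beta)

with y = 1 for SY, 0 for ASY, missing for AHY. Hyperpriors are weakly
informative: Normal(0, 10) on the hypermeans, Uniform(0, 10) on the
hyper-standard-deviations; both are configurable. AHY adults are treated
as missing at random and excluded from the likelihood — equivalent to
integrating out the latent age — so a fit with and without AHY rows gives
identical draws at a shared seed. An optional post-hoc imputation draws
latent ages for reporting only.

### Sampler

Metropolis-within-Gibbs, fully vectorised across species:

1. joint random-walk update of each species' (alpha_j, beta_j), accepted
   per species (species are conditionally independent given the
   hyperparameters); per-species Bernoulli log-likelihoods are accumulated
   with a single `bincount` pass;
2. interweaved ancillarity–sufficiency moves: a *translation* proposing
   (mu + δ, all effects + δ) and a *scale* proposing
   (mu + c·(effects − mu), c·sigma) with log-acceptance Δloglik + log c.
   These are essential here: per-species slopes are weakly identified (the
   EVI covariate spans only ~0.3 units), and without them the hypermean
   effective sample size was two orders of magnitude below the draw count;
3. conjugate normal updates of the hypermeans and bounded
   shrinkage-slice updates of the hyper-standard-deviations.

Proposal scales adapt during warmup (targets 0.35 for the 2-d species
blocks, 0.44 for the 1-d interweaved moves). Defaults are 3 chains of
2,000 warmup + 2,000 retained draws; runs are reproducible from a base
seed via per-chain child streams. Convergence is checked with
split-R̂ (< 1.1) and bulk ESS (≥ 400) on every monitored parameter;
violations are surfaced as warnings on the posterior object and collected
into run reports, never dropped. Hyperparameters can be clamped
(`fixed_hypers`) for single-species fits, pooling limits, and oracle
tests. Recovery studies that refit the model across many replicates use 2
chains of 1,500 + 1,500, which keeps hypermean ESS in the 600–900 range
at a fraction of the default cost.

### Post-processing

Species are profiled by capture-weighted EVI use: each adult year-unique
individual contributes its station-year EVI; the species mean assigns a
habitat group by sample quartiles across species (lowest quartile =
successional, middle two = intermediate, top = mature; boundary species go
to the lower group, quantiles use linear interpolation). Group summaries
average beta_j within group per draw and summarise across draws. A
meta-regression (standardized OLS, same conventions as above) relates
per-species posterior-mean coefficients to the species' EVI mean and EVI
range; posterior uncertainty in the coefficients is not propagated.

## Synthetic data

The generator runs the analysis model forward under explicit study
conditions and emits the ground truth beside the data.

- **Stations**: 15 natural (>90% natural cover), 15 disturbed, 5 reclaimed,
  over six years. True station-year EVI ramps linearly from a station floor
  (set by natural share, or the reclaimed floor) to the natural-station
  mean, reaching parity at 20 years since reclamation; 81-cell composites
  add composite-level and cell-level Gaussian noise, clipped to the valid
  EVI range.
- **Community**: 29 species with true intercepts/slopes drawn from the
  hyperdistribution (defaults mu_alpha = −0.38, i.e. mean yearling
  proportion ≈ 0.41; sigma_alpha = 0.5; mu_beta = −1.29; sigma_beta = 1).
  Abundance is lognormal across species, calibrated so the six-year
  community produces on the order of 13,000–14,000 adult bird-years, with
  a log-linear EVI tilt per species so species sort into successional/
  mature habitat-preference groups.
- **Observation layer**: each bird-year is masked to AHY with probability
  0.118 (matching an 11.8% indeterminate share); unmasked determinations
  flip SY↔ASY independently with probability 0.0423, the solution of
  2e(1−e) = 0.081, so paired re-determinations disagree at the 8.1%
  community change rate; within-year extra captures are Poisson(0.35)
  and between-year returns Bernoulli(0.085) per year (returned bird-years
  are truly ASY), matching a ~1.36 captures-per-bird-year ratio and ~8%
  between-year recapture share. Juvenile (HY) captures are generated at a
  configurable rate purely to exercise their exclusion.

Identical (config, seed) reproduces output byte for byte. Presets:
`paper-like` (above), `null` (no habitat effect: mu_beta = sigma_beta = 0),
`error-free`, `high-missingness`, and a miniature `smoke` community for
fast end-to-end tests. The `null` preset intentionally sets sigma_beta = 0
(every slope exactly zero); the generator accepts zero dispersions even
though the fitted model requires positive ones.

### What the generator does not emulate

Net-level capture effort, weather, within-season timing, movement between
stations, direction-biased aging errors, and non-random masking. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated generative assumptions, not robustness to every
field reality.

### A known, quantified limitation: attenuation under the full
observation process

The inferential model — by design the raw-proportions model, with no
misclassification correction — is mildly misspecified with respect to the
generator's observation layer, and the community slope is attenuated
toward zero. Holding everything else at the default scenario, the mean
posterior mean of mu_beta across replicates (truth −1.29) is ≈ −1.27 with
a clean observation layer, ≈ −1.18 with between-year returns only
(returned bird-years are structurally ASY, diluting the EVI signal),
≈ −1.23 with misclassification only, and ≈ −1.09 with both. The resulting
~0.2 bias is comparable to two-thirds of the posterior standard deviation,
so nominal 95% intervals cover the generating value in roughly 85–90% of
replicates rather than 95% — the dominant contributor being the aging
error rate that the generator is deliberately calibrated to exhibit.
This is a property of the estimand/observation-process pair, not of the
sampler: with the observation layer disabled the estimator is unbiased
and calibration is nominal.

## Numerical conventions

- Proportions: NaN (flagged), never 0, on empty denominators; hard errors
  when an operation has no defined result at all (no species with a
  defined rate, empty covariate).
- Presentation rounding half-up via `decimal`; internal values unrounded.
- Non-finite parameters get log-posterior −inf; sigma supports are open at
  0 and closed at the prior upper bound.
- Ties in within-year capture ordering break by file order (stable sorts
  throughout).
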