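# yearlings

Adult age structure analysis for constant-effort landbird capture data.

Many landbirds can be aged in the hand as yearling adults (second calendar
year, banding code SY) or older adults (ASY); birds left indeterminate are
coded AHY. The *yearling proportion* SY/(SY+ASY) is a little-used vital
rate that tracks habitat quality: where older adults exclude yearlings
from preferred breeding habitat, yearling proportion rises in marginal
sites and falls in preferred ones. This package implements the analysis
chain for a multi-species, multi-station study of that signal — built for
demographic monitoring data in the style of the MAPS (Monitoring Avian
Productivity and Survivorship) program — and a forward simulator with
known ground truth so the whole pipeline is testable offline.

Stages (each a module, usable independently):

- `capture_data` — parse and validate banding records; resolve them to
  year-unique individuals (one bird per calendar year) with a
  determinate-age precedence rule; per-species summaries and the ≥20
  adults/year target-species filter.
- `age_quality` — age-determination error rates from recapture histories
  (a determinate call is propagated forward — SY becomes ASY after a year
  — and compared with the next determinate call), plus aging-completeness
  statistics.
- `yearling_stats` — per-species proportions, the unweighted community
  mean, and the pooled ratio (kept distinct, because they differ).
- `evi_habitat` — station-year greenness from 81-cell Enhanced Vegetation
  Index (EVI) grids averaged over two June composites; weighted in-situ
  cover; the EVI ~ %natural + years-since-reclamation regression with
  standardized coefficients.
- `hier_model` — the core model: a multispecies hierarchical
  Bernoulli/logit regression of yearling probability on centered EVI,

      logit(p_i) = alpha_j[i] + beta_j[i] * evi_kt,
      alpha_j ~ N(mu_alpha, sigma_alpha),  beta_j ~ N(mu_beta, sigma_beta),

  fit by an adaptive Metropolis-within-Gibbs sampler with
  ancillarity–sufficiency interweaving, AHY birds entering as unknown-age
  (missing) outcomes; habitat-quartile species groups and the
  coefficient-vs-EVI-niche meta-regression.
- `synthetic` — the generator: reclamation-driven EVI trajectories,
  species effects drawn from the community hyperdistribution, symmetric
  SY/ASY misclassification, AHY masking, and within/between-year
  recaptures, with full truth emitted alongside.
- `pipeline` / `cli` — end-to-end orchestration with a manifest
  (config hash, seed, input digests, per-stage counts and warnings).

A packaged 29-species community table (`yearlings.table1`) from a six-year,
35-station boreal-forest study drives the count-level statistics.

## Worked example

Community statistics from the packaged table:

```
$ yearlings run-all --table1 --out runs/table1
{
  "n_species": 29,
  "total_year_individuals": 13790,
  "total_SY": 4943,
  "total_ASY": 7224,
  "total_AHY": 1623,
  "mean_yearling_proportion": 0.40689264279452797,
  "pooled_yearling_proportion": 0.40626284211391467,
  "min_yearling_proportion": 0.17757009345794392,
  "max_yearling_proportion": 0.6134020618556701,
  "percent_aged": 0.8823060188542422,
  "ahy_share": 0.1176939811457578,
  "mean_age_error_rate": 0.08396551724137931,
  "percent_initial_ahy": 0.25288579179743603,
  "percent_ahy_redetermined": 0.6586032814472024
}
```

Reading: of 13,790 adult year-individuals, 88.2% were aged to SY or ASY;
the mean yearling proportion across the 29 species is 0.407 (species range
0.178–0.613), and the pooled ratio is slightly different at 0.406 —
abundant species pull it down. The mean recapture-verified age-change rate
across species computes to 0.084 from the per-species table rows.

Simulate a community with a known habitat effect and recover it:

```
$ yearlings simulate --preset paper-like --seed 1 --out runs/sim1
wrote 19164 adult bird-years to runs/sim1
$ yearlings fit --captures runs/sim1/captures.csv \
                --evi runs/sim1/evi_cells.csv \
                --habitat runs/sim1/habitat.csv \
                --chains 2 --iterations 1500 --warmup 1500 \
                --seed 1 --out runs/fit1
mu_alpha: -0.583 95% CI [-0.772, -0.378]
mu_beta: -1.339 95% CI [-2.001, -0.678]
sigma_alpha: 0.488 95% CI [0.368, 0.651]
sigma_beta: 1.170 95% CI [0.553, 1.937]
```

This community was generated with mu_beta = −1.29: a negative community
EVI effect (yearlings concentrated in less-green habitat) recovered
within its 95% credible interval. The run directory holds
the draws, per-parameter summaries (posterior mean, 95% CI, R̂, bulk ESS),
species EVI profiles with successional/intermediate/mature groupings, the
group coefficient summaries, the meta-regression, and a manifest.

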