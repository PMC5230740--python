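# alienrich

Drivers of alien bird introductions and gridded alien species richness.

## The problem

When species are moved beyond their native ranges by human activity, the
number that ends up established in a place (alien species richness, **ASR**)
is the outcome of a chain: introduction, establishment or failure, and
spread.  The count of distinct species introduced to a location —
**colonisation pressure (CP)** — is the anthropogenic driver at the head of
that chain, and analyses of ASR that lack CP data risk crediting its effect
to whatever happens to correlate with where people released animals.
`alienrich` is a pipeline for the two analyses this motivates, written for
invasion biologists and spatial macroecologists:

1. **Introduction histories.**  A dated first-record table (one record per
   species x country unit, censored to 1500–2000) is split into date
   quartiles and analysed with bespoke randomization nulls (how many
   countries received species, how much the receiving-country sets of two
   eras overlap, whether particular bird families are over-represented, with
   a sequential Bonferroni correction), a realm-of-origin chi-squared test
   with simulated p-value, a colonial-status Wilcoxon test, and a regression
   of introductions on per-capita GDP.
2. **Gridded richness modelling.**  Ranges are rasterized onto a Behrmann
   equal-area grid (96.486-km cells, 360 x 152 = 54,720 cells), per-cell ASR
   is modelled as

   ln(1 + ASR_i) = x_i' b + u_i,   u = lam W u + e   (SAR error model)

   with row-standardised 150-km neighbour weights W, estimated by
   concentrated maximum likelihood (log-determinant via the spectrum of the
   symmetrised weights).  Lagrange-multiplier tests choose between error and
   lag specifications; a minimum adequate model (MAM) is selected by forward
   stepwise search with a >4 AIC threshold, quadratic terms for six
   designated predictors, per-term removal impacts, a comparison run without
   CP, and realm-holdout cross-validation.

A synthetic-data generator with known ground truth (Gaussian-random-field
covariates, block countries in six realms, colonial-then-GDP era biases,
family-clumped species draws, distance-decay range spread) stands in for the
real introduction database, so the whole pipeline is testable offline.
External data in the documented CSV/GeoJSON schemas can be ingested in its
place.

## Worked example

```python
import alienrich as ar
from alienrich.grid import MODEL_PREDICTORS

cfg = ar.WorldConfig(seed=1)          # 20x20 world, 400 events, 60 species
world = ar.synthesize(cfg)

records = ar.censor_records(world.records)
split = ar.split_quartiles(records)
print(split.sizes, split.spans[0], split.spans[3])
# [100, 99, 99, 102] (1508, 1914) (1983, 2000)

null = ar.null_country_count(records, split.quartiles[0],
                             iterations=10_000, seed=1)
print(null.observed, null.quantiles, null.significant)
# 22.0 (21.0, 23.0, 24.0) False

table = ar.transform_table(world.grid_table)
table, removed = ar.filter_cells(table)
weights = ar.build_weights(table, threshold_km=1.5 * cfg.cell_km)
engine = ar.SarEngine(table, weights)
mam, trace = ar.forward_stepwise(engine, MODEL_PREDICTORS)
print(mam.summary())
```

```
SAR_err maximum-likelihood results
  n = 388, loglik = -124.168, AIC = 258.335, pseudo R2 = 0.6056
  lambda = 0.733803, sigma2 = 0.099774
  term                          coef        s.e.        z    P>|z|
  intercept                  1.41784     0.09960    14.24 5.55e-46
  log1p_CP                   0.15530     0.02802     5.54 2.98e-08
  sqrt_NSR                   0.01906     0.00620     3.07  0.00212
```

The quartile split shows the long historical and short modern quartiles; the
randomization null reports the observed receiving-country count against the
expected median and 2.5–97.5% range (here, a world with no era bias, so not
significant).  The selected MAM finds what the generator put in: richness
rises with colonisation pressure and with native species richness, with
strong residual spatial autocorrelation (lambda ~ 0.73) absorbed by the SAR
error term.  `ar.removal_impacts(trace.terms, engine)` ranks the terms by
the AIC cost of dropping them (here CP dominates, +26.0 vs +5.5).

The same stages run end to end from a config file:

```bash
alienrich run --config demo.yaml --out results/demo
```

writing the quartile table, null-distribution JSONs, grid table, weights,
scan, MAM report, removal impacts and CV folds, plus a manifest with seeds
and row counts.  Repeated runs with the same config and seed are
byte-identical (manifest timing aside).

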