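# Methods

This note describes the models and procedures implemented in `alienrich`,
the design choices behind them, and what the synthetic data generator does
and does not emulate.

## The scientific setting

Alien species richness (ASR) in a spatial unit is the end point of a
multistage process: species are transported and introduced (the count of
distinct species introduced to a location is its *colonisation pressure*,
CP), some introductions fail, and established populations spread into
neighbouring areas.  ASR is therefore expected a priori to be a positive
function of CP, and analyses of ASR that lack CP data risk attributing its
effect to whatever covariates correlate with where humans released species.
The package implements the two analyses this logic motivates:

1. **Introduction histories** — who, where and when: a dated first-record
   table (one record per species x country unit) is censored to 1500–2000,
   split into date quartiles, and interrogated with bespoke randomization
   nulls (number of receiving countries, between-era country overlap,
   per-family introduction counts), a realm-of-origin chi-squared test, a
   colonial-status Wilcoxon test and a GDP regression.
2. **Gridded richness modelling** — per-cell ASR on an equal-area grid is
   regressed on anthropogenic and environmental predictors, with CP first
   among them, using simultaneous autoregressive (SAR) models and
   AIC-threshold stepwise selection, validated by realm-holdout
   cross-validation.

## Equal-area grid

The analysis grid is a cylindrical equal-area (Behrmann, standard parallel
30°) grid with 96.486-km cells: 360 columns x 152 rows = 54,720 cells after
partial polar cells are omitted.  One column spans exactly 1° of longitude.
The sphere radius is derived from the cell size (360 x 96.486 km spanning
the full circumference at the standard parallel), which makes the projection
self-consistent and every cell exactly equal in projected area.  Cells are
indexed (row, col) from the north-west, 0-based, with half-open extents
[x_min, x_max) x (y_min, y_max] so every projected point maps to exactly one
cell; a degenerate point range lying exactly on a shared cell corner is
assigned to the lowest touching cell id.  These conventions are stated here
because nothing in the problem fixes them.

A species is scored present in a cell if *any* positive-area overlap exists
between its range and the cell, so small island populations still count.
ASR counts each species' most recently dated established map; CP counts
introduction-location maps regardless of outcome; the per-cell first-record
year is the minimum date over all alien maps touching the cell (when a cell
has both introduction and establishment dates, the earliest is used).

Cells where both CP = 0 and ASR = 0 carry no information about
establishment and would inflate covariation measures (the double-zero
problem); they are excluded, as are cells with any missing covariate, with
per-rule removal counts reported.

### Predictor transformations (fixed by design)

| raw column                | transform                  |
|---------------------------|----------------------------|
| ASR, CP                   | ln(1 + x)                  |
| time since first record   | ln(x)                      |
| distance to historic port | sqrt(x / 1000), m to km    |
| native species richness   | sqrt(x)                    |
| median elevation          | ln(x + 30)  (minimum -29.7 m) |
| elevational range, temperature range, precipitation | sqrt(x) |

Median temperature, human footprint and 8-neighbour habitat complexity
enter untransformed.  Re-applying the transform step is detected and
refused.  A collinearity screen reports pairwise Pearson correlations and
applies a fixed a-priori exclusion list (temperature min/max/range, median
elevation, 24-cell habitat complexity, population-density and
distance-to-city variants), leaving nine predictors for model building;
additional pairs above |r| = 0.7 are reported as warnings only.

## Spatial weights and diagnostics

Neighbours are cells whose centroids lie within 150 km, which on the
96.486-km grid captures exactly the eight surrounding cells; weights are
row-standardised, isolated cells are flagged and excluded from the row-sum
rule.  Moran's I uses the standard cross-product form with E[I] = -1/(n-1)
and a permutation p-value (one-sided in the direction of the observed
departure).  Spatial correlograms recompute Moran's I with binary weights
per distance band; empty bands are reported as missing.

Lagrange-multiplier tests on OLS residuals (classical LM-error and LM-lag
statistics, chi-squared with 1 df) choose between the two SAR
specifications; the larger statistic is the recommendation.

## SAR estimation

Two Gaussian models on the transformed response y = ln(1 + ASR):

* **SAR error**: y = Xb + u, u = lam W u + e;
* **SAR lag**:  y = rho W y + Xb + e.

Both are fitted by concentrated maximum likelihood.  For fixed spatial
parameter the coefficients and error variance have closed-form profiles, and
log|I - lam W| is evaluated from the eigenvalues of the symmetrised weight
matrix D^-1/2 B D^-1/2 (similar to the row-standardised W, hence the same
spectrum).  The eigendecomposition is computed once per neighbour structure
and cached, so repeated fits during stepwise selection are cheap.  The
feasible interval for the spatial parameter is (1/omega_min, 1/omega_max)
shrunk by a 1e-6 interior margin; optimisation is a bounded scalar search
with tolerance 1e-8, with an explicit guard that the optimum is never worse
than independence (lam = 0).  The eigenvalue route is exact but dense
(O(n^3) once), sized for grids up to a few thousand included cells — the
scale of all analyses here.

AIC counts the regression coefficients plus the error variance plus the
spatial parameter.  Fitted values for the error model include the spatial
signal (Xb + lam W (y - Xb)); the pseudo-R² is the squared Pearson
correlation between fitted and observed values and is illustrative only.
Coefficient standard errors are conditional on the estimated spatial
parameter.

## Model selection

Quadratic terms are allowed for six designated predictors (CP, time since
introduction, native richness, elevational range, median temperature,
precipitation) and admitted only when the linear+quadratic single-predictor
model improves AIC by strictly more than 4.  The minimum adequate model
(MAM) is built by forward stepwise selection: start from the best
single-predictor model, add the candidate with the largest AIC improvement
> 4 at each step (ties broken lexicographically), stop when none qualifies,
then offer every excluded predictor once more (a pure re-add pass; no
backward elimination).  A quadratic term never enters without its linear
term, and removing a linear term removes its quadratic — the hierarchy is
implied but not stated by the protocol, so it is fixed here.  Removal
impacts report the AIC increase from dropping each MAM term; by construction
of the selection rule each exceeds 4.

The no-CP comparison repeats the identical procedure with CP (and CP²)
removed from candidacy and reports the AIC gap and any newly admitted terms:
when CP mediates a covariate's effect on richness, that covariate is
expected to stand in for CP in the reduced model.  Because the search is
greedy, the no-CP model can occasionally find a path the full search missed;
the gap is reported signed.

Realm-holdout cross-validation holds out one biogeographic realm at a time,
re-runs the full selection on the remaining realms with the neighbour
weights rebuilt on training cells only, and predicts the held-out realm from
the regression trend Xb alone — no spatial smoothing crosses the train/test
boundary, which makes the RMSE an honest out-of-realm error.  Realms below
`min_n` cells (default 100 at study scale; demo runs scale the floor to the
world size) are excluded and reported.

## Randomization nulls

* **Country count**: each iteration draws the era's record count at random
  without replacement from the full censored set and counts distinct
  receiving country units (or species).  Two-tailed significance is declared
  when the observed count falls strictly outside the [2.5%, 97.5%] quantiles
  of the draws; a +1-corrected doubled-tail Monte-Carlo p-value is reported
  alongside.  On a discrete statistic with narrow support the strict
  quantile rule is conservative (attained size below alpha); at the study's
  scale (thousands of records, hundreds of country units) the attained size
  is within the binomial band around alpha, which is what the calibration
  test checks.
* **Country overlap**: two independent subsets are drawn per iteration
  (paired by iteration index; a flag forces disjoint draws) and the shared
  country count recorded.
* **Family counts**: the introduced species are compared against draws from
  the global avifauna; per family the smaller of the two +1-corrected tail
  probabilities (Psim) is reported with its direction, and significance
  applies a sequential (Holm) Bonferroni over families ordered by Psim, at
  threshold beta_k/2 with beta_k = alpha/(m - k + 1) — halved because the
  test is two-sided.

Realm-of-origin shift uses a Pearson chi-squared on the 2 x k era-by-realm
table with a Monte-Carlo p-value from era-label permutations (both margins
fixed, 2,000 replicates).  A species' native realm is the realm holding the
largest share of its native range; exact ties (relative tolerance 1e-9 on
area fractions) exclude the species.  The colonial analysis is a two-sample
Wilcoxon rank-sum (statistic reported as the former-colony group's
Mann-Whitney U, i.e. the R convention, asymptotic p with tie correction);
whether countries with zero introductions enter is ambiguous in the
protocol, so both modes exist behind a flag (default: era-receiving
countries only).  The GDP analysis is OLS of ln(1 + introductions) on
ln(1 + GDP per capita); countries without GDP are dropped, and the fit is
deliberately not invariant to currency rescaling because of the ln(1 + x)
transform.

## Quartile split

Records are stably sorted by year and cut near ranks n/4, n/2, 3n/4, with
all records sharing a boundary year snapped into the same quartile: the
shared-year block goes to the earlier quartile when that leaves the cut
closer to the ideal rank, otherwise to the later (ties favour earlier).
This makes quartile date spans contiguous and non-overlapping, which is the
property the published spans exhibit.

## The synthetic world

The generator stands in for the real introduction database so every stage is
testable offline.  Defaults describe a desk-scale world: a 20 x 20 grid,
24 rectangular country blocks grouped into 6 contiguous realms, 60 species
in 8 families, 400 introduction events over 1500–2000 with the
historical/modern split at 1903.

* **Covariates** are stationary Gaussian random fields with exponential
  covariance (correlation length 8 cells by default), simulated by direct
  Cholesky factorisation of the cell-distance covariance — exact, O(n^3),
  intended for grids up to ~60 x 60.  Fields are rescaled to plausible
  units; native richness is a smooth increasing function of temperature and
  precipitation plus white noise.  At the default range each covariate's
  Moran's I exceeds 0.7, the strong-autocorrelation regime of real gridded
  richness data.
* **Events** follow a step-increasing yearly intensity (steps at 1850 and
  1955, levels 1:6:40), chosen so roughly a quarter of events pre-date the
  era split — a long historical quartile and a short modern one.  Before the
  split, country odds are multiplied by 8 for former-colony countries; after
  it, country log-odds are proportional to ln GDP(2000).  GDP is log-normal
  (2000 median ~ Int$4,600, 1900 levels correlated through a growth factor).
  Species are drawn with family-level clumping (Dirichlet weights,
  concentration 0.5); at most one record per (species, country).
* **Ranges**: each record receives 1–4 introduction cells concentrated
  around a per-country gateway cell (introductions pile up at ports and
  cities).  Establishment is Bernoulli with a logit linear in standardised
  covariates at the site; established species grow a range from the
  introduction cells with an exponential distance-decay kernel (e-folding
  1 cell by default — alien ranges are typically compact around release
  sites).  Established maps are *cumulative snapshots* in chronological
  order, so a species' most recently dated map is its full established range
  to date, matching the "most recent established range" convention used for
  ASR.  Outcome statuses are 1 (established) or 3 (unsuccessful); the other
  categories are accepted by parsers but never generated, since the analyses
  only distinguish established (1) from introduced (1–6).
* **Seeds**: one global seed; each stage derives an independent stream via
  `SeedSequence([seed, stage_index])` with a fixed stage table, so stages
  can be re-run in isolation and full runs are byte-reproducible.

A separate *regression-style* generator produces a grid table whose
transformed response follows a known SAR-error model (default generating
terms: ln(1+CP) with a strongly concave quadratic, and sqrt NSR; spatial
parameter 0.6, innovation sd 0.3).  The pronounced CP curvature mirrors the
dominance of colonisation pressure and its quadratic in the real system and
puts the quadratic's AIC contribution far above the inclusion threshold.
This generator is what the selection recovery studies use, because the term
set must be known exactly.

**What the synthetic world does not emulate**: coastlines and islands,
phylogenetic structure beyond family labels, propagule pressure, sub-national
recording heterogeneity, observation effort, and the long-tailed
country-size distribution of the real world.  Passing tests therefore
demonstrate the correctness and calibration of the machinery under known
ground truth, not that the real data would yield any particular estimate.

## Problem sizes and numerical choices

Recovery and calibration studies run at fixed sizes chosen to estimate the
quantities stably at desk scale: SAR parameter recovery at n = 400 with 200
replicates; stepwise recovery at n = 1,500 with 100 seeds; null-test
calibration on 3,600 records with 500 repetitions of 400-iteration nulls;
correlogram improvement over 40 seeds.  Monte-Carlo p-values use the
+1-corrected estimator and are never exactly zero.  Degenerate inputs are
errors where silent coercion would mislead (constant variables in Moran's I,
rank-deficient designs, unparseable years in external files) and logged
exclusions where the protocol expects filtering (censoring, missing GDP,
empty distance bands).

## Known limitations

* The SAR path is the package's inference engine; hierarchical Bayesian
  spatial fits (Gaussian-random-field random effects) are out of scope, so
  published coefficient *values* from such fits are targets of sign and
  ordering, not numeric reproduction.
* Dense eigendecomposition limits weights to a few thousand units; the full
  10k-cell study scale would need a sparse log-determinant, which is not
  implemented.
* Coefficient standard errors are conditional on the spatial parameter.
* The greedy stepwise search carries the usual caveats: AIC differences near
  the threshold are noisy, and about one run in ten at the default recovery
  settings admits one spurious term — the intrinsic false-inclusion rate of
  a >4 AIC rule over nine candidates.
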