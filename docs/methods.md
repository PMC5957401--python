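# Methods

This note documents the statistical models and numerical procedures
implemented in `mldendro`, the choices made where several constructions
were defensible, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

All inputs are reduced to one canonical long table (`HierSeries`):
measurement columns first, then time units (month before year), then
classification factors ordered from the innermost sampling level to the
outermost (core within tree within plot).  Wide growth tables carry
years in rows and dot-separated hierarchy codes in column headers
(`plot.tree.core`, outer levels first); wide climate tables use
`plot.Mon` headers with English three-letter month abbreviations.
Factor codes are kept as strings throughout — a tree labelled "17" is a
label, not a number.  Uniqueness of the (factor path, time path) key is
enforced at construction.

## One-level routines

**Relative times (`rtimes`).**  Within an evaluation group (by default
a tree), `time = year - min(year) + 1`, with the minimum pooled over
the whole group so that replicate cores share a common clock.  With
`only_dup` the records whose time occurs in only one replicate are
dropped; this synchronisation confines the detrending fit to years
observed in at least two cores.  When the group has a single replicate
(nothing to synchronise) the filter is skipped.  The alternative
convention — per-core cambial age — was not adopted because replicate
alignment is precisely what the downstream grouping requires.

**Anchored cumulative sums (`scacum`).**  Cumulative ring widths are
shifted *additively* so that the cumulative series equals a reference
radius at a reference calendar year (`rf_t`, defaulting to the last
year of the series or the measurement year of the radius vector).  An
additive shift models a truncated core (missing inner rings) as a
constant missing radius and leaves the increments untouched
(`diff(csx) == x` exactly); a multiplicative rescaling would distort
the ring widths themselves, which are measured quantities.  Reference
radii are matched to cores by hierarchy-code prefix, so a per-tree
radius vector serves all of a tree's cores.

**Allometric transformation (`amod`).**  `y <- a_i * y**b_i` applied
recursively to the cumulative series; `(1, 1)` keeps radii, `(2, 1)`
gives diameters, `(0.25*pi, 2)` basal areas, and a fitted pair such as
`(2.87, 0.85)` converts inside-bark diameters to diameters over bark.
Increments are recomputed by differencing the transformed cumulative
series (first increment = first value) so that relative and cumulative
growth live on one scale.  Chaining many pairs compounds the error of
each allometric equation; the routines do not guard against that
beyond requiring positive bases under non-unit exponents.

**Seasonal years (`move_yr`).**  Months at or after the initial month
(default October, the start of the meteorological year in Spain) are
relabelled to the following year, months are reordered within each
seasonal year, and incomplete seasonal years at the record edges are
dropped.  The mapping is a bijection on records belonging to complete
seasonal years.

## Walter-Lieth aridity index

Monthly precipitation P (mm) and the evaporation proxy E = 2·T
(1 °C of monthly mean temperature ≈ 2 mm/month of evaporation) are
drawn as piecewise-linear curves through the midpoints of twelve
equal-width month intervals on [0, 12]; the year edges take the
December/January wrap value of the seasonal sequence, so the curve is
continuous across the (seasonal) year boundary.  The annual aridity
index is the ratio of the dry area (E above P) to the wet area (P above
E).  Both areas are integrated **in closed form** segment by segment,
splitting each segment at the sign change of E − P; this is the exact
limit of trapezoid integration on an ever finer grid, so the index is
grid-free by construction and a 10⁴-point numerical oracle agrees to
its own discretisation error (~10⁻⁷ relative).  No >100 mm
precipitation-axis compression is applied: that is a plotting
convention of the classical diagrams, whereas the index is defined
directly by the two curves.  A year whose wet area is zero has an
undefined ratio and yields `nan` with a warning rather than aborting a
multi-plot run.  The square-root transform (default) stabilises the
variance of the index across years.

## The nested mixed-model engine

The detrending models are Gaussian linear mixed models with strictly
nested grouping,

    y = X beta + sum_l Z_l b_l + e,        b_l ~ N(0, Psi_l),   e ~ N(0, sigma^2 W),

where the grouping levels l run plot / tree / core, `Psi_l` is either
diagonal (one SD per random covariate per level) or a multiple of the
identity (one shared SD), and `W` is block-diagonal over the innermost
series with blocks `D^(1/2) C D^(1/2)`: `C` the stationary ARMA(p, q)
autocorrelation evaluated at calendar-year lags and `D` the optional
"constant plus power of the fitted value" variance weights
`(rho1 + |fitted|^rho2)^2`.

**Estimation.**  All covariance parameters are expressed relative to
`sigma^2`; the restricted likelihood is profiled over `beta` (GLS) and
`sigma^2`, leaving the vector of SD ratios (log scale), ARMA
coefficients (constrained to stationarity/invertibility through the
partial-autocorrelation transform) and variance-function parameters.
Outermost groups are independent, so the marginal covariance is block
diagonal; within a block the random effects contribute a low-rank term
`W_g D W_g^T` whose rank is the number of subgroups times the number of
random covariates (~21 for the default design), and the profiled
quantities are computed through the matrix-inversion lemma from cached
cross-products.  With identity error covariance one likelihood
evaluation costs microseconds; with ARMA or variance weights the
innermost blocks are re-factored per evaluation.  Optimisation is
L-BFGS-B from moment-based starting values (the spread of OLS
group-mean residuals sets the intercept SD ratios), with additional
starting points when a correlation structure is present — a group
intercept and a strong AR term can trade off, and a single start can
land on the wrong ridge — followed by a Nelder–Mead polish, because the
log-scale profile is flat near zero variance components.  Variance
components can legitimately reach the boundary; they appear as ~1e-7
SDs, as in the standard mixed-model software output.  The
const-plus-power variance function is only weakly identified on
homoscedastic data (a flat ridge in (rho1, rho2)); fits on such data
agree with reference software in `beta` but not in the ridge position.

**Degenerate cases.**  With no grouping, correlation or weights the
model is ordinary least squares, returned exactly, with the maximised
Gaussian log-likelihood and `k = p + 1` parameters so that information
criteria line up with standard linear-model output.

**Information criteria.**  `AIC = -2l + 2k`; `BIC = -2l + k ln(N - p)`
with `p` the number of fixed-effect coefficients.  The restricted
likelihood is a likelihood of `N - p` error contrasts, and mixed-model
comparison tables conventionally apply the same effective sample size
to every model in the table, single-level fits included; this single
convention reproduces published comparison tables to their printed
precision.

**Degrees of freedom.**  Conditional t-tests use containment
denominator DF: each fixed term is assigned to the innermost level
within whose groups it is constant (terms varying within the innermost
groups, and the intercept, belong to the observation level), and level
i contributes `m_i - m_{i-1} - p_i` DF with `m_i` the group count and
`p_i` the number of non-intercept terms assigned to the level.  For
the default three-level design with two within-core covariates this
gives `N - m_cores - 2`.

**Diagnostics.**  Raw residuals are taken at the innermost level
(observed minus fixed plus all BLUP contributions).  Normalized
residuals premultiply each innermost series by the inverse Cholesky
factor of its estimated error covariance `sigma^2 W`; with `W = I`
this is division by `sigma`.  The pooled empirical autocorrelation of
grouped residuals divides the lag-l cross-products by the pair count
`N(l)` and normalises by the pooled lag-0 term; the two-sided critical
bound at level alpha is `z_{1-alpha/2} / sqrt(N(l))`.  Likelihood-ratio
tests report `2(l_big - l_small)` against the chi-square with the
parameter-count difference; comparing a restricted-likelihood fit with
a different fixed-effects structure is reported but warned about.

## Formula families and the model frame

`td_form` builds the growth-theory detrending spec
`log(x) ~ log(csx) + f(t) | plot/tree/sample` with `f(t) = t` (a
time-decline form) or `f(t) = log(t)` (a logarithmic time-decline
form), `t` being relative time or calendar year; `lme_form` builds
`resp ~ covar | group` with the response defaulting to the first
measurement column and the covariate to the year.  Random effects
default to a diagonal structure on the fixed covariates (intercept
included) at every grouping level; `lev_rm` removes levels from the
grouping term.

`model_frame` chains the one-level routines (growth default:
rtimes/scacum/amod at tree/core/core; climate default: seasonal-year
relabelling and the aridity index at the year level), fits the model by
REML, and extracts the fluctuation table — the within-group residual
series per core (or per plot for aridity), ordered by year.
Fluctuations default to raw residuals, which is what detrended-series
plots show; normalized residuals are available where the error model
matters.  The frame records its fully resolved call, so `update()` is
deterministic and an update with no changes reproduces the fit.

## Mantel correlograms

Two fluctuation sets sharing an outermost factor are compared per
growth series: Euclidean year-pair distances of the growth fluctuations
are standardised to z-scores (sample SD), the aridity-fluctuation
distances of the matching plot are binned into `ceil(1 + 3.3 log10(m))`
equal-width classes, and the statistic of class d is
`r(d) = sum w z / sum w` with binary membership weights — the mean
growth-distance z-score among the class pairs.  Note the two
consequences of that definition: `r(d)` is *not* bounded by 1 (it is a
class mean of z-scores, not a correlation coefficient), and a positive
association between the two series appears as **negative** r in the
short-distance classes, because years with similar aridity then show
below-average growth distances.  Significance per class is a two-sided
permutation test, permuting the z-matrix simultaneously by rows and
columns, with the add-one correction `p = (1 + #{|r*| >= |r|}) / (nperm
+ 1)`; seeded generators make every p-value reproducible.  Equal-width
binning over the observed range was chosen over equal-frequency
binning as the standard correlogram construction; empty classes yield
missing r.

## Synthetic data

`SimDesign` fixes the emulated study: 2 plots × 2 trees per plot × 2
cores per tree, 125-year records (1881–2005), monthly climate per plot
and one reference radius per tree.

**Dynamic growth generator (`gen_growth`).**  Ring widths follow the
logarithmic time-decline recursion with concurrent cumulative growth:
per core, `log(x_t) = A + B log(csx_t) - C f(t) + e_t` with
`csx_t = csx_{t-1} + x_t`, solved per year by fixed-point iteration
(unique for B < 1).  Coefficients receive nested plot/tree/core random
effects; residuals are white or ARMA(1,1) on the log scale.  Defaults
`beta = (0.6, 0.5, 0.7)` with `f = log` give early ring widths near
2 mm declining below 1 mm and final radii of 15–20 cm — a plausible
slow-grown pine; level SDs (0.25/0.2/0.05 intercept, 0.02/0.02/0.005
log-size slope, 0.08/0.08/0.02 time slope) and `sigma = 0.3` place
most variability between plots and trees, as the hierarchical sampling
premise assumes.  Optional truncation drops a random number of inner
rings per core while the radius vector keeps the full stem radius
(the largest core total per tree), exercising the anchoring path.

**Regression twin (`gen_growth_frame`).**  Validating the *estimator*
requires exogenous covariates: in the dynamic generator the cumulative
covariate recomputed from noisy increments contains the current year's
residual, and its variation orthogonal to f(t) is mostly accumulated
noise, so no estimator regressing on it can recover B consistently —
that is a property of the data-generating process, not of the fitting
code.  The regression twin therefore holds the cumulative covariate at
the noiseless population skeleton (identical for every core, a
balanced design) and puts the random effects and residual noise in the
response only, making the fitted model exactly the data-generating
process.  The parameter-recovery experiment (100 seeded replicates at
the design size; each coefficient within 2 SE in ≥ 90% of fits,
observed 96–97% per coefficient) runs on this twin.  Passing it shows
the REML machinery is calibrated at the study's design size; it does
not show that detrending real chronologies recovers "true" growth-law
coefficients, which the simultaneity argument above shows is not
attainable from a single noisy trajectory.

**Climate generator (`gen_climate`).**  Sinusoidal seasonal cycles
(temperature peaking, precipitation dipping in July — a Mediterranean
regime; means 11 °C and 45 mm, amplitudes 8 °C and 25 mm), per-plot
offsets, optional linear annual trends, white observation noise, and
precipitation truncated at zero.  Neither spatial correlation between
plots beyond the shared cycle nor autocorrelated climate noise is
emulated, so tests on these fixtures do not probe such structure.

## Problem sizes used by the test and acceptance runs

Routine unit tests use 20–45-year fixtures; the recovery experiment
uses the full design size (1 000 observations per replicate, 100
replicates); the permutation calibration uses 200 replicates of
20-year series at 999 permutations; the ARMA whitening check uses one
65-year design.  These sizes were chosen to estimate each quantity's
Monte-Carlo error well below the margin of its acceptance band.

## Known limitations

- Grouping must be strictly nested; crossed random effects and general
  covariance structures beyond diagonal/identity are out of scope.
- Standard errors of fixed effects are Wald-type; with two plots the
  outermost variance component is estimated from one contrast and
  intervals for plot-level quantities are anti-conservative.
- The variance function is fitted by alternating the variance
  covariate (fitted values) with the covariance parameters; on
  homoscedastic data the (rho1, rho2) profile is a flat ridge.
- Back-transformation of model predictions to the original scales
  applies no bias-correction factors; inferences concern the
  transformed scales.
- The Tucson/rwl ring-width formats are not read; CSV in the two wide
  dialects and the canonical long form is the exchange format.
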