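# Methods

`elevcomm` implements the statistical workflow used to analyse stratified
community samples collected along elevational transects: plot × species
count matrices from replicated trapping in several biogeographic
subregions, with a table of environmental predictors per plot.  This
note documents the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Study design and synthetic data

The default design mirrors a five-subregion survey of flightless ground
beetles in tropical upland rainforest: subregions SU, AU, BK, CU, WU
with elevational zones spaced ~200 m apart (4 + 6 + 4 + 6 + 3 = 23
zones), three plots per zone (69 plots), three pitfall traps per plot
sampled monthly for a year (2,484 trap-months).  Because the original
field data are not publicly deposited, the `simulate` module generates
communities with the same statistical structure, and every downstream
stage is tested against that generator.

Counts for species *s* at plot *p* are negative-binomial with log mean
`alpha_s + beta_s * elev_km(p)` and size (dispersion) `theta`:

- `beta_s ~ N(elev_effect, slope_sd)` with `elev_effect = 4.2` per km and
  `slope_sd = 0.75`; `alpha_s ~ N(-5.0, 1.0)`; `theta = 1` (strongly
  overdispersed, as pooled trap catches are).  These defaults were set so
  that the generated communities match the magnitudes the survey design
  is known to produce — a few thousand individuals over 69 plots, ~43
  species, richness and abundance rising with elevation, and lowland
  plots frequently empty.  All-zero plots are valid data, not errors.
- A configurable fraction (default 33%) of species are subregional
  endemics: their counts are structurally zero outside one randomly
  assigned home subregion.
- The 17 predictors comprise 8 bioclimatic variables, two soil-moisture
  indices (AWC, TWI), four local habitat descriptors (Habitat, Treefall,
  Litter and terrain Aspect), historical vegetation stability
  (Hist.veg), plus Elevation and Latitude.  Temperature variables fall
  with elevation at a fixed lapse rate (default 1 °C per 200 m);
  precipitation rises with elevation (cloud stripping).  Pairwise
  correlation targets between predictors are induced through a Gaussian
  copula on the predictors' latent residuals; the default target is
  r = 0.90 between Hist.veg and Seas.P, which by construction are purely
  residual-driven so the realised correlation is undiluted.  An
  infeasible (non-positive-definite) target set is rejected with the
  offending pairs named.
- Generators are pure functions of the configuration: the config seed is
  split into per-stage child seeds, so the design, environment and
  community tables are each reproducible in isolation.

What the generator does **not** emulate: spatial autocorrelation within
subregions beyond the shared elevation/subregion structure (the
within-subregion distance decay of similarity is deliberately exposed as
a free parameter rather than asserted), monthly phenology, species-level
trait differences other than intercept/slope variation, and detection
differences between trap stations.  Tests passing on synthetic data
therefore demonstrate that the estimators recover known structure of
this model class, not that real beetle data satisfy the model.

## Rarefaction and sample coverage

Sampling sufficiency is assessed per subregion (plots pooled) with
individual- and coverage-based rarefaction/extrapolation curves
extending to twice the observed sample size.

- Interpolation is classic hypergeometric rarefaction,
  `S(m) = Σ_i [1 − C(n−X_i, m)/C(n, m)]`; binomial coefficients are
  evaluated in log space (gammaln) to avoid overflow at large n.
- Sample coverage is `Ĉ = 1 − (f1/n) · (n−1)f1 / ((n−1)f1 + 2f2)` from
  the singleton/doubleton counts; `Ĉ = 1` exactly when there are no
  singletons.
- Extrapolation uses the Chao1 estimate of undetected richness,
  `f̂0 = (n−1)/n · f1²/(2f2)`, with the bias-corrected form
  `(n−1)/n · f1(f1−1)/(2(f2+1))` when `f2 = 0`;
  `S(n+m*) = S_obs + f̂0[1 − (1 − f1/(n f̂0 + f1))^{m*}]`.  Coverage
  beyond the sample uses the analytic extension
  `C(n+m*) = 1 − (f1/n)·A^{m*+1}`, not resampling.

Hill numbers of order q ≠ 0 and bootstrap confidence bands are out of
scope.

## Dissimilarity, ordination, environmental vectors

Multivariate analyses use Bray–Curtis dissimilarity on square-root
transformed abundances with a dummy pseudo-species of 1e-7 appended to
every plot, so that comparisons involving empty plots are defined (two
empty plots have dissimilarity 0).  The dummy is appended after the
transform; at 1e-7 the difference between conventions is below 1e-6 and
the choice is immaterial.

NMDS minimises Kruskal stress-1.  Configurations come from
scikit-learn's non-metric SMACOF (isotonic regression inner loop); the
first start is the classical metric-MDS eigendecomposition, the
remaining starts (default 20 in total) are random, and the best
configuration by stress-1 is kept.  Stress-1 is recomputed in-package
from the final configuration via isotonic regression, giving a
definition stable across library versions.  The configuration is
centred and rotated to its principal axes with a fixed sign convention,
so a fixed seed yields a byte-reproducible layout.  Plots with zero
total abundance are excluded from the ordination (they carry no
compositional information and their dissimilarities are dummy-driven),
but retained in the exported dissimilarity matrix.

Environmental vectors: each predictor is regressed on the ordination
coordinates; the unit coefficient vector gives the direction, R² the fit
quality, and a permutation test (shuffling the predictor across plots)
the P value.  A constant predictor reports r² = 0 with a warning.

## PERMANOVA

Distance-based permutational MANOVA with Type I (sequential) sums of
squares on the Gower-centred matrix `G = −½ J D² J`.  For ordered terms
the j-th sum of squares is `tr[(H_j − H_{j−1}) G]` with `H_j` the
projector of the cumulative design; pseudo-F uses the full-model
residual mean square.  P values permute the reduced-model residual
matrix `(I − H_{j−1}) G (I − H_{j−1})` (the Freedman–Lane scheme), with
the +1-corrected estimate `P = (1 + #{F* ≥ F}) / (n_perm + 1)`; 4,999
permutations by default.  The standard design is subregion (factor,
entered first) then actual plot elevation (covariate, entered second,
unstandardised — F statistics are invariant to linear rescaling of a
single covariate).  The "random factor" logic is carried by the
permutation scheme rather than an expected-mean-squares denominator.
Under Euclidean distances on a univariate response the pseudo-F equals
the classical ANOVA/ANCOVA F exactly, which the tests verify, along
with agreement with an independent reference implementation on a fixed
toy.  Projectors are computed by SVD, so redundant factor dummy columns
are harmless, while genuinely aliased terms raise an error naming the
term.

## Count models

The NB2 GLM (variance `mu + mu²/theta`, log link) is fitted by IRLS for
the coefficients alternating with Newton updates of `log theta` on the
profile likelihood, to a relative log-likelihood tolerance of 1e-8
(200 iteration cap).  Numerical specifics:

- For integer counts the digamma/trigamma/gammaln sums over
  observations collapse to sums over exceedance counts
  `T_j = #{y_i > j}` with elementary functions of `theta + j` — faster
  and stable at large theta.
- A step-halving guard keeps the alternation monotone in the
  likelihood; plain IRLS/profile alternation can oscillate when theta
  is small.
- `theta` is capped at 1e8 to represent the Poisson limit; when the
  profile score is still positive at large theta the MLE is reported at
  the cap.  A floor of 1e-4 guards the opposite extreme.
- The weighted least-squares systems carry a relative ridge (1e-10 of
  the Gram diagonal), which keeps quasi-separated responses (very
  sparse species) solvable without measurably perturbing regular fits.
- An all-zero response is a boundary case: the intercept is pinned at
  the linear-predictor floor, the log-likelihood is ~0, and a warning
  is emitted.
- A batched variant fits many response columns against one design in a
  single vectorised sweep with an active set (converged columns drop
  out).  The model-averaging engine calls it with permuted responses
  and species stacked as columns.

AICc is `−2ℓ + 2k + 2k(k+1)/(n−k−1)` and is undefined (an error, or
model exclusion in the averaging engine) for `n ≤ k+1`.  The parameter
count k includes the intercept, the slope coefficients and theta, so
the penalty is consistent across the model set.

The richness/abundance trend model is a random-intercept NB mixed model
(subregion as the grouping factor, actual elevation in km as the fixed
covariate) fitted by maximising the Laplace-approximated marginal
likelihood: a 1-D Newton solve for each group's conditional mode inside
a Nelder-Mead outer optimisation over (coefficients, log sigma, log
theta).  Standard errors come from the numerical Hessian of the
marginal likelihood; when the variance or dispersion sits at a boundary
(flat directions), the corresponding rows are dropped before inversion.
Wald z statistics with normal P values are reported.  Agreement with an
independent Laplace implementation (R glmmTMB, nbinom2) is verified on
fixed toys to ~0.1% in coefficients.  Elevation enters in km so the
printed slope is per-kilometre; zero plots are data and are never
dropped from trend models.

## Predictor screening

Before model averaging the 17 predictors are reduced by pairwise
correlation: when two predictors of the same property group exceed
|r| > 0.90 (strictly greater), the lower-priority member is removed,
iterating until no same-group pair exceeds the threshold (hence
idempotent).  Cross-group pairs are never removed however collinear —
notably Hist.veg and Seas.P at r ≈ 0.90 both survive, so the importance
analysis must be read with that collinearity in mind.  Elevation is
grouped with the temperature variables (at a fixed lapse rate
temperature is a linear function of elevation), so the default
screening removes Max.T, Min.T, P.Wet.Q, P.Dry.Q and Elevation,
leaving 12 predictors.  Which member of a flagged pair drops is
governed by an explicit priority list rather than an implicit rule.

## Variable importance: summed Akaike weights with a permutation null

The core inference engine fits every subset of the screened predictor
pool — 2^12 = 4,096 NB GLMs for 12 predictors — computes Akaike weights
`w_m = exp(−Δ_m/2)/Σ exp(−Δ/2)` from AICc, and scores each predictor by
the summed weight of all models containing it.  No ΔAICc cut-off is
applied; all models enter the sum.  In multivariate (composition) mode
each candidate model is fitted species-by-species on the shared subset
and the per-species AICc values are summed (per-species k, shared n);
model-averaged coefficients and prediction are out of scope.

Summed weights have no absolute scale, so significance is calibrated by
permuting response rows against the fixed predictor table (whole
community-matrix rows in multivariate mode, preserving species
co-occurrence and the predictor correlation structure), 999 null
datasets by default.  Each predictor gets a standardised effect size
`SES = (observed − null mean)/null SD` and a one-sided upper-tail
permutation P with the +1 correction.  Models whose AICc is undefined
are dropped from the weight normalisation.  Theta is re-estimated per
model; a minimum-prevalence filter for rare species in multivariate
mode exists but defaults to off.  Within the averaging engine the
likelihood tolerance is relaxed to 1e-6 — AICc movements at that scale
are orders of magnitude below anything that shifts an Akaike weight.

## Pipeline

`run_pipeline` chains screening → per-subregion rarefaction → trend
models → dissimilarity/NMDS/vector fits → PERMANOVA → model averaging
(univariate and multivariate), writing one delimited table per stage
plus a JSON manifest (seed, config hash, per-stage child seeds).  CSV
floats are written at 6 significant digits so reruns are byte-stable.
A stage failure halts the run, leaves the completed tables, and writes
a FAILED marker naming the stage.

## Test and verification scale

Stochastic verification suites run at reduced scale chosen to give
tight Monte-Carlo error at desk-scale runtimes: null calibration of the
permutation tests uses p = 6 predictors, 199 null permutations and 200
replicate datasets (for both the averaging engine and PERMANOVA); the
power check uses 2 active predictors in a pool of 6 with 50 replicates;
mixed-model slope recovery uses 100 replicates of the default 69-plot
design.  The acceptance script reports the full observed analysis on
the default synthetic design, with the averaging stage at a reduced
pool (p = 6, 199 nulls univariate; p = 4, 99 nulls multivariate).

## Known limitations

- The multivariate AICc composes independent per-species likelihoods;
  it ignores residual between-species correlation, as the underlying
  multivariate-GLM framework does.
- The permutation null for summed weights permutes whole samples; it
  calibrates against the predictor correlation structure but not
  against spatial autocorrelation, which the generator does not emulate.
- NMDS stress depends on restarts; with the default 20 restarts local
  minima are unlikely but not impossible for pathological inputs (the
  non-convergence flag is reported).
- The NB GLMM supports a single random intercept; random slopes, nested
  factors, zero inflation and quasi-likelihood families are out of
  scope.
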