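# Methods

## Problem and model

`vgscmap` models the frequencies of the three codon-995 alleles of the
voltage-gated sodium channel gene (*Vgsc*) — the wild type 995L and the
pyrethroid target-site resistance alleles 995F ("kdr-west") and 995S
("kdr-east") — in the African *Anopheles gambiae* complex, across space,
years and species. Observations are allele-count samples: at a location
and year, for one species (or the unresolved complex, *An. gambiae s.l.*),
`n` alleles are screened and counts `(y_L, y_F, y_S)` recorded. The
modelling target is the allele-frequency triple on the 3-simplex per
(pixel, year, species).

### Stacked generalization

Three base learners — gradient-boosted trees (xgboost), a random forest
and a single-hidden-layer neural network — each predict the per-sample
allele-frequency vector from environmental covariates (with annual lags
0–3), ITN coverage, a species factor and the collection year. Their
*K*-fold out-of-sample predictions (default K = 10) are combined by a
multinomial-logit meta-model ("generalizer"). With the out-of-sample
frequency predictions of learner q stored, after an empirical-logit
transform, in the N×J matrix X^q, the linear predictor for sample i and
class j is

    V_ij = β_j^1 X_ij^1 + β_j^2 X_ij^2 + β_j^3 X_ij^3,     β_j^q ≥ 0,

with class probabilities p_ij = exp(V_ij) / Σ_j' exp(V_ij'). All nine
(3 learners × 3 classes) slope coefficients are constrained nonnegative.
There are no intercepts inside V: with alternative-specific covariates no
reference-category constraint is needed, and any per-sample shift of the
V row is absorbed by the Poisson intercepts described next.

### Multinomial-Poisson fitting

The multinomial likelihood of the counts is re-expressed as independent
Poisson likelihoods with one free intercept φ_i per sample:

    L(y | B, φ) = Π_i Π_j (g_ij e^{φ_i})^{y_ij} exp(−g_ij e^{φ_i}),
    g_ij = exp(V_ij).

The φ maximiser is available in closed form, exp(φ_i) = n_i / G_i(B) with
G_i = Σ_j g_ij, and substituting it returns the multinomial
log-likelihood up to a constant free of B. The fit therefore maximises
the *profiled* Poisson log-likelihood over B alone by box-constrained
L-BFGS-B with an analytic gradient (the multinomial score
Σ_i (y_ij − n_i p_ij) X^q_ij). Positivity is enforced with bound
constraints — not an exp-reparameterisation — so exact zeros are
attainable; the starting point is β = 1/3 throughout, the objective and
gradient are scaled by the total allele count, and convergence requires a
projected-gradient infinity norm below 1e-7 (or the optimizer's own
success criterion) within 500 iterations. A fully Bayesian treatment
would cast B as fixed effects and φ as an iid random effect; the
profiled constrained maximum likelihood used here coincides with that
model's mode under flat priors and needs no extra machinery. Posterior uncertainty is
out of scope; a nonparametric bootstrap over samples
(`MultinomialStackingResults.bootstrap_se`) is the optional surrogate.

For final mapping, the base learners are refitted to all data and their
in-sample predictions replace X^1..X^3 in the fitted model. A binary
variant (J = 2: 995F vs not-995F) runs through the identical code path.

### Empirical logit

All frequency-to-covariate transforms use ln((p + ε)/(1 − p + ε)) with a
single shared ε (default 0.001, configurable); the transform is finite at
0 and 1, strictly increasing and antisymmetric about ½. The same ε must
be used at fit and prediction time and is stored in the serialized fit.

## Base learners

* **xgb** — `XGBClassifier`, histogram trees; defaults depth 3, learning
  rate 0.1, 60 rounds. Tuning grid: depth {3, 6} × rate {0.05, 0.1}.
* **rf** — `RandomForestClassifier`; defaults 60 trees, `sqrt` feature
  subsampling, leaf size 3. Tuning grid: 300 trees × features
  {sqrt, 1/3}.
* **nn** — single-hidden-layer `MLPRegressor` (default 16 units, lbfgs,
  ≤300 iterations) fitted to the per-sample frequency vector on
  standardized inputs, predictions clipped and renormalized to the
  simplex. The architecture is the package's own minimal choice; the
  backend accepts no observation weights, so the network weighs samples
  equally rather than by allele count.

Tree learners are count-weighted: every (sample, class) pair with a
positive count becomes one training row with weight equal to the count —
the same likelihood as row replication at a fraction of the memory.
Default sizes are desk-scale choices meant for the bundled synthetic
studies; tuning (`tune_learner`) scores a small grid on a held-out
validation subset (default 60/20/20 split) by multinomial
log-likelihood, never touching the test subset.

Degenerate folds (a single allele class present in training) fall back
to the training class distribution and are logged. A learner family
registry lets tests insert stub learners; the constant-frequency `mean`
family doubles as a floor baseline.

## Posterior validation

`cross_validate` nests two fold levels: outer folds (default 10) are
withheld from the base learners *and* the meta-model; stacking covariates
are regenerated by inner folds drawn only from each outer training set.
This is the only reading of "test sets withheld from learners and
meta-model" that is structurally leak-free, and a memorising stub learner
is used in the tests to demonstrate that held-out labels cannot reach any
model. Errors are scored between predicted and observed per-sample allele
frequencies, pooled over alleles and samples (MAE and RMSE); a flag
restricts pooling to the two resistance alleles if preferred.

The bundled benchmark (`stacking_benchmark`) repeats this on 20 fresh
synthetic studies of 500 samples with inner K = 5 — the benchmark's
desk-scale sizing — and records per-seed pooled RMSE for the ensemble and
each base learner. The ensemble is expected to be no worse than the best
base learner (+0.005 RMSE slack) in at least 90% of seeds.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Covariates** — zero-mean unit-variance Gaussian random fields over
  uniformly placed sites in a 10°×10° box, exponential covariance
  exp(−d/range) with a single range parameter (default 1°); annually
  varying covariates evolve as AR(1) across years (lag-1 correlation
  0.6), the rest are static. Defaults use 12 covariates; the count is a
  knob, standing in for the ~hundred-variable stacks used with real
  rasters.
* **ITN coverage** — a national trajectory (near zero through 2004, then
  a linear scale-up to 0.65 by 2017) plus a spatially correlated static
  deviation, clipped to [0, 1].
* **Latent frequencies** — per species, two logistic-scale linear
  predictors (995F-vs-995L and 995S-vs-995L) in the covariates and the
  mean ITN coverage over lags 0–3, mapped to the simplex by softmax.
  Default effect sizes encode the field-observed segregation: strong
  ITN-driven 995F selection in *An. gambiae* and *An. coluzzii*, weak in
  *An. arabiensis*; 995S mostly in *An. gambiae*. `gambiae_sl` surfaces
  mix the three species with weights (R_a, (1−R_a)/2, (1−R_a)/2), where
  the relative abundance R_a of *An. arabiensis* is a logistic-transformed
  static random field.
* **Allele sampling** — total alleles per sample are 10 + 2·NegBin
  (mean 40 by default): the diploid equivalent of the five-mosquito
  inclusion minimum, with a realistic tens-of-alleles depth. Counts are
  multinomial draws from the latent triple.
* **Bioassays** — complex-level 995F frequency f_C = R_a f_a +
  (1−R_a)(f_g+f_z)/2; true mean mortality is linear in the
  empirical-logit of f_C (defaults: intercept 1.37, slope −0.65, the
  strongest published country-level relationship, reused as generating
  truth), plus Gaussian noise of sd 0.25 on that scale — the measurement
  error estimated for deltamethrin susceptibility tests — then mapped
  back to (0, 1).

A single master seed spawns independent child streams for sites,
covariates, latent surfaces, allele sampling and bioassays, so each stage
is separately reproducible and identical configs give byte-identical
outputs.

What the generator does *not* emulate: real geography (no coastlines,
country masks or true covariate distributions), non-stationary spatial
covariance, reporting biases, species misidentification, or spatially
clustered sampling effort. Passing tests therefore demonstrate that the
machinery recovers structure of the assumed form, not that the real maps
are reproduced.

## Phenotype regression

Mortality and f_C are both empirical-logit transformed (shared ε) and
related by OLS. Coefficient covariance is Newey-West: Bartlett weights
w_l = 1 − l/(L+1) on the estimating-equation autocovariances, with the
plug-in truncation lag L = ⌊4(n/100)^{2/9}⌋ by default and the
Newey-West (1994) data-driven rule available (`bandwidth="nw1994"`);
L = 0 reduces exactly to the lag-free HC0 sandwich. Observations are
ordered by (year, then location) before the HAC step — time is the only
natural serial axis; point estimates are order-invariant, the covariance
is not. Confidence intervals use the normal critical value 1.96
(large-n practice), degrees of freedom are n − 2, and the one-row output
table mirrors the published per-country layout.

## Importance and ICE

Importance per learner uses each family's native measure: xgboost split
gain, random-forest Gini (mean decrease in impurity) and — for the neural
network — permutation importance computed in-house: the mean over seeded
repeats of the increase in all-data mean absolute frequency error when
one column is shuffled. One-hot species columns are collapsed back into a
single `species` feature so the three rankings share a feature set; ties
break by feature name.

The ICE evaluates the fitted ensemble's 995F prediction at one map
location and year while ITN coverage is swept over a grid (default 0–0.9
in steps of 0.1; the full 0–1 grid is a parameter away — the source
descriptions differ between the two ranges and both are supported). The
focal value is written into the coverage feature and all three of its lag
columns together. Every curve point and the baseline go through one-row
calls of the same prediction path, so the ICE at the observed coverage
equals the standard grid prediction exactly.

## Numerical choices and edge cases

* Softmax with per-row max subtraction; simplex rows renormalized and
  asserted to within 1e-9.
* Monthly-profile PCs (for variables on a monthly time step) use a full
  SVD with a fixed sign convention — the largest-magnitude loading of
  each axis is positive; rank-deficient profiles return the available
  axes and flag the deficiency. PCs are computed pooled over years so
  scores are comparable across years.
* Fold assignment is a seeded permutation split; sizes differ by at most
  one.
* Grids are exchanged as long-format CSV (pixel_id, longitude, latitude,
  year, variable, value); pixel-center WGS84 registration is assumed for
  real rasters rasterised upstream.
* Ingest drops rows per rule with counts (sample-size minimum,
  representativeness flag, count conservation, coordinate validity) and
  reports line numbers for malformed rows, so sample accounting on real
  data is reproducible.

## Known limitations

* No Bayesian posterior for the stacking coefficients (bootstrap only).
* No spatial random effects in the meta-model (none are part of the
  stacking formulation).
* Diploid genotypes are not modelled; counts are treated as independent
  allele draws.
* The neural-network learner ignores per-sample allele depth (see above).
* Real-raster acquisition, country masking and cartography are out of
  scope; the package consumes prepared per-pixel tables.
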