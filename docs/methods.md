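# Methods

## The model

`fledgechoice` implements Bayesian multinomial-logit **discrete choice**
models for used-vs-available habitat data organised in *choice sets*: one
location an animal used plus two paired random locations sampled at the
same time.  Each location j in a set receives a utility

    V_j = x_j' beta

where x_j stacks six vegetation covariates (litter depth, understory
foliage density, sapling / pole / saw timber stem densities, canopy
cover), distance to the nearest nonforest edge, and the six
vegetation-by-edge interactions — 13 terms in the default model.  The
probability the animal picks location j from its three options is the
conditional-logit softmax

    P(j) = exp(V_j) / sum_k exp(V_k).

Only within-set contrasts are identified, so the model has no intercept;
alternatives are unlabeled and exchangeable (the stored position of the
used location is randomized to keep position from leaking anywhere).

Two models share this likelihood:

* **Nest-site model.** All nest choice sets share a single coefficient
  vector with vague Normal(0, precision 0.01) priors (variance 100).
* **Stage-structured postfledging model.** Each individual bird, in each
  developmental stage (early dependent: first week out of the nest; late
  dependent: day 8 onward with parental care; independent: no parental
  care), carries its own coefficient vector drawn from stage-level normal
  population distributions, beta_{i,s,k} ~ N(mu_{s,k}, sigma_{s,k}).
  Hyperpriors: mu_{s,k} ~ N(0, precision 0.01); each precision
  tau_{s,k} = sigma_{s,k}^-2 ~ Gamma(1, 1e-4), the conventional diffuse
  inverse-gamma construction on the variance.  Stages can be pooled by
  mapping two stage labels to one model stage (used when a stage's data
  cannot support separate coefficients).

Day 8 itself is assigned to the late-dependent stage: the stage
definitions ("first week", "> 8 days") leave day 8 unstated, and a
contiguous partition avoids discarding data.

The Normal(0, 0.01) priors are read in precision parameterization
(variance 100).  An SD-0.1 reading would be strongly informative, which
contradicts their role as vague priors; precision is also the native
parameterization of the BUGS/JAGS ecosystem these models are usually fit
in.  Likewise Gamma(1, 1e-4) is placed on the precision (shape 1, rate
1e-4), equivalent to an inverse-gamma on the variance.

## Sampler

The paper trail for models of this family prescribes the distributions,
not the algorithm, so the sampler is the package's own design: an
adaptive random-walk **Metropolis-within-Gibbs**:

* componentwise random-walk updates of every coefficient vector
  (individuals are conditionally independent, so all blocks update in one
  pass per component);
* conjugate Gibbs draws for mu (normal) and tau (gamma);
* two **interweaved moves** per stage and component that fix the
  well-known funnel pathology of centered hierarchical samplers: a joint
  location shift of mu and all its individual coefficients, and a
  non-centered rescaling of sigma holding the standardized offsets
  (beta - mu)/sigma fixed — one with an adapted step and one with a wide
  fixed step (log-scale SD 1.5) to cross the flat ridge the posterior has
  when individual-level information is weak.

Proposal scales adapt toward a 0.44 acceptance rate in batches of 50
iterations during burn-in only (diminishing-adaptation gains), so the
retained chain is a valid fixed-kernel MCMC.  Default: 3 chains,
overdispersed N(0, 0.5^2) initializations, burn-in = half the iterations.
All likelihood evaluations use max-shifted log-sum-exp; raw utilities are
never exponentiated.  The inner loops are compiled with numba; the first
call in a fresh environment pays a one-time compilation cost.

Convergence is judged by the split-chain Gelman-Rubin statistic on every
monitored parameter (all individual coefficients and hyperparameters)
with the conventional threshold Rhat <= 1.1, inclusive.  Non-convergence
is a *reported state* (warning + flag), not an exception: the remedy is
longer chains, and the pipeline can automatically refit the juvenile
model with late-dependent and independent stages pooled when the full
stage structure fails to converge.  Weakly identified variance components
mix slowly — fits of the full hierarchical model at realistic sizes can
need tens of thousands of iterations, consistent with the 20k–250k
post-burn iterations such models are reported to need in the field
literature.

## Covariate scaling

The reader and generator work on raw field scales (cm, stems/ha, %, m).
Fitting standardizes all seven covariates by pooled z-score over every
location of the dataset (`standardize_covariates`); interactions are
formed from the standardized mains and edge, never re-centered
separately.  The scaling record maps results back to field scales.
Raw-scale fitting is supported (`scheme="none"`) but standardized fitting
is the default: it makes "one unit" comparable across covariates and is
numerically far better conditioned (stem densities span thousands).

## Synthetic data generator

The generator emulates the *statistical* structure the inference assumes,
not the field geometry:

* **Covariates.** Each covariate has a marginal distribution shaped to
  the field protocol's natural range (canopy cover Beta on 0–100% with
  mean ~80; understory board scores Beta(2,2) on 0–1; stem densities
  Gamma, means ~150–500 stems/ha; litter truncated normal 0–10 cm; edge
  distance Gamma shifted to 10–400 m).  These are presets chosen as
  plausible for mature-forest study areas, not estimates from any
  dataset.  The three locations of a set are coupled by a Gaussian
  copula with equicorrelation rho (default 0.5): locations 50 m apart
  share habitat, which the inference sees only as within-set covariate
  correlation, so no landscape is simulated.
* **Coefficients.** Individual vectors are drawn N(mu_s, sigma_s) per
  stage; defaults use sigma = 0.3 (moderate heterogeneity) and the
  species presets use sigma = 0.5.
* **Choices.** All covariates are generated first, standardized by the
  pooled mean/SD, and choices are then drawn from the same
  design-matrix + softmax code path the inference evaluates.  Ground
  truth recorded in `SimTruth` is therefore directly on the scale a
  z-scored fit estimates.
* **Species presets.** `flycatcher_preset` and `ovenbird_preset`
  reproduce the deposited study's shape: 170 / 53 nest sets, ~420 / ~500
  juvenile sets across ~39 / ~42 birds, with generating population means
  set to the study's headline estimates (e.g. nest canopy-cover selection
  ratio 2.19 -> beta = ln 2.19; ovenbird understory effect 0.25 early vs
  1.16 late; interaction -0.32 vs 0.41) and zeros where no estimate is
  highlighted.

What the generator does **not** emulate: spatial autocorrelation beyond
the within-set copula, temporal ordering of sets within a bird,
observer/measurement error, covariate dependence between sets of the same
bird, and unmodeled selection behaviour (non-logit errors).  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness of the model
to real-data violations of them.

## Posterior summaries

For each coefficient: posterior mean, central 95% credible interval
(2.5th/97.5th percentiles of pooled post-burn-in chains), and *f* — the
proportion of the posterior sharing the sign of the mean (draws exactly
at zero count as agreeing).  Selection ratios exp(beta) are reported for
main effects; when the covariate's edge interaction has f >= 0.90 the
ratio is still computed but flagged not interpretable on its own.
Ratio intervals are the exponentiated CRI endpoints (identical to
percentiles of exponentiated draws, by monotonicity); the ratio point
estimate is exp of the posterior-mean beta, not the mean of exponentiated
draws.

**Estrella's pseudo-R²** with null log-likelihood L0 = n ln(1/3):
R² = 1 − (L/L0)^(−(2/n)L0), 0 at the random-choice null and 1 at perfect
prediction.  The likelihood is evaluated at posterior means — the shared
vector for the nest model, each individual's own posterior-mean vector
for the hierarchical model.  Which point estimate enters this statistic
is a genuine choice; using the individual level matches the model whose
fit is being described, and the building blocks (`data_loglik`,
`estrella_r2`) are exposed for any other convention.

**Relative-probability-of-use curves** sweep one focal covariate over its
observed range with all other covariates at their dataset means and edge
distance fixed by scenario: the mean edge distance, or its 10th ("near")
/ 90th ("far") percentile when the focal-by-edge interaction is
supported.  Curves are anchored at the all-covariates-at-mean point
(r(x_bar) = 1, zero-width band there); anchoring changes only the
y-scale, never the shape, and the anchor is recorded on every output.

## Numerical and design choices

* One individual per brood (ovenbird-style sibling decorrelation) is
  enforced by a seeded uniform draw per brood; deterministic given seed.
* Choice sets with a row count other than 3 are excluded and counted;
  duplicate used rows are an error, not a silent fix.
* Softmax/likelihood: max-shifted log-sum-exp throughout; probabilities
  sum to 1 within 1e-12.
* Rhat: split-chain variant (each chain halved), the conservative and
  now-standard form; constant chains return Rhat = 1.
* f is computed against the sign of the pooled posterior mean.
* Standardization refuses zero-variance covariates by name.
* Edge distance enters untransformed (meters, or its z-score); no log
  transform is applied by default.
* All random processes take explicit integer seeds; dataset generation,
  fitting, and the pipeline are bit-reproducible given (config, seed).

## Problem sizes used in the shipped validation

The test suite and `scripts/acceptance.py` size their simulations to
desk scale as the package's own validation design: likelihood oracles on
<= 10 sets; MLE agreement on 300 sets; a dense-grid posterior check on a
20-set single-covariate model; hierarchical recovery at 2 stages x 40
individuals x 12 sets over 20 replicates (10 in the acceptance script);
and full study-shaped refits at the deposited study's sample sizes
(53–170 nest sets, ~420–510 juvenile sets).  Recovery fits use 2,500
iterations (half burn-in), which leaves some slowly mixing variance
components short of the Rhat threshold; the recovery metrics (coverage,
bias) are computed regardless and the convergence fraction is reported
alongside.

## Known limitations

* Choice sets are fixed at 3 alternatives by the field design.
* No correlated random coefficients: each of the 13 components has an
  independent hierarchy, matching the model family implemented.
* No model selection or multiple-comparison machinery.
* The sigma hyperparameters are weakly identified when individuals carry
  few choice sets; under the diffuse inverse-gamma prior the posterior
  then concentrates near small sigma.  At moderate heterogeneity
  (sigma ~ 0.3 standardized) population means remain well-calibrated —
  the recovery study checks exactly this — but when true heterogeneity is
  larger (sigma ~ 0.5) the partial collapse behaves like fitting a
  homogeneous logit to mixed-logit data: the largest population means are
  attenuated toward zero and their interval coverage of the generating
  values drops to roughly 0.85.  Designs with ~12 choice sets per bird
  cannot fully separate individual heterogeneity from noise; sigma point
  estimates and the largest effects should be read accordingly.
* GIS is out of scope: edge distance is consumed as a column, never
  derived from maps.
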