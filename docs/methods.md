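# Methods

## The outcome: composite index of anthropometric failure

A child contributes three standardized anthropometric z-scores: height-for-age
(HAZ), weight-for-age (WAZ) and weight-for-height (WHZ). Failure on any axis
is defined strictly below the conventional cutoff, z < −2; the value −2.0
exactly is not a failure. The joint failure pattern maps to the lettered
categories A (none), B (wasting only), C (wasting + underweight), D (all
three), E (stunting + underweight), F (stunting only) and Y (underweight
only). The classic seven-letter scheme is not an exhaustive partition: it
omits the biologically unusual wasted-and-stunted-but-not-underweight
combination. We assign that pattern an explicit label X, count it as a
failure (it is one), and report it separately, so every record maps to
exactly one category. The binary CIAF indicator is 1 for every category
except A. No biological-plausibility exclusion is applied by default; an
optional flag can drop records with any |z| > 6. Records with missing
z-scores are flagged, never silently dropped.

## The model hierarchy

All three models share a survey-weighted Bernoulli likelihood with logit
link; weights enter as likelihood multipliers (pseudo-likelihood), i.e.

  ℓ = Σᵢ wᵢ [ yᵢ ηᵢ − log(1 + exp ηᵢ) ].

This matches the common practice of passing normalized sampling weights
straight to the fitting routine; no design-based variance correction is
applied to the Bayesian fit. The linear predictor grows across the
hierarchy:

* **GLMM** — intercept, categorical fixed effects (reference-cell coding),
  optional linear continuous effects, and an exchangeable zone random effect
  u_h ~ N(0, σ²).
* **GAMM** — adds nonlinear effects f_l(x) of continuous covariates.
* **GGAMM** — adds the spatial pair f_str + f_unstr at zone level
  (structured + unstructured heterogeneity, the BYM-style decomposition).

Nonlinear terms are piecewise-constant over covariate bins. Integer-valued
covariates with at most 60 distinct values (child age in months) get one bin
per value; otherwise bins are equally spaced with a right-closed top bin.
Bin effects carry a second-order random-walk (RW2) prior with structure
matrix K = D₂ᵀD₂ (D₂ the second-difference operator), variance τ² per term:
rank m − 2, nullspace spanned by constant and linear sequences. Each smooth
is constrained to sum to zero; the *linear* nullspace direction is
deliberately kept inside the smooth (flat prior) so a fitted curve carries
its own trend and can be read as the whole covariate effect.

The structured spatial effect uses the intrinsic CAR prior over the zone
adjacency graph: precision structure Q = D − A, i.e. Q[d,d] = n_d (number
of neighbours) and Q[d,e] = −1 for adjacent zones. The implied full
conditional of one zone is Normal(mean of neighbours, π²_str/n_d). Zones
are adjacent when they share a boundary of positive length (rook adjacency;
a corner touch does not count). Q is rank-deficient with nullspace the
per-component constants, so the field is constrained to sum to zero within
every connected component; an isolated zone has an undefined conditional
and its structured effect is pinned at 0, leaving its heterogeneity to the
unstructured term. The unstructured effect is exchangeable N(0, π²_unstr)
with no sum constraint. Because an unstructured spatial effect and an
exchangeable zone effect are the same object at zone level, the default
configuration fits a single iid zone term; asking for both emits a
weak-identifiability warning and reports their variances jointly.

Fixed effects get flat priors. Every variance component gets an
inverse-Gamma IG(a, b) hyperprior, a = b = 0.001 by default (the
conventional weakly-informative choice). Intrinsic priors (RW2, ICAR) use
rank-aware normalisers — the product of the nonzero structure eigenvalues —
which is what makes the variances learnable.

### Internal parametrisation

Every penalised block is re-expressed in the eigenbasis of its structure
matrix with the constant directions removed. The coordinates then have
diagonal prior precision λⱼ/variance, sum-to-zero constraints hold by
construction (no re-centring steps anywhere), and the rank bookkeeping is
explicit: flat directions are exactly the zero-λ coordinates.

## Inference

### Routine engine: Laplace / empirical Bayes with grid mixing

For fixed variance components the conditional posterior of the latent field
is log-concave; its mode is found by damped Newton iteration (penalised
IRLS with backtracking line search) and Laplace-approximated by a Gaussian
at the mode. The log marginal posterior of the variances adds the
rank-aware prior normalisers, −½ log det H, the IG hyperpriors and the
log-scale Jacobian.

Variances are estimated on log-spaced grids by coordinate descent: one
coarse global sweep (11 points over [2·10⁻⁴, 5]) followed by two zoomed
sweeps (7 points over a ×4 window around the incumbent). Posterior
summaries of each variance come from a 21-point conditional grid
(×25 window) with normalised weights. Every conditional-grid evaluation
also contributes its (mode, covariance) to a Gaussian-mixture approximation
of the latent posterior, weighted by the marginal posterior — a lightweight
version of how deterministic nested-approximation schemes integrate over
hyperparameters. Latent summaries (fixed effects, curves, zone effects)
come from the mixture moments, so they carry hyperparameter uncertainty
rather than conditioning on a single variance estimate. Full nested-INLA
internals are deliberately not replicated.

Known accuracy limits, measured against the MCMC oracle: fixed-effect
posterior means agree to a few hundredths on a 200-child instance; posterior
SDs of coefficients entangled with weakly-identified variances (the
intercept on a 5-zone study) can still be underestimated by ~20% because the
mixture only integrates along one hyperparameter axis at a time. On the
2 000-child, 20-zone studies used throughout, 95% credible intervals cover
generating fixed effects at ~94%.

Degenerate designs do not crash: separation triggers a warning and a
`separation` flag; Newton non-convergence sets `converged = False`.
A tiny diagonal jitter (10⁻¹⁰) keeps the Hessian factorisable.

### Validation oracle: Gibbs + preconditioned MALA

The oracle targets the exact joint posterior. Variances are updated by
their conjugate full conditionals, IG(a + rank/2, b + quadform/2), with the
quadratic form read off the diagonal eigencoordinates. The whole latent
block is updated by Metropolis-adjusted Langevin steps preconditioned with
the inverse Hessian of the Laplace approximation at the starting variances;
the step size is adapted toward 57% acceptance during burn-in only, so the
post-burn-in chain is exact. With zero observations the latent block is
drawn exactly from its conditional prior, making prior-recovery checks
exact. Convergence is monitored by Geyer initial-positive-sequence ESS and
split-chain R̂ on the fixed effects and variances.

## Model comparison and validation

DIC, WAIC and CPO are computed from posterior draws of the linear predictor
(the approximate engine samples its Gaussian mixture; the oracle uses its
chain). pD uses the plug-in deviance at the posterior mean of the latent
field — the standard stable choice for latent Gaussian models. WAIC uses
the sample variance (ddof 1) of per-observation log-densities. CPO uses the
harmonic-mean identity with log-sum-exp stabilisation; observations whose
summands have coefficient of variation above 10 (or any infinite summand)
are flagged and re-estimated with the top 0.5% of summands trimmed. "Best
CPO" is operationalised as highest LPML (sum of log CPO). A model is
declared preferred when it is best on at least two of {DIC, WAIC, LPML};
AUC (in-sample, tie-corrected Mann–Whitney, with sensitivity/specificity at
a 0.5 threshold) is reported as supplementary evidence only. Per-observation
log-densities keep their survey weights, so all criteria compare the same
weighted pseudo-likelihood the models maximise.

The univariable screen fits one weighted logit per candidate and keeps it
when any non-reference level is significant at the 10% level. The Wald test
uses a pseudo-likelihood sandwich covariance: with mean-one random weights a
plain information-based test is anticonservative by the factor E[w²]/E[w],
which would break the 10% calibration the protocol assumes.

The hyperprior sensitivity protocol refits the model under a list of IG
settings — the four standard choices are IG(0.001, 0.001), IG(0.01, 0.01),
IG(0.5, 0.0005) and IG(1, 0.026) — and tabulates the spatial variance
posteriors and DIC per setting. A failed refit is recorded as a failed row;
the run continues.

Odds-ratio tables report exp(posterior mean of β) with exponentiated
interval endpoints (not the posterior mean of exp β); reference levels show
OR 1.00.

## The synthetic-data generator

The generator emulates a national cross-sectional household survey of
under-five children, which is what the model assumes:

* **Zones** — a rectangular lattice (default 4×5) with rook adjacency,
  standing in for administrative zones; a fixed number of sampling clusters
  per zone (default 5).
* **Spatial fields** — f_str drawn exactly from the intrinsic CAR prior in
  the eigenbasis of Q (zero-eigenvalue directions removed, so component
  sums are exactly zero); f_unstr iid normal. Ground-truth variances
  default to π²_str = 0.22 and π²_unstr = 0.055 — the posterior estimates a
  full-scale survey analysis of this kind reports — giving the
  structured-to-unstructured ratio of four the recovery checks assume.
* **Covariates** — sex (51/49), residence (75% rural), wealth quintiles
  (uniform), survey round (four rounds, uniform), age in integer months
  uniform on 0–59, maternal BMI uniform on 16–34 kg/m², and an aridity
  index uniform on 0–300 as a climate covariate. Joint covariate
  distributions of real surveys are not targeted; marginals are a documented
  modelling choice and the covariates are generated independently.
* **Effects** — default fixed effects on the logit scale encode a baseline
  CIAF prevalence near 45%, lower risk for girls, urban children, richer
  households and later survey rounds (e.g. richest vs poorest −0.70,
  latest vs first round −0.70). Two nonlinear truths: a saturating age
  effect 1.2·(1 − e^(−age/15)) (steep rise over the first two years, then
  flat) and a u-shaped maternal-BMI effect 0.010·(BMI − 25)², both centred.
  Amplitudes (≈1 on the logit scale end-to-end) are in the range such
  surveys report.
* **Weights** — Gamma with mean 1 and variance `weight_dispersion`
  (default 0.2), so the effective sample size stays interpretable.
* **Outcomes and z-scores** — y ~ Bernoulli(logit⁻¹ η). The trivariate
  z-scores use correlation (HAZ,WAZ) = (WAZ,WHZ) = 0.65, (HAZ,WHZ) = 0.15 —
  underweight correlates with both other failures, stunting and wasting
  only weakly. A common mean shift is calibrated by monotone interpolation
  of the Gaussian orthant probability so that P(any z < −2) equals each
  child's CIAF probability; draws are then rejection-sampled to agree with
  the child's simulated binary outcome. Classifier-outcome agreement is
  therefore exact while the z-score marginals stay calibrated (stragglers
  with vanishing conditional probability — none observed in practice at the
  default sizes — would be nudged across the boundary after 500 rounds).

Everything is driven by explicit seeds through `numpy` generators; the same
config and seed reproduce outputs bit for bit.

What passing on these data does *not* show: robustness to informative
weights, covariate dependence (e.g. wealth–residence correlation), cluster-
level (sub-zone) correlation, missing data, or real-survey measurement
error. The generator is a correctness instrument, not a survey emulator.

## Numerical choices

* Rank decisions use tolerance 10⁻⁸ relative to the largest eigenvalue.
* Likelihood evaluations are stable for |η| up to ~700 via `logaddexp`.
* Bin edges: right-closed top bin, so the maximum lands in the last bin.
* Gaussian-approximation quantiles are mean ± 1.96·sd; draw-based summaries
  use empirical percentiles.
* MCMC storage thins to at most 20 000 kept draws.

## Problem sizes used in the checks

The study sizes the test-suite and the acceptance script use are chosen as
the smallest at which the statistical claims are decisively measurable:
2 000 children / 20 zones for recovery and comparison replicates, 5 000 for
smooth-curve recovery and screening calibration, 200 children / 5 zones with
a 200 000-iteration oracle for engine validation, 10 000 children / 100
zones for structured-field recovery. The full-scale survey the model class
was designed for (tens of thousands of children, ~72 zones) is an order of
magnitude larger; nothing in the implementation is specific to the desk
scale.

## Known limitations

* The structured/unstructured split is weakly identified with few zones:
  the likelihood pins down each zone's *total* effect, but the split is
  informed only by smoothness across the graph. With 20 zones a
  tight-at-zero prior such as IG(0.5, 0.0005) can reattribute variance from
  the structured to the unstructured term on some realisations, while the
  total spatial variance stays stable. At the zone counts of real national
  surveys the split is much better behaved. The hyperprior sensitivity
  table makes this visible rather than hiding it.
* A single-zone spike is, to the likelihood, unstructured heterogeneity;
  planted-spike recovery experiments should fit the structured field alone
  (the generator then contains no exchangeable component) or read the total
  zone effect.
* AUC is in-sample, as labelled; no cross-validation is implemented.
* The linear-trend direction retained in each smooth has an improper flat
  prior; with extremely sparse bins this can slow Newton convergence.
* The screen tests each candidate marginally; it inherits the usual
  blindness to masked effects (a u-shaped covariate with no linear trend is
  invisible to it — visible in the worked example, where maternal BMI is
  screened out while its smooth is clearly recovered by the GGAMM).
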