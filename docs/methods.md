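# Methods

## Setting and estimands

The package decomposes a group disparity in a perinatal outcome into a
direct component and a component mediated by chemical exposures. The group
variable (self-identified race/ethnicity in the motivating setting) is
non-manipulable; "effects" are therefore disparity-decomposition
associations in the counterfactual notation, not biological causal claims.
For contrast x = 1 vs the reference x* = 0:

* TE = E[Y(1) − Y(0)]
* NDE = E[Y(1, M(0)) − Y(0, M(0))]
* NIE = E[Y(1, M(1)) − Y(1, M(0))]
* CDE(m) = E[Y(1, m) − Y(0, m)]
* PM = 100 × NIE / TE (log-OR ratio on the odds-ratio scale)

All regressions are complete-case: rows missing any used column are dropped
and the count is logged by the pipeline.

## Single mediator (closed forms, delta method)

With linear mediator and outcome models (optional exposure-mediator
interaction θ3), the identity-link effects are

    CDE(m) = θ1 + θ3 m
    NDE    = θ1 + θ3 (β0 + β2 c̄)
    NIE    = (θ2 + θ3) β1
    TE     = NDE + NIE

and for a rare binary outcome on the odds-ratio scale

    log CDE(m) = θ1 + θ3 m
    log NDE    = θ1 + θ3 (β0 + β2 c̄ + θ2 σ²) + ½ θ3² σ²
    log NIE    = (θ2 + θ3) β1

with σ² the mediator residual variance. TE = NDE + NIE holds exactly on the
difference scale and multiplicatively on the OR scale — these are algebraic
identities of the implementation, asserted to 1e-10 in tests. The
rare-outcome approximation is adopted for PTB (prevalence ≈ 6%, inside the
conventional <10% regime); exact-odds alternatives are out of scope.

Covariates are conditioned at their complete-case sample means c̄ by
default (`cvals` overrides); CDE percentile levels use the full-cohort
mediator distribution. PM is reported as NaN when TE is numerically zero.

Standard errors: numeric central-difference gradient (step 1e-6) of each
effect in the stacked (θ, β) vector, sandwiched with the block-diagonal
joint covariance of the two fits; σ² is treated as fixed. Numeric rather
than symbolic gradients keep one code path across link functions. The delta
CI was checked against a 1000-replicate percentile bootstrap (agreement
within 10% relative width) and achieves 92–98% coverage over 200 replicates
at the motivating study size n = 2008.

## Weighted quantile sum

Exposures are quantile-scored (type-7 cut points, ties to the lower
category; default q = 4), the cohort is split 40% training / 60% validation,
and weights are estimated on 500 bootstrap resamples of the training split,
constrained to w ≥ 0, Σw = 1 with the index coefficient sign-restricted
(negative = toward shorter gestation, the primary direction here). Final
weights are the plain average over iterates with a correctly-signed,
non-degenerate fit (iterates that collapse to a zero coefficient are
dropped and counted; an all-collapsed fit raises). The index is computed
for all subjects — mediation needs the full cohort — and the resulting
training/validation double use is the standard caveat of this design. The
validation-split regression of the outcome on index + covariates is
reported as the index effect.

Optimization: substituting b = β1·w turns each bootstrap fit into a convex
sign-constrained regression, solved to its global optimum with bounded
least squares (`scipy.optimize.lsq_linear`) for the identity link and a
bound-constrained quasi-Newton on the logistic likelihood for binary
outcomes. No random restarts are needed because the problem is convex; this
also makes each iterate deterministic given its resample.

The WQS index entering mediation is used on its raw quantile scale (range
0..q−1), not re-standardized. When the index itself is re-quantized as a
sensitivity analysis, quintiles (q = 5) are used.

## Quantile g-computation

A single joint fit on all quantile-scored exposures plus covariates; ψ is
the sum of exposure coefficients (the effect of a simultaneous one-quantile
increase), and weights are coefficients normalized within their sign
partition. The negatively-associated partition can be re-formed into a
weighted index mediator (`negative_index`).

## Multiple mediators (counterfactual imputation) and g-formula

Six mediator regressions share a design; their residuals get an empirical
covariance (multivariate-normal draws — the joint residual law is a modeling
choice the data cannot fully pin down and is documented as such). For each
subject and Monte-Carlo draw, mediator vectors under x and x* are sampled
and outcomes imputed from the outcome model at (x, M(x)), (x, M(x*)),
(x*, M(x*)); averaging gives TE/NDE/NIE, and fixing all mediators at a
component-wise percentile vector of the standardized mediators gives CDEs.
Because the imputed outcome depends on the residual draw only through its
projection onto θ2, that scalar projection is drawn directly — an exact
distributional identity that cuts the cost by the number of mediators.
With no interactions the estimator's expectation equals Σⱼ θ2ⱼ β1ⱼ, and
with zero residual variance the equality is exact (both are tested).

CIs are percentile bootstrap over cohort resamples with all models refit
per resample (default n_boot = 1000; the bootstrap can run with fewer MC
draws per resample since CI width is dominated by sampling, not MC, noise).
A resample that loses an entire group raises. When the mediator is a WQS
index the default bootstrap resamples the fixed index; refitting the WQS
weights inside the bootstrap is substantially more expensive and changes
CIs little in our checks — the distinction matters for strict inference on
the weights themselves.

Mediator-mediator and exposure-mediator interactions can be screened by
adding all pairwise products to the outcome model and retaining them only
when a joint Wald test rejects at 0.05; the default model omits them.

The g-formula variant first simulates the exposure-induced confounders
L | (X, C) (linear models, joint residual covariance), then M | (X, L, C),
then Y, producing randomized-interventional analogues of NDE/NIE; with L
empty it reduces to plain counterfactual imputation. For binary outcomes
the imputed event probabilities are compared as odds ratios or absolute
risk differences (`scale="RD"`).

## Exposure preprocessing

* Total lipids (mg/dL) = total cholesterol × 2.27 + triglycerides + 62.3.
* Lipid adjustment: ng/mL plasma ÷ (lipids mg/dL × 10⁻⁵ g/mL) = conc × 10⁵ /
  lipids, in ng/g lipid. The 10⁵ factor is the unit conversion made
  explicit (and tested) because published tables typically state only the
  input and output units.
* Molar sum: Σ over detectable (machine value > 0) congeners of
  lipid-adjusted concentration / molecular weight × 1000, in pmol/g lipid.
  Molecular weights ship as an overridable config table (PBDE 28: 406.90;
  47: 485.79; 99/100: 564.69; 153/154: 643.58 g/mol).
* Geometric means substitute non-positive machine values with half the
  lowest positive value; CIs are t-intervals on the log scale (a bootstrap
  would also be defensible; t-based is the deterministic choice).
* Model mediators are natural-log-transformed machine-observed values
  (below-LOQ values retained unsubstituted) standardized with the sample
  sd (ddof = 1). Descriptives use lipid-adjusted values; models treat
  plasma lipids as a covariate instead.
* Quantile scoring: without an LOQ, scores 0..q−1 from empirical cut
  points; with an LOQ, category 0 below it and q-tiles of the remainder
  above (the "<LOQ + quartiles" coding).

## Synthetic cohorts

Each scenario generates: a 4-level group with probabilities
(0.275, 0.251, 0.283, 0.191); one standard-normal confounder whose mean is
shifted +0.5 in the Black group — the minimal structure that separates
adjusted from crude estimates and so exercises covariate handling;
linear-Gaussian mediators; and a linear gestational-age outcome
(intercept 39.3 wk, residual sd 1.5, chosen so the total sd approximates a
typical cohort's 39.2 ± 1.7 after structural variance), a direct logistic
PTB outcome, or a thresholded one (PTB = GA < 37, configurable). All
randomness flows through one `numpy` generator seeded explicitly;
regeneration with the same seed is byte-identical.

Calibrated scenarios (true effects set to published point estimates for the
Black-White contrast): S1 — index mediator, TE −0.297965 wk, NIE −0.035165,
PM 11.80%; S1b — exposure-mediator interaction, CDE −0.23 at the mediator
median and −0.18 at its 25th percentile; S2 — logistic PTB with planted
OR 1.82 on a 5.1% reference risk (implying an 8.9% group risk); S3 — single
congener, PM 7.90%; S4 — six correlated mediators (exchangeable correlation
0.4, a stand-in since congener correlations are rarely published), joint
NIE −0.04868, PM 16.30%; S5 — six log-normal congeners driving the outcome
through a planted weighted quantile sum (dominant weight 0.60, slope
−0.20 wk per index unit, residual sd 1.0 so a cohort of a few thousand can
resolve the weights). `scenario_truth` returns these values exactly from
the coefficients — group effects on quantile scores (S5) via root-finding
on the mixture CDFs, threshold-outcome risk differences via exact Gaussian
convolution marginalized over the population confounder distribution — with
no simulation.

What the generator does **not** emulate: the full 11-covariate confounding
structure of a real cohort, missingness patterns, assay batch effects,
heavy-tailed or zero-inflated concentration distributions, or finer
subgroup structure. Passing recovery tests therefore demonstrates estimator
correctness under the assumed model, not robustness to real-data
violations of it.

## Problem sizes and numerical choices

Recovery tests use n = 200,000 (single-mediator scenarios), n = 100,000
with 2000 MC draws (six-mediator imputation), and n = 500,000 (logistic);
coverage suites use 200 replicates at the motivating study size n = 2008
with bootstrap n_boot = 200 and 50/25 MC draws per fit/resample — CI
endpoints at these sizes are dominated by sampling noise, not MC noise. The
S5 weight-recovery check averages 4 replicate fits at n = 5000 because a
single fit's dominant-weight sampling sd (~0.09) is comparable to the 0.10
recovery band. WQS fits declare an iterate degenerate when |β1| < 1e-10;
bounded least squares runs at tolerance 1e-10; delta gradients use step
1e-6; PM is undefined at |TE| < 1e-12. The pipeline derives stage seeds
from the config seed by a fixed affine map and logs them.

## Known limitations

* The OR-scale decomposition relies on the rare-outcome approximation.
* Natural-effect identification assumes no unmeasured mediator-outcome
  confounding and (absent the g-formula variant) no exposure-induced
  confounders; the group exposure is non-manipulable, so estimands are
  disparity decompositions.
* WQS weight estimates are biased toward the dominant congener on strongly
  correlated panels; the simplex constraint trades variance for this bias.
* Mediator measurement error is not modeled.
* Multiple-mediator draws assume multivariate-normal residuals.
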