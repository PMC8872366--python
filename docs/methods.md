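# Methods

`wqsmix` implements a sex-stratified weighted quantile sum (WQS) analysis
of a chemical-mixture exposure index against a continuous child outcome
(7-year full-scale IQ), together with g-computation counterfactuals and
exposure-reduction scenario calculus.  This note records the models, the
estimation choices, and what the synthetic cohort used for testing does and
does not establish.

## The outcome model

Each of c = 26 chemicals is scored into deciles q_ij ∈ {0, …, 9} from the
full-cohort empirical quantiles.  The index for subject i is

    WQS_i = Σ_j w[s(i), j] · q_ij,

where s(i) is the child's sex stratum and the 2c = 52 stratum-by-chemical
weights are nonnegative and sum to one across *both* blocks — a single
simplex, so the equi-weight guideline for a non-negligible weight is
1/(2c) = 1/52 ≈ 0.019.  The outcome model is the stratified interaction
parameterization

    y = β0 + β1·WQS + β2·x + β12·x·WQS + φ'z + ε,

with x the female indicator and z the covariates (maternal nutrition index
MNI, energy intake, age, pre-pregnancy weight, education, Raven IQ,
smoking).  β1 is the boys' slope; the girls' slope is always reported as
β1 + β12, never as a free parameter.

A consequence of the single-simplex design worth knowing: the *magnitude*
of β1 alone is scale-ambiguous, because the optimizer may allocate very
little total weight to one stratum block, making that stratum's index
small-ranged and its slope correspondingly steep.  Interpretable quantities
are the slope times the index spread, or the holdout-stage estimates where
the weights are frozen.

## Two-step estimation with repeated holdout

Step (i), weight estimation, minimizes the residual sum of squares of the
full interaction model jointly over coefficients and weights, with weights
softmax-parameterized on the simplex and β1 sign-constrained to a chosen
direction (negative for an adverse index).  Coefficients are profiled out
by least squares at every weight evaluation; when the unconstrained β1
violates the sign constraint the fit is moved to the boundary (β1 pinned at
0, remaining coefficients refit), which is the exact solution of the
single-inequality-constrained least-squares problem.  The profiled
objective is minimized by L-BFGS-B with an analytic envelope gradient
(only the explicit dependence of the design on the weights contributes,
since the profiled coefficients are stationary).  The first start is the
equi-weighted index (softmax parameters all zero); additional restarts
(default 3 total) perturb randomly.  Convergence is L-BFGS-B's own
criterion with a 300-iteration cap; unconverged fits are excluded from
ensembles and counted.

Step (i) is run on bootstrap resamples of the training subjects (default
100 per split) and the weight vectors averaged — plain arithmetic mean and
renormalization by default; a variant weighting each fit by the magnitude
of its index-slope t statistic is available.  Step (ii) freezes the
averaged weights, computes the index on the holdout subjects, and fits the
interaction model by ordinary least squares.

The whole two-step procedure is repeated on independent random 40/60
train/holdout splits (default 100 repeats).  Decile breakpoints are
computed once on the full sample and frozen across splits, so all repeats
and all downstream counterfactuals share a single quantile designation.
Reported "standard errors" are SDs of estimates across repeats, and
interval summaries are 2.5/97.5 percentiles of the repeat distribution;
this is a generalizability summary, not a strict confidence procedure, so
simulation coverage of the percentile interval is expected in a broad
90–99% band rather than at exactly 95%.

Per-repeat and per-bootstrap seeds derive deterministically from the master
seed (`SeedSequence([seed, repeat, bootstrap])`), so any single repeat can
be reproduced in isolation and the full run is bit-reproducible.

## g-computation

The marginal contrast between two settings of an exposure metric (the
centered-and-scaled WQS index, or MNI) is estimated by the parametric
g-formula specialized to a linear model: fit y on metric, sex, metric×sex
and covariates; set every subject's metric to each counterfactual level;
predict; average within boys, girls and overall; difference.  Percentile
95% intervals come from a subject-level nonparametric bootstrap (default
200 replicates) repeating the whole fit–predict–average cycle.  Without an
interaction term the contrast reduces analytically to coefficient × shift,
which is asserted in tests to machine precision.

The causal reading requires consistency, conditional exchangeability given
the modeled covariates, and positivity; these are assumptions about the
data, not checkable by the code.  As a guardrail, a counterfactual level
more than one SD outside the observed metric range raises a positivity
warning.  When the metric is a WQS index its weights are frozen inputs —
they are never re-estimated inside the counterfactual loop.

## Scenario calculus

Because the index is additive, each subject's index decomposes exactly into
chemical-class contributions (phenols, plasticizers, other short-lived,
PFAS, persistent chlorinated; the last two form the "persistent" group).  A
reduction scenario multiplies each class contribution by a retention factor
in [0, 1] under fixed weights and frozen quantile designations; re-deriving
decile scores from reduced concentrations would change the population
quantiles and is deliberately out of scope.  Scenarios are judged by the
fraction of subjects whose adjusted index falls strictly below the target,
defined as one sample SD below the observed index mean.  The named battery
comprises a 70% cut to all non-persistent classes, elimination of the
plasticizers, of plasticizers plus other short-lived compounds, and of
plasticizers plus phenols.  Histograms use fixed-width bins spanning the
pooled original and adjusted range (default 30 bins) so panels are
comparable.

## The synthetic cohort

Real cohort data of this kind are restricted, so the generator emulates the
published summary statistics and is itself first-class, tested code.

* **Exposures.** 26 chemicals, partitioned 4/9/3/6/4 into the five classes.
  Dependence is a Gaussian copula with block-exchangeable correlation —
  default 0.4 within a class, 0.1 between classes — and lognormal
  marginals.  These correlation defaults are stated choices, not estimates:
  no correlation or detection-limit values are published for the target
  cohort.  Urinary analytes are stored unadjusted (analysis-scale value ×
  lognormal creatinine with mean 10.4, SD 4.7 mmol/L) so the creatinine
  adjustment step operates on realistic inputs.  Values below a chemical's
  detection limit — the (1 − detect_rate) quantile of its marginal — are
  flagged and substituted by LOD/√2 (a conventional constant substitution;
  configurable).
* **Covariates.** Independent normals/Bernoullis at the published
  marginals: MNI 66.8 ± 14.0, energy 1895 ± 545 kcal, maternal age
  31.3 ± 4.6 y, weight 68.8 ± 13.5 kg, Raven IQ 114.8 ± 14.9, college
  education 69%, smoking 11%, female children 51%.  MNI is drawn directly
  as a score; constructing it from food-frequency data is out of scope.  An
  optional confounding switch tilts MNI (and can be extended to smoking)
  along a latent factor shared with exposures for stress-testing covariate
  adjustment; by default covariates are independent of exposures.
* **Outcome.** Generated from the stratified interaction model with the
  published holdout-ensemble coefficients as default truth (β0 = 88.7,
  β1 = −2.13, β2 = −0.622, β12 = 1.98, φ per the published table) and
  residual SD σ = 10 IQ points.  True weights are sparse and uniform
  within the active set: 8 boys' chemicals and 6 girls' chemicals, each
  with weight 1/14, mirroring the sex-specific chemicals-of-concern
  pattern.  With these defaults the generated index averages ≈ 2.2 with SD
  ≈ 0.7 and mean IQ ≈ 100 — the right scale, though the index SD is not
  calibrated to the published 0.50.

What the generator does **not** emulate: the real cohort's empirical
correlation pattern (only a two-level exchangeable structure), exposure–
covariate dependence (off by default), measurement error in analytes,
non-normal covariate shapes, or cohort-specific quantities such as the
~26% persistent share of the index.  Tests passing on this cohort
demonstrate the *procedures* are correct and calibrated under a known
truth; they do not reproduce cohort-specific published estimates.

## Numerical choices

* Decile scoring averages tied ranks before binning; heavy ties collapse
  duplicate breakpoints with a warning while scores stay within
  {0, …, K−1}.  Scores run 0–9 so a bottom-decile exposure contributes
  nothing to the index.
* Breakpoints are retained and re-scoring of new data uses right-closed
  bins (`searchsorted(..., side="left")`), consistent with the original
  binning for continuous data.
* "Below target" uses strict inequality.
* Split sizes use floor(fraction · n) for training — 271/407 at n = 678 —
  and a split leaving either sex absent from either part is resampled with
  a derived seed, at most 10 times.
* The SE attached to a single bootstrap fit's slope (used only for
  signal-weighted averaging) treats the fitted weights as fixed and falls
  back to a pseudoinverse when a stratum block holds all the weight.

## Problem sizes used by the test suite

The heavy simulation checks run at deliberately chosen sizes: parameter
recovery uses 50 cohorts × 20 repeats × 50 bootstraps with single-start
optimization (the repeat-and-bootstrap ensemble already averages over
starts), and bootstrap-CI coverage uses 200 cohorts with 200 bootstrap
replicates each.  The package defaults remain 100 repeats × 100 bootstraps
with 3 restarts.

## Known limitations

* With the default truth, the girls' slope β1 + β12 = −0.15 is nearly
  zero, so the girls' weight block carries almost no outcome signal at
  σ = 10 and n = 678: girls' active weights are only weakly separated from
  the 1/52 guideline in recovery simulations.  This is a property of the
  generating conditions (near-null stratum effects leave simplex weights
  weakly identified), not of the estimator alone.
* At realistic signal-to-noise the bootstrap ensemble shrinks mean weights
  strongly toward the equi-weight value; individual bootstrap fits are
  near-corner solutions and their average is informative mainly in rank
  order.
* The sign constraint applies to β1 only; whether the stratum-sum slope
  should also be constrained is left open, and the default leaves it free.
* Percentile-of-repeats intervals are not confidence intervals (see above).
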