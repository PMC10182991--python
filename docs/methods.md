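# Methods

## The models

`flyddm` fits two generative accounts of two-choice reaction-time behavior
in walking flies discriminating odor concentrations.

**Temporal integration (drift-diffusion).** The decision variable is a
Wiener process with unit diffusion coefficient, drift `v = k*x` set by the
task difficulty `x` (log10 odor concentration ratio, in [-1, +1] for the
standard 1/4/5/7/9-vs-10-ppm design), starting point 0, and absorbing
bounds at `+A` (correct) and `-A` (incorrect). This gives closed forms for
the psychometric function `P(correct) = 1/(1 + exp(-2Akx))` and the
chronometric function `T(x) = (A/kx) tanh(Akx) + T0` (limit `A^2 + T0` at
x = 0), plus the first-passage-time density at either bound. The density
is evaluated by the standard dual series representation for the Wiener
first-passage problem (small-time image-charge sum below a scaled time of
`t/(2A)^2 = 0.1`, large-time sine series above it), truncated so the
absolute series error is at most 1e-29, with even-index terms skipped
because the midpoint start makes them vanish. Note: the published form of
this density circulates with inconsistent sign conventions; the package
derives its form from the unit-diffusion convention of the psychometric
and chronometric equations and pins it down by two independent checks —
analytic (the density's marginals must reproduce those closed forms, to
1e-6/1e-3; enforced in the test suite on an 80-point parameter grid) and
stochastic (agreement with an Euler-Maruyama simulator at 1e5 paths).

**Extrema detection.** An independent Gaussian evidence sample
`N(k*x*dt, dt)` is drawn every sampling interval `dt` and the trial ends
when one sample exceeds `+A` or falls below `-A`. The per-interval
crossing probabilities are `p_+/- = 0.5*erfc((A -/+ kx*dt)/sqrt(2dt))`, the
interval count is geometric with success `p_+ + p_-`, the mean decision
time is `tau_R = dt/(p_+ + p_-)`, and for small `dt` the reaction-time
density is the ex-Gaussian (exponential of mean `tau_R` convolved with the
non-decision Gaussian), weighted per choice by `p_sign/(p_+ + p_-)`. All
crossing probabilities are computed in log space (`log_ndtr`) because
`erfc` underflows beyond arguments of ~27, which realistic bound heights
reach; a configuration whose total crossing probability underflows to zero
in linear space raises an error advising a larger `dt` or a smaller `A`.

**Non-decision time.** Both families add a Gaussian non-decision (sensory
plus motor) latency with mean `T0` and SD `sigma0`, truncated at zero
because latencies are physically positive. In the drift-diffusion
likelihood the convolution with the truncated Gaussian is evaluated by
16-node Gauss-Hermite quadrature, renormalized over the retained nodes so
that the discrete kernel is exactly a probability kernel — the reaction-
time density then integrates to 1 for *every* parameter value, not just
asymptotically, which matters because model comparison is sensitive to
even percent-level normalization bias. The ex-Gaussian of the extrema
model is evaluated as printed (untruncated support), with all factors in
log space. Densities are floored at 1e-300 before logarithms.

## Units

Reaction times are walking-speed-normalized and therefore dimensionless;
one normalized unit is on the order of one second of wall time, which is
how the default sampling interval `dt = 5e-4` maps onto the 0.5 ms used in
the original acquisition. `dt` is exposed in `ModelSpec` because this
mapping is a convention, not a measurement.

## Bayesian estimation

`DecisionModel.fit()` samples the posterior under flat priors (all
parameters positive; `T0`, `sigma0` restricted to (0, 3]) with
coordinate-wise univariate slice sampling (step-out and shrinkage),
retaining 500 draws per fitted parameter after 300 burn-in sweeps.
Initial points come from method-of-moments inversion of the psychometric
and chronometric closed forms at the easiest and hardest difficulties
(both families have closed-form inversions). Step widths start at 10% of
the prior range for bounded coordinates and 1.0 otherwise, and are
re-tuned to 3x the recent draw SD every 50 burn-in sweeps, then frozen, so
the retained chain is a correct slice sampler. Every stochastic operation
takes an explicit seed; chains are bit-reproducible.

The best estimate is the draw maximizing a kernel-smoothed *joint*
density over the draws (Gaussian product kernel, Silverman bandwidth per
dimension, evaluated on the draws themselves to stay dimension-robust);
above four dimensions the highest-likelihood draw is used instead. The
maximized log-likelihood entering the BIC is refined by a deterministic
Nelder-Mead ascent from the best retained draw, because a finite chain
systematically under-shoots the maximum — and does so by different amounts
for the two families, which would otherwise leak into the Bayes factors.

Multi-condition ("global") models share `T0` and `sigma0` across
photostimulation conditions and let the bound height `A` and/or the drift
scaling `k` vary per condition; the global likelihood is the product of
per-condition likelihoods. The number of fitted parameters `q` counts
only free parameters (fixed non-decision values estimated beforehand from
the unstimulated condition are excluded), `n` is the total number of
decisions, and `BIC = q ln(n) - 2 Lhat`. Bayes factors are
`exp(-dBIC/2)`; a factor above 100 (below 0.01) is decisive on Jeffreys'
scale, and the intermediate grades at factors of 10^0.5 are reported for
context only.

## Reaction-time extraction from trajectories

Position series (30 frames/s, 50 mm chamber) are smoothed with a 10-frame
centered moving average (truncated windows at the edges, so length is
preserved and constant input is unchanged). Videos with fewer than two
end-to-center runs — decision-zone entries preceded by a visit to a 7 mm
end region — are discarded, as are videos flagged for grooming by the
caller. A traverse of the 7 mm central decision zone counts as a decision
iff the minimum 5-frame average speed inside the zone is at most 10% of
the 5-frame average speed just before entry, and the dwell is at most
15 s; the dwell is the raw reaction time, the exit side against the arm
holding the lower odor concentration gives the choice sign. Raw times are
divided by the fly's mean transit time across the two 7 mm off-center
zones flanking the decision zone, making the result dimensionless and, by
construction, invariant under a uniform rescaling of walking speed (this
invariance is property-tested). The 5-frame speed window is a package
choice (~167 ms, balancing noise against locality); the normalization
arithmetic (division by the per-trajectory mean transit) is likewise a
package choice among the operationalizations consistent with the stated
measurement.

## Synthetic data

The generator emulates the statistical structure of the behavioral assay
at the trial level; it does not model odor plumes, photon physics, or any
within-fly correlation (every trial is independent given its condition,
and simulated fly IDs are cosmetic). Defaults define the study conditions
used throughout the tests:

- difficulties: `x = +/- log10(10/c)` for `c` in {1, 4, 5, 7, 9} (ten
  levels);
- drift-diffusion truth: `A = 1.0, k = 2.0, T0 = 0.5, sigma0 = 0.1`,
  giving ~98% accuracy at the easiest contrast and a ~1.5-fold
  chronometric dynamic range — in the regime of the published
  chronometric/psychometric curves;
- photostimulation implemented as bound lowering: `A = 1.0 / 0.9 / 0.75`
  at optical powers 0 / 0.01 / 0.20 mW/mm^2, with `k`, `T0`, `sigma0`
  light-insensitive;
- extrema-detection truth: `A = 0.08, k = 20, T0 = 0.5, sigma0 = 0.1` at
  `dt = 5e-4`, chosen so that mean decision times (~0.55-1.44) and
  accuracies (0.5-0.97) span the same range as the drift-diffusion
  conditions. Extrema-model bound heights are numerically much smaller
  than drift-diffusion ones because a *single* interval's evidence SD is
  `sqrt(dt)`.

The drift-diffusion simulator integrates Euler-Maruyama paths at step
1e-4 with a per-step boundary check plus a Brownian-bridge crossing
probability `exp(-2(A-a)(A-b)/step)` for each bound and step (evaluated
only within ~0.035 evidence units of a bound, where it is non-negligible).
The bridge term removes the O(sqrt(step)) missed-crossing bias of the bare
endpoint check; with it, accuracy and mean reaction time agree with the
closed forms to within Monte-Carlo error at 4e5 paths. The
extrema-detection simulator draws the interval count directly from the
geometric law and the choice from the crossing-probability weights, which
is distribution-identical to sampling every interval (the samples are
independent) and feasible when `p_+ + p_-` is ~1e-4. Non-decision times
are drawn by rejection from the zero-truncated Gaussian.

What passing tests show — and what they do not: the pipeline recovers the
parameters and the generating mechanism of data that satisfy the model
assumptions (independent trials, stationary parameters, Gaussian
non-decision time). Real behavioral data violate these in known ways
(between-fly variability, slow drifts, censored dwells), so test results
bound implementation error, not model adequacy.

## Problem sizes used by the verification suite

Chosen to keep the full suite and the acceptance script each inside tens
of minutes on one CPU while retaining statistical power:

- density-vs-closed-form consistency: 80 (A, k, x) triples, adaptive
  quadrature, tolerances 1e-6 (mass, choice probability) and 1e-3
  (conditional mean);
- simulator checks: 1e5 paths/trials per parameter set, 3-SE bands;
  chi-square goodness of fit for the geometric interval count at
  alpha = 0.01;
- parameter recovery: 8 replicate datasets of 8 difficulties x 250 trials
  (2000 decisions each), non-decision parameters fixed, full 500/param +
  300 burn-in budget; per-dataset error bound 10%, mean bias bound 5%;
- strategy selection: 2000 decisions per dataset (ten difficulties x
  200), four free parameters per family, full sampling budget. At this
  size the expected BIC gap between the generating and the alternative
  family is close to the decisive threshold (2 ln 100 ~ 9.2) — family
  identification at a few thousand independent trials is intrinsically
  marginal because a 4-parameter drift-diffusion model imitates an
  ex-Gaussian reaction-time distribution (and vice versa) to within a few
  thousandths of a nat per trial;
- mechanism selection: 600 decisions per light condition, non-decision
  parameters fixed from a 4-parameter fit of the unstimulated condition,
  200/param + 150 burn-in for the comparison fits (BIC gaps between
  mechanism variants are tens to hundreds of units here, far above chain
  noise).

## Known limitations

- No hierarchical (per-fly) structure; all trials in a condition pool.
- The extrema-detection likelihood uses the continuous ex-Gaussian
  approximation of the geometric decision-time law; exact at the 1e-7
  level for the default `dt` but not lattice-exact.
- Collapsing bounds, starting-point bias, and drift-rate variability are
  deliberately out of scope.
- The Gauss-Hermite kernel approximates the truncated non-decision
  Gaussian coarsely when `T0 < ~2 sigma0`; it remains a proper density
  (unit mass) there, so comparisons stay fair, but pointwise accuracy
  degrades in that corner of parameter space.
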