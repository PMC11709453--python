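# Methods

`snarcflex` implements a complete analysis chain for parity-judgement
SNARC experiments in which the same numbers (4 and 5) appear in a lower
and a higher number range: synthetic trial generation, the preregistered
exclusion pipeline, per-participant dRT slope regression, default Bayes
factors, and the design analyses behind the sequential sampling plan.
This note records the models, the defaults, and the choices made where
the design was genuinely open.

## The measurement model

For each participant, range and number magnitude *m*, the dRT is the mean
right-hand RT minus the mean left-hand RT.  The SNARC effect is the slope
of the per-participant ordinary least-squares regression of dRT on *m*
(the Lorch–Myers repeated-measures approach): more negative means
stronger.  Derived per fit are the predicted dRT at the range's smallest
magnitude ("smallest-number intercept"), at its mean magnitude
("mean-number intercept"), and the raw cell dRTs of the critical numbers
4 and 5.  In the orthogonal stimulus sets (ranges 1–5 without 3 and 4–8
without 6) a ±0.5 parity contrast (−0.5 odd, +0.5 even) can enter as a
second regressor; its coefficient is the MARC effect.  Because parity and
magnitude are exactly orthogonal there, adding the contrast never changes
the slope.  The critical-number dRTs are deliberately the raw cell means,
not fitted values: the corresponding paired hypothesis concerns observed
dRTs for the same number, and the joint fit is reserved for the MARC
coefficient.  In the classic ranges (0–5, 4–9) parity and magnitude are
mildly correlated (r ≈ −0.293), so the MARC regressor is not fitted
there by default.

## The synthetic cohort generator

The generator exists so every downstream stage is testable without the
deposited datasets; its defaults are the study conditions the analysis
assumes, not tuning knobs.

Each participant carries latent parameters per range — intercept α (dRT
extrapolated to magnitude 0), slope β, and a MARC coefficient γ — drawn
from normal distributions; the pair (β_lower, β_higher) is bivariate
normal with correlation ρ, built from two independent standard normals so
that the degenerate cases σ = 0 and |ρ| = 1 are exact.  A trial with
number *m* answered on side *s* ∈ {−1 left, +1 right} has

    RT = exGaussian(μ, σ, τ) + (s/2) · (α + β·m + γ·parity(m)),

so the expected dRT at *m* is exactly α + β·m + γ·parity(m), and side
means stay centred on the base RT (only the right-minus-left difference
is identified by the analysis).  The ex-Gaussian base — normal(μ, σ) plus
exponential(τ) — is the standard right-skewed RT model; real datasets of
this design report only means and SDs, so the defaults
(σ = 45 ms, τ = 95 ms, with μ = 448/418 ms per experiment) are chosen to
put the grand mean near the observed 543/513 ms with a plausible skew.
Contaminants: errors flip the response side with probability 0.055 (the
RT is kept, to be removed later by the error filter); anticipations
replace the RT with uniform(50, 200) ms at rate 0.002 and lapses with
uniform(1500, 5000) ms at rate 0.02; missing responses default to
probability 0.  Reference cohorts per experiment anchor slope
means/SDs, intercept means and ρ to the group estimates such data
produce (e.g. slopes (−10.17, −5.92) ms with SD ≈ 14.3 and ρ = 0.34 for
the orthogonal-stimulus experiment).  Intercept SDs (34 ms) and the MARC
SD (80 ms) are not reported quantities; they are set once to values that
make the corresponding between-range and MARC tests roughly as decisive
as observed at comparable n.

What the generator does **not** emulate: practice effects, fatigue,
block-order effects, handedness or finger-counting covariates,
participant-varying ex-Gaussian shape, and RT autocorrelation.  Passing
recovery tests therefore show that the estimator chain is correct under
the assumed generative model, not that real data satisfy that model.

Design layout: four blocks (range × key assignment), four counterbalanced
block orders, two practice presentations per number per block, 25
experimental repetitions per number per key assignment (600/400
experimental trials per participant), fully randomized within block.  All
randomness derives from one `SeedSequence`, so identical (parameters,
seed) give byte-identical trial tables.

## The exclusion pipeline

Stages run in a fixed order with an audit tally per stage; fractions use
*sequential* denominators (each stage's entry count), matching how such
pipelines are conventionally reported.  Participant screening (age 18–40,
seriousness, quiet-enough environment, no multiple major distractions,
index-finger compliance, optional completeness/key-compliance flags)
assigns each excluded participant the *first* matching reason in that
order — never double-counted.  Unknown/missing self-report values do not
exclude.  Then trials: practice, missing, incorrect, RT < 200 ms
(anticipations), RT > 1500 ms (lapses) — bounds inclusive, i.e. exactly
200/1500 ms is kept.  Then per participant, iterative trimming: remove
trials strictly more than 3 sample SDs (ddof = 1) from the mean of the
remaining trials, recompute, repeat until a pass removes nothing; values
exactly at mean ± 3 SD are retained.  Finally, participants need at least
75% of their *designed* experimental trials remaining (missing responses
count against validity) and no empty number × response-side cell in
either range (an empty cell would leave a dRT undefined).

A consequence worth knowing: fixed-threshold trimming on right-skewed
RTs removes more right-tail mass from cells whose structural offset is
larger, which attenuates group slopes by roughly 0.5–1 ms at slopes near
−10 ms under the default noise level.  The recovery tests therefore
compare group estimates to generating values within Monte-Carlo bounds
(3 empirical standard errors) rather than demanding sub-millisecond
agreement; in the noiseless configuration the round trip is exact to
machine precision.

## Bayes factors

The one-sample/paired Bayes factor is the JZS default: a zero-centred
Cauchy prior with scale r = 0.707 on the standardized effect δ against
the point null δ = 0, two-sided.  It is computed from the observed t via
the scaled inverse-chi-square mixture representation of the Cauchy — a
one-dimensional integral over the prior variance g, evaluated by adaptive
quadrature (relative tolerance 1e-10, after mapping g ∈ (0, ∞) to the
unit interval; the integrand is evaluated as a likelihood *ratio* in log
space so that large |t| cannot underflow).  Quadrature failure raises
with diagnostics rather than returning a number.  The test suite
cross-checks this against two independent routes: a Monte-Carlo
integration over the Cauchy prior using the exact sampling representation
of the t statistic, and `pingouin.bayesfactor_ttest` (agreement to
~1e-6 relative; pingouin is used only as an oracle).

The correlation Bayes factor integrates the exact sampling density of
the Pearson correlation (its Gauss-hypergeometric kernel; ρ-free
normalization cancels in the ratio) over a symmetric stretched-beta
prior of width κ on ρ.  κ = 1 — a uniform prior on (−1, 1) — is the
conventional default and is used because no narrower prior is implied by
the analysis; the κ used is recorded in the result object (`rscale`
field).  At r = 0.34, n = 255 this gives BF10 ≈ 3.9 × 10⁵, consistent
at 2-dp rounding of r with the ~5 × 10⁵ such data produce.

Evidence labels use the conventional thresholds (3, 10, and their
reciprocals).  Boundary convention: exactly 3 or 1/3 is "inconclusive"
(the thresholds are strict), exactly 10 or 1/10 counts as strong.

Degenerate inputs are errors, not numbers: zero-variance samples,
|r| = 1, n < 2.

## Design analyses

**Frequentist sensitivity.**  Two-sided one-sample/paired t-test power is
computed in closed form from the noncentral t distribution (scipy's far
tails can underflow to NaN at extreme noncentrality; such terms are
zeroed as they are genuinely negligible).  The minimum detectable
difference solves power(δ) = target by bracketed root-finding (Brent,
xtol 1e-10·sd); with n = 24 and a difference SD of 18.34 ms this gives
11.0 / 12.7 / 14.1 ms at powers 0.80 / 0.90 / 0.95 (d = 0.60 / 0.69 /
0.77).  A vectorized Monte-Carlo power routine (default 10⁴ replications)
is kept alongside and is tested to agree with the closed form within
Monte-Carlo error.

**Bayes-factor design analysis.**  Each replication draws n standardized
values from Normal(d, 1), computes the JZS BF, and tallies crossings of
3 and 1/3.  Replications default to 5000; the analysis is deterministic
given its seed.  With d = 0.15 the probability of BF10 > 3 at n = 800 is
≈ 0.90, and under d = 0 the probability of BF10 < 1/3 at n = 180 is
≈ 0.91 — the numbers behind the sampling plan.  `required_n` bisects a
user grid (default step 20, mirroring batch recruitment) assuming the
evidence probability is monotone in n; every grid point gets its own
child seed so the answer does not depend on the search path.  Because
these probabilities are Monte-Carlo estimates, tests of "at least 0.90"
claims allow a one-sided 3σ binomial margin at the replication count
used.

**SBF+maxN.**  `run_sbf_maxn` consumes a stream of analysable
participant records, evaluates the hypothesis battery at n = 200 and
after every further 20, and stops when *every* BF lies outside
(1/3, 3) — per-hypothesis early freezing is deliberately not applied —
or at n = 800.  The battery is an arbitrary callable from cohort to BFs,
so the same machinery runs on idealized fit streams (fast, used in tests
and examples) or on the full simulate→preprocess→fit chain.

## Problem sizes in the shipped tests and script

The bundled test suite and the acceptance script favour sizes that keep
a full run in the tens of seconds while leaving Monte-Carlo error well
inside the asserted tolerances: cohorts of 12–400 simulated
participants, 5000 design-analysis replications, 10⁴–2×10⁴ power
replications, and 4×10⁵-draw Monte-Carlo oracles.  All of these are
parameters, not constants.

## Known limitations

* The generator's ex-Gaussian parameters are shared across participants;
  real between-participant RT-shape heterogeneity would inflate slope
  SEs somewhat.
* Group slope estimates inherit a small attenuation from fixed-threshold
  trimming (see above); this is a property of the preregistered
  pipeline, not of the estimator.
* The correlation-BF prior width and the MARC/intercept population SDs
  are conventions, not estimates.
* `required_n` assumes monotone evidence probability in n, which holds
  for one-sample designs with fixed d but is not verified per call.
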