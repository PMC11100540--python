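# Methods

## Scope and rationale

`wmgate` packages the inferential pipeline of a four-experiment paradigm that
asks *when* working memory (WM) draws on episodic long-term memory (eLTM):
paired-associate 4AFC tasks crossing WM load with LTM load (E1/E2), a
set-size x pair-type design contrasting new-new, old-match and old-mismatch
pairings (E3), and a continuous colour-reproduction analogue (E4).  Because
the human trial-level data are not packaged here, every inferential component
is validated by **parameter recovery on synthetic cohorts**: the generative
simulators are first-class, tested code, and the acceptance surface is
"simulate at known parameters, fit, and check that the truth comes back".

## Generative models (the study conditions)

### Trial schedules

The schedule builders reproduce the printed designs exactly: E1 has 90 WM
trials (15 per condition in {2+0, 4+0, 6+0, 0+2, 2+2, 4+2}, one per condition
per block across 15 blocks) with two learning phases of 90 word pairs; E2
drops the 2+2 cell (75 trials — the minimal delta from E1); E3 has 27 trials
in 3 blocks of 9 with 54 learned pairs; E4 has 81 trials in 9 blocks of 9
with 120 learned colour-object conjunctions (studied in groups of 10).  Each
E3/E4 block contains one trial per set-size-2 composition, three trials of
the single set-size-3 composition and one per set-size-4 composition — the
only reading consistent with both "blocks of 9" and "three trials per set
size".  In E3 this consumes each of the 54 learned pairs exactly once; in E4
the 120-conjunction pool is consumed without replacement and the
earliest-used objects are recycled once it is exhausted (the printed
counts, 18 old objects per block over 9 blocks, exceed 120).

Stimulus identities are opaque integers (the analyses use only the category
structure); new identifiers never repeat.  Presentation timings are carried
as metadata only.  The colour wheel is the standard CIELAB circle (centre
L = 70, a = 20, b = 38, radius 60) with 360 one-degree steps; all colour
arithmetic lives on degrees in [-180, 180).

### Response simulators

4AFC choices are multinomial draws over {target, within-trial intrusion, LTM
lure, new} with propensities per design cell; the within-trial lure's source
pair is drawn uniformly from the trial's other pairs, so in mixed E1/E2
trials it comes from an LTM pair or a new pair with positive probability.
Continuous reproduction first draws a component — memory, swap, guess, LTM
intrusion — and then a colour: von Mises around the component's centre
(the swap centre uniform over the trial's other items, the standard swap
convention) or uniform for guessing.  Old-mismatch pairs carry their
genuinely pre-learned colour; new-new and old-match pairs receive
"imaginary" LTM colours drawn uniformly from the wheel, giving the intrusion
parameter a baseline cell in which its true value is at floor.  The
generator samples the LTM component around the imaginary colour too — it
mirrors the fitted model, not a claim about real behaviour in those cells.

Cohorts (`simulate_population`) place participant variation on the
unconstrained scales: a Normal intercept shift on the accuracy logit for
choice cohorts (lure logits held equal, so a +delta on one condition's entry
is exactly a +delta-logit accuracy effect), and one Normal deviation per
mixture-component baseline plus one on log-kappa for reproduction cohorts.
Default dispersions (0.5 SD on accuracy logits; 0.3/0.3/0.3/0.2 on the
mixture baselines) are typical of the between-participant spread seen in
hierarchical fits of this kind of task.  Ground truth is returned with the
data.

## Inference

### Sampler

No probabilistic-programming backend is used: both models expose a log
posterior and analytic gradient on an unconstrained vector, sampled by a
compact multinomial No-U-Turn sampler with dual-averaging step-size
adaptation (target acceptance 0.8–0.85), a diagonal mass matrix estimated in
doubling warmup windows, and divergence detection at an energy error of
1000.  Gradients are verified against finite differences in the test suite;
the sampler itself is validated on analytically known Gaussians.
Convergence is assessed by split-R-hat (arviz) with the conventional
pass threshold 1.01; non-convergence is reported, never hidden.  The
mixture likelihood's hot path has a numba-compiled kernel with an
equivalent vectorized numpy fallback.

### Aggregated binomial GLMM (E1–E3)

Per participant x cell counts k/n are modelled Binomial with a logit link
(which also buys power near ceiling/floor).  Fixed-effect priors are
Normal(0, 1) (Normal(0, 1.5) on the intercept).  Every fixed-effect column
gets a by-participant random slope, non-centred, **independent across
columns** with half-Student-t(3, 2.5) SD priors: the focal quantities are
population-level cell contrasts, which do not involve random-effect
correlations, and the diagonal structure keeps the hand-coded gradients
simple and the posterior well-conditioned.  Two codings are offered:
sum-to-zero *cell* coding (always full rank — the E1/E2 load crossing
observes only 6 of the 4 x 2 factorial cells, so a factorial
parameterization of that design is rank-deficient and is rejected rather
than silently repaired) and sum-to-zero *factorial* coding for complete
designs.  Cell means on the logit scale are attached to the posterior draws,
and the prior SD of any cell contrast follows analytically from the
coefficient priors — this is what the Savage-Dickey tests use.

### Hierarchical von Mises mixture (E4)

Each response's density is
`P_M vM(target, kappa) + P_Swap mean_j vM(other_j, kappa) + P_LTM vM(ltm, kappa) + P_G/360`,
per degree.  Component probabilities vary over set size x pair type through
a SoftMax link with the guessing logit fixed at 0 (any reference works; the
tests check the SoftMax identities); kappa varies over set size through a
log link and is shared by all three von Mises components (the minimal
parameterization).  Participants deviate on each component's baseline logit
and on log-kappa — one deviation per component shared across cells rather
than a deviation per cell.  This keeps the posterior ~150-dimensional, is
exactly mirrored by the generator, and recovers the group parameters well;
richer per-cell hierarchies are a straightforward extension but are not
needed for the questions the model answers here.  Priors: Normal(0, 1) on
group logits, Normal(log 10, 1) on group log-kappa, half-Normal(0.5) on the
participant SDs; all overridable.

### Evidence

Savage-Dickey BF10 = prior(0)/posterior(0), the posterior density at zero
estimated by default from a normal approximation to the draws (the
logit-scale marginals are near-Gaussian; a KDE option exists and both are
gated by the conjugate normal oracle, which they must match within 5%).
Directed BFs are mass ratios by draw counting; when every draw falls on one
side the result is reported as a *bound* at the draw count, not a point
value.  BF10 > 3 counts as substantial evidence for an effect, BF01 > 3 for
the null, anything else inconclusive.

### Screening and descriptives

Chance levels: 25% (4AFC), 1/3 (3AFC — the learning test of E3 is
three-alternative, though the same results section quotes the 25% 4AFC
anchor; both are exposed), 90 degrees mean absolute error (continuous
reproduction; the expectation of |uniform error|).  Exclusion rules:
delayed-test accuracy strictly below chance; overall accuracy strictly more
than 2 SD below the cohort mean (the boundary case is kept); learning-phase
mean recall error within +/-5 degrees of 90 (the "did not learn, ~90 degrees"
rule made operational; the band is configurable).  Error bars are
Cousineau participant-centred means with the Morey sqrt(C/(C-1)) correction.

## Numerical choices and problem sizes

* Angles: degrees on [-180, 180); `wrap(180) = -180` by the half-open
  convention.  kappa = 0 is valid and means uniform, so the guessing
  component reuses the von Mises code path.
* Von Mises normalization uses exponentially scaled Bessel functions
  (stable to kappa ~ 1e5); log-kappa is clipped to [-10, 12] inside the
  hierarchical model.  The mixture density is floored at 1e-300 before the
  log.
* HDI is the literal narrowest-window interval over sorted draws; it
  requires at least 100 draws, Savage-Dickey and directed BFs at least 1000.
* Default MCMC settings are 4 chains x (2000 warmup + 3000 retained).  The
  test suite uses 2 chains x (400–500 warmup + 400–600 retained), which the
  recovery checks pass comfortably; at those sizes split-R-hat on the
  slowest hyperparameters (hierarchical SDs) sits around 1.01–1.03, so the
  reduced-setting tests assert R-hat < 1.05 as a sanity bound while the
  strict 1.01 criterion governs the `ConvergenceReport.passed` flag used by
  the pipeline.
* Reference recovery design: 30 participants x 81 trials, (P_M, P_Swap,
  P_G, P_LTM) = (0.7, 0.1, 0.1, 0.1), kappa = 12, five seeds; the
  calibration study uses 30 participants and ten seeds per condition on the
  two WM-load-2 cells of the E1 design.

## What the synthetic data do and do not show

The generators emulate the category structure, the factorial designs, the
wheel geometry, and participant-level heterogeneity of the real experiments.
They do not model serial-position effects, response times, learning dynamics
during the LTM phase, categorical colour memory, lapses of attention, or any
lexical/image content.  Passing recovery therefore demonstrates that the
estimation machinery is correct and calibrated *under the assumed generative
model* — it cannot certify that the model is adequate for any particular
human dataset, which is precisely what the convergence reports, baseline
(imaginary-colour) cells, and BF calibration checks are there to probe when
real data are supplied.

## Known limitations

* Random effects are independent across design columns; correlations
  between, e.g., participant intercepts and slopes are not estimated.
* The mixture hierarchy places participant deviations on component
  baselines, not on every cell; strong participant x condition interactions
  in component use would be absorbed into the residual fit.
* The Savage-Dickey normal estimator is exact only for Gaussian marginals;
  for visibly skewed contrasts use the KDE option.
* Directed BFs from finite draws saturate at the draw count; astronomically
  large evidence is reported as a bound.
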