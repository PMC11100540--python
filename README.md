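# wmgate

Simulation and hierarchical Bayesian inference for experiments on **when
working memory (WM) draws on episodic long-term memory (eLTM)**.

The paradigm: participants first commit material to eLTM (word pairs, or
colour-object conjunctions on a 360-colour wheel), then perform a WM task
whose trials mix novel and pre-learned material while WM load varies.  If WM
contents are shielded from LTM at low load, pre-learned material should
produce neither proactive facilitation (old-match vs. new-new pairings) nor
proactive interference (old-mismatch vs. new-new) at sub-capacity set sizes,
with both appearing once capacity is exceeded.  `wmgate` provides the full
analysis stack for that question — and, because trial-level human data are
not bundled, validates it by parameter recovery on synthetic cohorts drawn
from explicit generative models of all four designs.

## What's inside

* **`wmgate.design` / `wmgate.simulate`** — exact trial schedules for the
  four experiments (load crossing 2+0 … 4+2; set-size x pair-type
  compositions; the CIELAB colour wheel, centre L=70, a=20, b=38, radius 60)
  and generative simulators for 4AFC choices and continuous colour
  reproduction, including cohort-level generators that return ground truth.
* **`wmgate.choice_model`** — the aggregated binomial logistic mixed model:
  k correct of n retrievals per participant x cell, logit link, Normal(0, 1)
  coefficient priors, by-participant random slopes.
* **`wmgate.mixture_model`** — the hierarchical von Mises mixture for
  continuous reproduction, separating target retrieval (`P_M`), swaps to
  other within-trial items (`P_Swap`), intrusions of pre-learned colours
  (`P_LTM`, with uniformly drawn "imaginary" baseline colours for pairs that
  have none), and uniform guessing (`P_G`), via a SoftMax link with
  precision kappa per set size:

  `f(x) = P_M·vM(x; θ_target, κ) + P_Swap·(1/m)Σ_j vM(x; θ_j, κ) + P_LTM·vM(x; θ_LTM, κ) + P_G/360`

* **`wmgate.evidence`** — Savage-Dickey density-ratio Bayes factors
  (BF10 = prior(0)/posterior(0)), directed BFs by posterior-mass counting,
  and the BF > 3 classification rule.
* **`wmgate.screening`** — chance levels (25% on 4AFC, 1/3 on 3AFC, 90°
  mean absolute error for reproduction), participant exclusion rules, and
  Cousineau-Morey within-subject confidence intervals.
* **`wmgate.sampler`** — a compact No-U-Turn sampler (both models supply
  analytic gradients); split-R-hat convergence reporting via arviz.
* **`wmgate.recovery` + CLI** — end-to-end recovery studies
  (`wmgate simulate|fit-choice|fit-mixture|bf|screen|report|recover`).

## Worked example

Simulate an E3-style cohort (30 participants) in which facilitation and
interference exist only at set size 4 (+/-1.0 logit), fit the hierarchical
logistic model, and test the focal contrasts:

```python
import numpy as np
from scipy.stats import norm
from wmgate import (ChoicePopulation, simulate_population, aggregate_cells,
                    fit_binomial_glmm, GLMMSpec, pf_pi_contrasts,
                    savage_dickey_bf, hdi)
from wmgate.choice_model import contrast_prior_sd

acc = {(ss, pt): 1.2 for ss in (2, 3, 4)
       for pt in ("new_new", "old_match", "old_mismatch")}
acc[(4, "old_match")] += 1.0      # proactive facilitation at set size 4
acc[(4, "old_mismatch")] -= 1.0   # proactive interference at set size 4

pop = ChoicePopulation("E3", acc, sd_intercept=0.5)
cohort = simulate_population(pop, 30, seed=7)
counts = aggregate_cells(cohort.data, ["set_size", "pair_type"])
draws, report = fit_binomial_glmm(
    counts, GLMMSpec(factors=("set_size", "pair_type")),
    n_chains=2, n_warmup=500, n_samples=1000, seed=8)

print(f"max R-hat: {report.max_rhat():.3f}")
for ss in (2, 4):
    for name, cd in pf_pi_contrasts(draws, ss).items():
        cell = "old_match" if name == "facilitation" else "old_mismatch"
        prior_sd = contrast_prior_sd(draws, {(ss, cell): 1.0, (ss, "new_new"): -1.0})
        bf = savage_dickey_bf(cd, norm.pdf(0, scale=prior_sd))
        lo, hi = hdi(cd)
        print(f"SS{ss} {name:13s} mean {cd.mean():+.2f}  95% HDI [{lo:+.2f}, {hi:+.2f}]"
              f"  BF10 {bf.bf10:.3g} ({bf.classification})")
```

Output:

```
max R-hat: 1.012
SS2 facilitation  mean -0.20  95% HDI [-0.72, +0.28]  BF10 0.245 (substantial_for_null)
SS2 interference  mean -0.10  95% HDI [-0.63, +0.45]  BF10 0.212 (substantial_for_null)
SS4 facilitation  mean +1.15  95% HDI [+0.72, +1.55]  BF10 3.06e+05 (substantial_for_effect)
SS4 interference  mean -1.06  95% HDI [-1.45, -0.64]  BF10 2.22e+04 (substantial_for_effect)
```

The contrasts are on the logit scale.  At set size 2 (no true effect) the
Bayes factors correctly favour the null; at set size 4 the generated
+/-1.0-logit effects are recovered (posterior means +1.15 / -1.06, 95%
highest-density intervals covering the truth) with decisive evidence.

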