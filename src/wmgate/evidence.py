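"""Bayes factors from posterior draws.

Two kinds of evidence are computed, matching how every inferential claim in
this line of experiments is phrased:

* **Savage-Dickey** point-null BF: the ratio of prior to posterior density of
  the test-relevant parameter at the null value (0).  The posterior density
  at 0 is estimated either from a normal approximation to the draws (stable
  for the near-Gaussian logit-scale marginals) or by Gaussian KDE.
* **Directed** BF: the ratio of posterior mass in the expected direction to
  the mass in the other direction, computed by draw counting.  When the
  minority count is zero the BF is reported as a lower bound at the number
  of draws.

Classification uses the conventional threshold: BF10 > 3 is substantial
evidence for an effect, BF01 > 3 substantial evidence for the null,
anything else inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BFResult", "savage_dickey_bf", "directed_bf", "classify_bf"]


@dataclass
class BFResult:
    bf10: float
    kind: str                    # "point_null_savage_dickey" or "directed"
    parameter: str = ""
    prior: str = ""
    bounded: bool = False        # True when bf10 is a counting bound

    def __post_init__(self):
        if not (self.bf10 > 0):
            raise ValueError("bf10 must be positive")

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def classification(self) -> str:
        return classify_bf(self.bf10)


def savage_dickey_bf(
    draws,
    prior_density_at_zero: float,
    estimator: str = "normal",
    parameter: str = "",
    prior: str = "",
) -> BFResult:
    """Savage-Dickey density-ratio BF10 = prior(0) / posterior(0).

    ``draws`` are posterior draws of the test-relevant parameter (at least
    1000); ``prior_density_at_zero`` is the prior density at the constraint.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 1000:
        raise ValueError("need at least 1000 draws for a Savage-Dickey estimate")
    if not prior_density_at_zero > 0:
        raise ValueError("prior density at 0 must be positive")
    if estimator == "normal":
        sd = float(np.std(x, ddof=1))
        if sd <= 0:
            raise ValueError("degenerate draws: zero spread")
        post0 = float(stats.norm.pdf(0.0, loc=float(np.mean(x)), scale=sd))
    elif estimator == "kde":
        post0 = float(stats.gaussian_kde(x)(0.0)[0])
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not post0 > 0:
        raise ValueError("posterior density estimate at 0 is nonpositive")
    return BFResult(
        bf10=prior_density_at_zero / post0,
        kind="point_null_savage_dickey",
        parameter=parameter,
        prior=prior or f"density(0)={prior_density_at_zero:.6g}, estimator={estimator}",
    )


def directed_bf(draws, direction: str = "positive", parameter: str = "") -> BFResult:
    """Directed BF by draw counting: mass in the expected direction over the rest."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 1000:
        raise ValueError("need at least 1000 draws for a directed BF")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    n_pos = int(np.sum(x > 0))
    n_neg = int(np.sum(x < 0))
    n_for, n_against = (n_pos, n_neg) if direction == "positive" else (n_neg, n_pos)
    if n_against == 0:
        # all draws on one side: report a bound at the draw count
        return BFResult(bf10=float(x.size), kind="directed", parameter=parameter,
                        prior=f"direction={direction}", bounded=True)
    return BFResult(bf10=n_for / n_against, kind="directed", parameter=parameter,
                    prior=f"direction={direction}")


def classify_bf(bf10: float) -> str:
    """BF10 > 3: substantial for the effect; BF01 > 3: substantial for the null;
    otherwise inconclusive."""
    if not bf10 > 0:
        raise ValueError("bf10 must be positive")
    if bf10 > 3.0:
        return "substantial_for_effect"
    if 1.0 / bf10 > 3.0:
        return "substantial_for_null"
    return "inconclusive"
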