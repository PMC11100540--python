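"""Participant screening, chance levels, descriptives, within-subject CIs.

Screening mirrors the preregistered-style exclusion rules of the
experiments: below-chance accuracy on the delayed memory test, overall
accuracy more than two standard deviations below the cohort mean, and (for
the continuous-reproduction learning phase) mean recall error at the 90-degree
chance level.  Condition-mean error bars use the Cousineau participant-
centering with the Morey sqrt(C/(C-1)) correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import abs_circ_error

DEFAULT_RULES = ("below_chance_delayed_test", "two_sd_below_mean", "at_chance_learning_error")


def chance_level(task: str):
    """Reference chance performance: accuracy for n-AFC, mean absolute error
    (degrees) for continuous reproduction."""
    levels = {
        "four_afc": 0.25,
        "three_afc": 1.0 / 3.0,
        "continuous_reproduction": 90.0,
    }
    if task not in levels:
        raise ValueError(f"unknown task {task!r}")
    return levels[task]


@dataclass
class ScreeningConfig:
    task: str = "four_afc"            # delayed-test task for the chance rule
    learning_error_band: float = 5.0  # degrees around 90 counting as "at chance"
    sd_multiplier: float = 2.0


def screen_participants(
    summaries: pd.DataFrame,
    rules=DEFAULT_RULES,
    config: ScreeningConfig | None = None,
):
    """Apply exclusion rules to per-participant summaries.

    ``summaries`` needs a ``participant`` column plus, per rule used:
    ``delayed_test_accuracy`` (below-chance rule), ``overall_accuracy``
    (2-SD rule; the boundary case exactly at mean - 2 SD is kept, the rule is
    strictly *below*), ``learning_mean_error`` (at-chance learning rule).
    Returns ``(kept, excluded)`` where ``excluded`` records each reason.
    """
    config = config or ScreeningConfig()
    if "participant" not in summaries.columns:
        raise ValueError("summaries need a participant column")
    reasons: dict = {}

    def flag(mask, rule):
        for p in summaries.loc[mask, "participant"]:
            reasons.setdefault(p, []).append(rule)

    for rule in rules:
        if rule == "below_chance_delayed_test":
            col = "delayed_test_accuracy"
            if col not in summaries.columns:
                raise ValueError(f"rule {rule!r} needs column {col!r}")
            flag(summaries[col] < chance_level(config.task), rule)
        elif rule == "two_sd_below_mean":
            col = "overall_accuracy"
            if col not in summaries.columns:
                raise ValueError(f"rule {rule!r} needs column {col!r}")
            mean, sd = summaries[col].mean(), summaries[col].std(ddof=1)
            if np.isfinite(sd) and sd > 0:
                flag(summaries[col] < mean - config.sd_multiplier * sd, rule)
        elif rule == "at_chance_learning_error":
            col = "learning_mean_error"
            if col not in summaries.columns:
                continue  # rule only applies to continuous-reproduction cohorts
            err = summaries[col]
            chance = chance_level("continuous_reproduction")
            flag(err.notna() & ((err - chance).abs() <= config.learning_error_band), rule)
        else:
            raise ValueError(f"unknown screening rule {rule!r}")

    excluded_ids = set(reasons)
    kept = summaries[~summaries["participant"].isin(excluded_ids)].reset_index(drop=True)
    excluded = pd.DataFrame(
        [{"participant": p, "reasons": ";".join(r)} for p, r in sorted(reasons.items())]
    )
    return kept, excluded


def within_subject_ci(condition_means: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals per condition.

    ``condition_means`` is a participant x condition table (index =
    participant, one column per condition, no missing entries).  Participant
    means are removed, the grand mean restored, and the SE scaled by
    sqrt(C/(C-1)) before forming mean +/- t * SE intervals.
    """
    tab = condition_means.astype(float)
    if tab.isna().any().any():
        raise ValueError("condition x participant table must be complete")
    n, C = tab.shape
    if n < 2:
        raise ValueError("need at least two participants")
    if C < 2:
        raise ValueError("centering undefined with a single condition")
    centered = tab.sub(tab.mean(axis=1), axis=0) + tab.values.mean()
    morey = np.sqrt(C / (C - 1.0))
    se = centered.std(axis=0, ddof=1) / np.sqrt(n) * morey
    tq = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return pd.DataFrame(
        {
            "mean": tab.mean(axis=0),
            "se": se,
            "lower": tab.mean(axis=0) - tq * se,
            "upper": tab.mean(axis=0) + tq * se,
        }
    )


def describe(dataset: pd.DataFrame, factors=None, level: float = 0.95) -> pd.DataFrame:
    """Per-condition accuracy (4AFC data) or mean absolute recall error
    (reproduction data), with within-subject CIs when at least two
    participants share all conditions.
    """
    df = dataset.copy()
    if df.get("response_category") is not None and df["response_category"].notna().any():
        df["_score"] = (df["response_category"] == "target").astype(float)
        measure = "accuracy"
    elif "response_deg" in df.columns and df["response_deg"].notna().any():
        df["_score"] = abs_circ_error(
            df["response_deg"].to_numpy(dtype=float),
            df["target_color_deg"].to_numpy(dtype=float),
        )
        measure = "mean_abs_error_deg"
    else:
        raise ValueError("dataset has neither choice nor reproduction responses")
    if factors is None:
        factors = ["set_size", "pair_type"] if df["pair_type"].nunique() > 2 or \
            df["experiment"].iloc[0] in ("E3", "E4") else ["wm_load", "ltm_load"]
    per_part = df.groupby(["participant"] + list(factors))["_score"].mean().unstack(factors)
    out = per_part.mean(axis=0).to_frame("mean")
    out["n_participants"] = per_part.notna().sum(axis=0)
    if per_part.shape[0] >= 2 and per_part.shape[1] >= 2 and not per_part.isna().any().any():
        ci = within_subject_ci(per_part, level)
        out["se"], out["lower"], out["upper"] = ci["se"], ci["lower"], ci["upper"]
    out.attrs["measure"] = measure
    return out.reset_index()
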