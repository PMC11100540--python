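"""Aggregation, design matrices, and the hierarchical logistic model."""

import numpy as np
import pandas as pd
import pytest

from wmgate.choice_model import (
    GLMMSpec,
    aggregate_cells,
    contrast,
    contrast_prior_sd,
    fit_binomial_glmm,
    pf_pi_contrasts,
)
from wmgate.simulate import ChoicePopulation, simulate_population

E3_CELLS = [(ss, pt) for ss in (2, 3, 4)
            for pt in ("new_new", "old_match", "old_mismatch")]


def _toy_rows(cats, participant=0, wm=2, ltm=0):
    return pd.DataFrame({
        "participant": participant,
        "wm_load": wm,
        "ltm_load": ltm,
        "response_category": cats,
    })


def test_aggregate_counts_target_responses():
    df = _toy_rows(["target", "target", "new", "target"])
    cells = aggregate_cells(df, ["wm_load", "ltm_load"])
    assert len(cells) == 1
    assert cells.iloc[0].k == 3 and cells.iloc[0].n == 4


def test_aggregate_all_target_cell():
    df = _toy_rows(["target"] * 5)
    cells = aggregate_cells(df, ["wm_load", "ltm_load"])
    assert cells.iloc[0].k == cells.iloc[0].n == 5


def test_aggregate_totals_match_raw_table():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "participant": rng.integers(0, 5, 300),
        "wm_load": rng.choice([2, 4], 300),
        "ltm_load": rng.choice([0, 2], 300),
        "response_category": rng.choice(["target", "new", "ltm_lure"], 300),
    })
    cells = aggregate_cells(df, ["wm_load", "ltm_load"])
    assert cells["n"].sum() == len(df)
    assert cells["k"].sum() == (df.response_category == "target").sum()


def test_aggregate_retains_empty_cells():
    df = pd.concat([
        _toy_rows(["target"], participant=0, wm=2),
        _toy_rows(["new"], participant=1, wm=4),
    ])
    cells = aggregate_cells(df, ["wm_load", "ltm_load"])
    assert len(cells) == 4  # 2 participants x 2 observed cells
    zero = cells[(cells.participant == 0) & (cells.wm_load == 4)]
    assert (zero.n == 0).all()


def test_factorial_coding_requires_complete_design():
    # the load-crossing design's six cells do not fill the 4 x 2 factorial
    df = pd.concat([
        _toy_rows(["target"], wm=w, ltm=l)
        for w, l in [(2, 0), (4, 0), (6, 0), (0, 2), (2, 2), (4, 2)]
    ])
    cells = aggregate_cells(df, ["wm_load", "ltm_load"])
    spec = GLMMSpec(factors=("wm_load", "ltm_load"), coding="factorial")
    with pytest.raises(ValueError, match="complete factorial"):
        fit_binomial_glmm(cells, spec, n_chains=1, n_warmup=10, n_samples=10, seed=0)


def test_intercept_only_model_centered_at_zero_for_even_split():
    cells = pd.DataFrame({"participant": range(4), "k": [200] * 4, "n": [400] * 4})
    draws, report = fit_binomial_glmm(
        cells, GLMMSpec(factors=()), n_chains=2, n_warmup=300, n_samples=500, seed=3
    )
    b = draws.flat("b[intercept]")
    assert abs(b.mean()) < 0.2  # logit(0.5) = 0
    assert report.max_rhat() < 1.05


@pytest.fixture(scope="module")
def e3_fit():
    """Moderate E3 cohort with facilitation/interference only at set size 4."""
    acc = {c: 1.2 for c in E3_CELLS}
    acc[(4, "old_match")] = 1.2 + 1.0
    acc[(4, "old_mismatch")] = 1.2 - 1.0
    pop = ChoicePopulation("E3", acc, sd_intercept=0.5)
    cohort = simulate_population(pop, 25, seed=91)
    cells = aggregate_cells(cohort.data, ["set_size", "pair_type"])
    draws, report = fit_binomial_glmm(
        cells, GLMMSpec(factors=("set_size", "pair_type"), coding="cells"),
        n_chains=2, n_warmup=400, n_samples=600, seed=92,
    )
    return draws, report


def test_effect_recovery_within_tolerance(e3_fit):
    draws, _ = e3_fit
    fac = contrast(draws, {(4, "old_match"): 1.0, (4, "new_new"): -1.0})
    assert fac.mean() == pytest.approx(1.0, abs=0.3)


def test_posterior_predictive_cell_means_in_unit_interval(e3_fit):
    draws, _ = e3_fit
    for ss, pt in E3_CELLS:
        p = 1.0 / (1.0 + np.exp(-draws.flat(f"cell[{ss},{pt}]")))
        assert ((p > 0) & (p < 1)).all()


def test_contrast_identities(e3_fit):
    draws, _ = e3_fit
    # contrast of a cell with itself: all-zero draws
    zero = contrast(draws, {(2, "new_new"): 0.0})
    assert np.all(zero == 0.0)
    d = {(3, "old_match"): 1.0, (3, "new_new"): -1.0}
    flipped = {k: -v for k, v in d.items()}
    np.testing.assert_allclose(contrast(draws, d), -contrast(draws, flipped))
    # brute-force recomputation from the raw cell draws
    brute = draws.flat("cell[3,old_match]") - draws.flat("cell[3,new_new]")
    np.testing.assert_allclose(contrast(draws, d), brute)
    with pytest.raises(KeyError):
        contrast(draws, {(9, "new_new"): 1.0})


def test_pf_pi_contrasts_match_generic_and_sign(e3_fit):
    draws, _ = e3_fit
    res4 = pf_pi_contrasts(draws, 4)
    np.testing.assert_allclose(
        res4["facilitation"],
        contrast(draws, {(4, "old_match"): 1.0, (4, "new_new"): -1.0}),
    )
    # generated with +1 logit facilitation and -1 logit interference at SS4
    assert (res4["facilitation"] > 0).mean() > 0.95
    assert (res4["interference"] < 0).mean() > 0.95
    res2 = pf_pi_contrasts(draws, 2)
    assert abs(res2["facilitation"].mean()) < 0.5
    with pytest.raises(KeyError):
        pf_pi_contrasts(draws, 9)


def test_contrast_prior_sd_positive_and_symmetric(e3_fit):
    draws, _ = e3_fit
    d = {(4, "old_match"): 1.0, (4, "new_new"): -1.0}
    sd = contrast_prior_sd(draws, d)
    assert sd > 0
    assert contrast_prior_sd(draws, {k: -v for k, v in d.items()}) == pytest.approx(sd)


def test_prior_dominance_limit():
    """With vanishing coefficient priors the effect posteriors collapse to 0."""
    acc = {(2, "new_new"): 1.5, (2, "old_match"): 0.0}
    pop = ChoicePopulation("E3", acc, sd_intercept=0.0)
    rows = []
    rng = np.random.default_rng(4)
    for p in range(8):
        for cell, logit in acc.items():
            prob = 1 / (1 + np.exp(-logit))
            k = rng.binomial(40, prob)
            rows.append({"participant": p, "set_size": cell[0],
                         "pair_type": cell[1], "k": k, "n": 40})
    cells = pd.DataFrame(rows)
    spec = GLMMSpec(factors=("set_size", "pair_type"), coding="cells", coef_sd=1e-3)
    draws, _ = fit_binomial_glmm(cells, spec, n_chains=2, n_warmup=300,
                                 n_samples=400, seed=5)
    dev = draws.flat("b[cell_dev[2,new_new]]")
    assert abs(dev.mean()) < 0.02
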