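"""Generative simulators: category frequencies, circular errors, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from wmgate.circular import abs_circ_error, circ_diff
from wmgate.design import build_design
from wmgate.mixture_model import MixtureParams
from wmgate.simulate import (
    CATEGORIES,
    ChoicePopulation,
    MixturePopulation,
    ParticipantParams,
    assign_imaginary_ltm_colors,
    simulate_choice_responses,
    simulate_delayed_test,
    simulate_population,
    simulate_repro_responses,
    write_dataset,
    read_dataset,
)


def uniform_params():
    return ParticipantParams(default_choice=np.full(4, 0.25))


def test_every_pair_tested_once(e1_schedule):
    df = simulate_choice_responses(e1_schedule, uniform_params(), seed=0)
    per_trial = df.groupby(["block", "trial"]).size()
    sizes = {(t.block, t.index_in_block): t.set_size for t in e1_schedule.trials}
    for key, n in per_trial.items():
        assert n == sizes[key]
    assert df["response_category"].isin(CATEGORIES).all()


def test_degenerate_propensities_give_perfect_accuracy(e1_schedule):
    p = ParticipantParams(default_choice=np.array([1.0, 0.0, 0.0, 0.0]))
    df = simulate_choice_responses(e1_schedule, p, seed=1)
    assert (df["response_category"] == "target").all()


def test_invalid_propensities_rejected(e1_schedule):
    p = ParticipantParams(default_choice=np.array([0.5, 0.5, 0.5, 0.5]))
    with pytest.raises(ValueError):
        simulate_choice_responses(e1_schedule, p, seed=1)


def test_category_frequencies_converge_to_propensities(e1_schedule):
    probs = np.array([0.55, 0.2, 0.15, 0.1])
    p = ParticipantParams(default_choice=probs)
    frames = [
        simulate_choice_responses(e1_schedule, p, seed=s, participant=s)
        for s in range(30)
    ]
    df = pd.concat(frames)
    n = len(df)
    freq = df["response_category"].value_counts(normalize=True)
    for cat, target in zip(CATEGORIES, probs):
        se = np.sqrt(target * (1 - target) / n)
        assert abs(freq.get(cat, 0.0) - target) < 3 * se + 1e-12


def test_choice_simulation_reproducible(e1_schedule):
    a = simulate_choice_responses(e1_schedule, uniform_params(), seed=9)
    b = simulate_choice_responses(e1_schedule, uniform_params(), seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_within_trial_intrusion_lure_comes_from_both_sources(e1_schedule):
    df = simulate_choice_responses(e1_schedule, uniform_params(), seed=2)
    mixed = df[(df.ltm_load > 0) & (df.wm_load > 0)]
    sources = set(mixed["intrusion_source"])
    assert {"ltm", "new"} <= sources


def test_imaginary_colors_uniform_and_seeded():
    s1 = assign_imaginary_ltm_colors(build_design("E4", seed=1), seed=50)
    s2 = assign_imaginary_ltm_colors(build_design("E4", seed=1), seed=50)
    cols1 = [
        p.ltm_color for t in s1.trials for p in t.items if p.pair_type != "old_mismatch"
    ]
    cols2 = [
        p.ltm_color for t in s2.trials for p in t.items if p.pair_type != "old_mismatch"
    ]
    assert cols1 == cols2
    # accumulate over seeds for a distributional check
    many = []
    for seed in range(40):
        s = assign_imaginary_ltm_colors(build_design("E4", seed=3), seed=seed)
        many += [
            p.ltm_color
            for t in s.trials
            for p in t.items
            if p.pair_type != "old_mismatch"
        ]
    stat = kstest((np.asarray(many) + 180.0) / 360.0, "uniform")
    assert stat.pvalue > 1e-4


def test_imaginary_colors_require_e4(e1_schedule):
    with pytest.raises(ValueError):
        assign_imaginary_ltm_colors(e1_schedule, seed=0)


def test_guessing_only_reproduction_is_at_chance(e4_schedule):
    params = ParticipantParams(
        mixture=MixtureParams.uniform_cells([0.0, 0.0, 1.0, 0.0], kappa=8.0)
    )
    frames = [
        simulate_repro_responses(e4_schedule, params, seed=s, participant=s)
        for s in range(10)
    ]
    df = pd.concat(frames)
    err = abs_circ_error(
        df["response_deg"].to_numpy(), df["target_color_deg"].to_numpy()
    )
    assert err.mean() == pytest.approx(90.0, abs=3 * 52.0 / np.sqrt(len(df)))


def test_perfect_memory_reproduction_hits_target(e4_schedule):
    params = ParticipantParams(
        mixture=MixtureParams.uniform_cells([1.0, 0.0, 0.0, 0.0], kappa=5000.0)
    )
    df = simulate_repro_responses(e4_schedule, params, seed=3)
    err = abs_circ_error(
        df["response_deg"].to_numpy(), df["target_color_deg"].to_numpy()
    )
    assert err.mean() < 2.0


def test_ltm_only_responses_follow_prelearned_color(e4_schedule):
    params = ParticipantParams(
        mixture=MixtureParams.uniform_cells([0.0, 0.0, 0.0, 1.0], kappa=50.0)
    )
    df = simulate_repro_responses(e4_schedule, params, seed=4)
    mm = df[df.pair_type == "old_mismatch"]
    to_ltm = np.abs(
        circ_diff(mm["response_deg"].to_numpy(), mm["ltm_color_deg"].to_numpy())
    ).mean()
    to_target = np.abs(
        circ_diff(mm["response_deg"].to_numpy(), mm["target_color_deg"].to_numpy())
    ).mean()
    assert to_ltm < 15.0 < to_target


def test_reproduction_requires_ltm_colors():
    sched = build_design("E4", seed=6)  # imaginary colours never assigned
    params = ParticipantParams(
        mixture=MixtureParams.uniform_cells([0.25, 0.25, 0.25, 0.25], kappa=5.0)
    )
    with pytest.raises(ValueError):
        simulate_repro_responses(sched, params, seed=0)


def test_population_dispersion_zero_gives_identical_participants():
    pop = MixturePopulation.from_probs([0.7, 0.1, 0.1, 0.1], 12.0, sd=(0, 0, 0, 0))
    cohort = simulate_population(pop, 4, seed=1)
    assert cohort.truth["P_M[2,new_new]"].nunique() == 1
    assert cohort.truth["kappa[2]"].nunique() == 1
    assert cohort.truth["P_M[2,new_new]"].iloc[0] == pytest.approx(0.7)


def test_population_cohort_mean_matches_group():
    pop = MixturePopulation.from_probs([0.7, 0.1, 0.1, 0.1], 12.0, sd=(0.3, 0.3, 0.3, 0.2))
    cohort = simulate_population(pop, 200, seed=2)
    # participant P_M values scatter around the group value
    assert cohort.truth["P_M[3,new_new]"].mean() == pytest.approx(0.7, abs=0.02)


def test_population_reproducible_and_dispersion_validated():
    pop = ChoicePopulation("E3", {(ss, pt): 0.8 for ss in (2, 3, 4)
                                  for pt in ("new_new", "old_match", "old_mismatch")},
                           sd_intercept=0.4)
    a = simulate_population(pop, 3, seed=5)
    b = simulate_population(pop, 3, seed=5)
    pd.testing.assert_frame_equal(a.data, b.data)
    pop.sd_intercept = -1.0
    with pytest.raises(ValueError):
        simulate_population(pop, 3, seed=5)


def test_delayed_test_covers_every_pair(e1_schedule):
    params = ParticipantParams(
        choice_probs={("delayed", "ltm"): np.array([0.7, 0.1, 0.1, 0.1]),
                      ("delayed", "new"): np.array([0.4, 0.2, 0.2, 0.2])}
    )
    df = simulate_delayed_test(e1_schedule, params, seed=8)
    assert len(df) == sum(t.set_size for t in e1_schedule.trials)
    acc = df.groupby("pair_type")["response_category"].apply(
        lambda s: (s == "target").mean()
    )
    assert acc["ltm"] > acc["new"]


def test_dataset_csv_roundtrip(tmp_path, e1_schedule):
    df = simulate_choice_responses(e1_schedule, uniform_params(), seed=0)
    path = tmp_path / "data.csv"
    write_dataset(df, path)
    back = read_dataset(path)
    assert len(back) == len(df)
    assert (back["response_category"] == df["response_category"].values).all()
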