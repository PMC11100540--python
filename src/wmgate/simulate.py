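"""Generative models of the four experiments' responses.

The simulators mirror the analysis models: 4AFC choices are multinomial
draws over {target, within-trial intrusion, LTM lure, new} with propensities
per design cell; continuous reproduction first draws a response component
(memory / swap / guess / LTM intrusion) and then a colour -- von Mises around
the component's centre, uniform for guessing.  ``simulate_population``
generates whole cohorts with participant-level variation on the
unconstrained scales (logit for probabilities, log for kappa) and returns
the ground truth alongside the data, which is what the parameter-recovery
suite consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import vm_sample, wrap_angle
from .design import TrialSchedule, build_design
from .mixture_model import MixtureParams

CATEGORIES = ("target", "within_intrusion", "ltm_lure", "new")

DATASET_COLUMNS = [
    "participant", "experiment", "block", "trial", "set_size", "wm_load",
    "ltm_load", "pair_type", "serial_position", "cue_id", "target_id",
    "target_color_deg", "ltm_color_deg", "response_category", "response_deg",
]


@dataclass
class ParticipantParams:
    """Per-participant generative parameters.

    ``choice_probs`` maps a condition key to a probability vector over
    :data:`CATEGORIES`.  Keys are tried from most to least specific:
    ``(set_size, pair_type)``, ``(wm_load, ltm_load, pair_type)``,
    ``(wm_load, ltm_load)``, then ``default_choice``.  ``mixture`` holds the
    continuous-reproduction parameters.
    """

    choice_probs: dict = field(default_factory=dict)
    default_choice: np.ndarray | None = None
    mixture: MixtureParams | None = None

    def probs_for(self, trial, pair) -> np.ndarray:
        keys = [
            (trial.set_size, pair.pair_type),
            (trial.wm_load, trial.ltm_load, pair.pair_type),
            (trial.wm_load, trial.ltm_load),
        ]
        for key in keys:
            if key in self.choice_probs:
                return _validated(self.choice_probs[key], key)
        if self.default_choice is not None:
            return _validated(self.default_choice, "default")
        raise KeyError(f"no choice propensities for trial cell {keys[0]}")


def _validated(p, key) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"propensities for {key} must be 4 nonnegative values summing to 1")
    return p


def assign_imaginary_ltm_colors(schedule: TrialSchedule, seed=None) -> TrialSchedule:
    """Fill the baseline "imaginary" LTM colours of an E4 schedule in place.

    new-new and old-match pairs get independent uniform wheel colours (they
    have no usable pre-learned colour: old-match's true colour *is* the
    target, so its baseline must be imaginary too); old-mismatch keeps the
    genuinely pre-learned colour.
    """
    if schedule.experiment_id != "E4":
        raise ValueError("imaginary LTM colours apply to the continuous-reproduction design only")
    rng = np.random.default_rng(seed)
    for trial in schedule.trials:
        for pair in trial.items:
            if pair.pair_type in ("new_new", "old_match"):
                pair.ltm_color = float(wrap_angle(rng.uniform(-180.0, 180.0)))
    return schedule


def _base_row(schedule, trial, pair, pos, participant):
    return {
        "participant": participant,
        "experiment": schedule.experiment_id,
        "block": trial.block,
        "trial": trial.index_in_block,
        "set_size": trial.set_size,
        "wm_load": trial.wm_load,
        "ltm_load": trial.ltm_load,
        "pair_type": pair.pair_type,
        "serial_position": pos,
        "cue_id": pair.cue_id,
        "target_id": pair.target_id,
        "target_color_deg": pair.target_color,
        "ltm_color_deg": pair.ltm_color,
        "response_category": None,
        "response_deg": None,
    }


def simulate_choice_responses(
    schedule: TrialSchedule,
    params: ParticipantParams,
    seed=None,
    participant=0,
) -> pd.DataFrame:
    """Simulate the 4AFC test of every pair of every WM trial.

    Pairs are tested in random order within a trial.  The within-trial
    intrusion lure is drawn uniformly from the trial's other pairs and its
    source pair type is recorded (``intrusion_source``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in schedule.trials:
        order = rng.permutation(len(trial.items))
        for pos in order:
            pair = trial.items[pos]
            p = params.probs_for(trial, pair)
            cat = CATEGORIES[rng.choice(4, p=p)]
            row = _base_row(schedule, trial, pair, int(pos), participant)
            row["response_category"] = cat
            if len(trial.items) > 1:
                others = [q for q in trial.items if q is not pair]
                row["intrusion_source"] = others[rng.integers(len(others))].pair_type
            else:
                row["intrusion_source"] = None
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_repro_responses(
    schedule: TrialSchedule,
    params: ParticipantParams,
    seed=None,
    participant=0,
) -> pd.DataFrame:
    """Simulate continuous colour reproduction for every pair of an E4 schedule.

    Component draws follow the participant's mixture probabilities for the
    pair's (set_size, pair_type) cell; the sampled component is recorded in
    the ``component`` column (simulation ground truth, absent in real data).
    """
    if params.mixture is None:
        raise ValueError("params.mixture required for reproduction simulation")
    mix = params.mixture
    rng = np.random.default_rng(seed)
    rows = []
    for trial in schedule.trials:
        order = rng.permutation(len(trial.items))
        for pos in order:
            pair = trial.items[pos]
            if pair.ltm_color is None:
                raise ValueError(
                    "pair without ltm_color; run assign_imaginary_ltm_colors first"
                )
            cell = (trial.set_size, pair.pair_type)
            if cell not in mix.probs:
                raise KeyError(f"no mixture probabilities for cell {cell}")
            p_m, p_swap, p_g, p_ltm = mix.probs[cell]
            kappa = mix.kappa[trial.set_size]
            comp = ("memory", "swap", "guess", "ltm")[
                rng.choice(4, p=[p_m, p_swap, p_g, p_ltm])
            ]
            if comp == "guess":
                resp = float(wrap_angle(rng.uniform(-180.0, 180.0)))
            else:
                if comp == "memory":
                    centre = pair.target_color
                elif comp == "ltm":
                    centre = pair.ltm_color
                else:
                    others = [q.target_color for q in trial.items if q is not pair]
                    centre = others[rng.integers(len(others))]
                resp = float(vm_sample(centre, kappa, 1, rng)[0])
            row = _base_row(schedule, trial, pair, int(pos), participant)
            row["response_deg"] = resp
            row["component"] = comp
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_delayed_test(
    schedule: TrialSchedule,
    params: ParticipantParams,
    seed=None,
    participant=0,
) -> pd.DataFrame:
    """Simulate the delayed 4AFC memory test over every pair of the experiment.

    Condition keys tried: ``("delayed", set_size, pair_type)``,
    ``("delayed", pair_type)``, then the WM-phase cascade.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in schedule.trials:
        for pos, pair in enumerate(trial.items):
            p = None
            for key in (("delayed", trial.set_size, pair.pair_type),
                        ("delayed", pair.pair_type)):
                if key in params.choice_probs:
                    p = _validated(params.choice_probs[key], key)
                    break
            if p is None:
                p = params.probs_for(trial, pair)
            cat = CATEGORIES[rng.choice(4, p=p)]
            row = _base_row(schedule, trial, pair, pos, participant)
            row["response_category"] = cat
            row["phase"] = "delayed"
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Population-level generators
# --------------------------------------------------------------------------


@dataclass
class ChoicePopulation:
    """Cohort-level 4AFC generator.

    ``accuracy_logit`` gives the group-mean accuracy per condition key on the
    logit scale; participants deviate by a shared Normal(0, sd_intercept)
    intercept.  Errors are split across the three lure categories by
    ``lure_split``.  With lure logits held equal, adding ``delta`` to a
    condition's entry shifts that cell's accuracy by exactly ``delta`` logits.
    """

    experiment_id: str
    accuracy_logit: dict
    sd_intercept: float = 0.5
    lure_split: tuple = (1 / 3, 1 / 3, 1 / 3)

    def participant_params(self, shift: float) -> ParticipantParams:
        probs = {}
        split = np.asarray(self.lure_split, dtype=float)
        split = split / split.sum()
        for key, logit in self.accuracy_logit.items():
            acc = 1.0 / (1.0 + np.exp(-(logit + shift)))
            probs[key] = np.concatenate([[acc], (1.0 - acc) * split])
        return ParticipantParams(choice_probs=probs)


@dataclass
class MixturePopulation:
    """Cohort-level continuous-reproduction generator.

    Group logits (memory, swap, LTM; guessing fixed at 0) per
    (set_size, pair_type) cell and log-kappa per set size; participant
    deviations are one normal draw per component baseline plus one on
    log-kappa, shared across cells -- the same hierarchy the fitted model
    assumes.
    """

    logits: dict          # (set_size, pair_type) -> (l_M, l_Swap, l_LTM)
    log_kappa: dict       # set_size -> group log concentration
    sd: tuple = (0.3, 0.3, 0.3, 0.2)  # (M, Swap, LTM, log_kappa)

    def participant_params(self, dev: np.ndarray) -> ParticipantParams:
        probs, kappa = {}, {}
        for cell, (lm, ls, ll) in self.logits.items():
            z = np.array([lm + dev[0], ls + dev[1], 0.0, ll + dev[2]])
            e = np.exp(z - z.max())
            pm, psw, pg, pl = e / e.sum()
            probs[cell] = np.array([pm, psw, pg, pl])
        for ss, g in self.log_kappa.items():
            kappa[ss] = float(np.exp(g + dev[3]))
        return ParticipantParams(mixture=MixtureParams(probs=probs, kappa=kappa))

    @classmethod
    def from_probs(cls, p, kappa, set_sizes=(2, 3, 4),
                   pair_types=("new_new", "old_match", "old_mismatch"),
                   sd=(0.3, 0.3, 0.3, 0.2)):
        """Build from a single probability vector [P_M, P_Swap, P_G, P_LTM]."""
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0):
            raise ValueError("probabilities must be positive to place them on the logit scale")
        ref = np.log(p / p[2])  # guess as SoftMax reference
        logits = {(ss, pt): (ref[0], ref[1], ref[3]) for ss in set_sizes for pt in pair_types}
        log_kappa = {ss: float(np.log(kappa)) for ss in set_sizes}
        return cls(logits=logits, log_kappa=log_kappa, sd=sd)


@dataclass
class Cohort:
    data: pd.DataFrame
    truth: pd.DataFrame        # per-participant true parameters
    group: object              # the generating population object
    schedules: list = field(default_factory=list)


def simulate_population(group_params, n_participants: int, seed=None) -> Cohort:
    """Simulate a cohort: per-participant schedules, data, and ground truth."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    part_seeds = ss.spawn(2 * n_participants)

    frames, truth_rows, schedules = [], [], []
    if isinstance(group_params, ChoicePopulation):
        if group_params.sd_intercept < 0:
            raise ValueError("dispersion must be nonnegative")
        for i in range(n_participants):
            shift = float(rng.normal(0.0, group_params.sd_intercept))
            pp = group_params.participant_params(shift)
            sched = build_design(group_params.experiment_id, seed=part_seeds[2 * i])
            df = simulate_choice_responses(sched, pp, seed=part_seeds[2 * i + 1],
                                           participant=i)
            frames.append(df)
            schedules.append(sched)
            row = {"participant": i, "intercept_shift": shift}
            for key, logit in group_params.accuracy_logit.items():
                row[f"acc[{_key_str(key)}]"] = 1.0 / (1.0 + np.exp(-(logit + shift)))
            truth_rows.append(row)
    elif isinstance(group_params, MixturePopulation):
        sd = np.asarray(group_params.sd, dtype=float)
        if np.any(sd < 0):
            raise ValueError("dispersion must be nonnegative")
        for i in range(n_participants):
            dev = rng.normal(0.0, 1.0, size=4) * sd
            pp = group_params.participant_params(dev)
            sched = build_design("E4", seed=part_seeds[2 * i])
            assign_imaginary_ltm_colors(sched, seed=part_seeds[2 * i])
            df = simulate_repro_responses(sched, pp, seed=part_seeds[2 * i + 1],
                                          participant=i)
            frames.append(df)
            schedules.append(sched)
            row = {"participant": i}
            for j, nm in enumerate(("dev_M", "dev_Swap", "dev_LTM", "dev_log_kappa")):
                row[nm] = dev[j]
            for cell, p in pp.mixture.probs.items():
                for k, nm in enumerate(("P_M", "P_Swap", "P_G", "P_LTM")):
                    row[f"{nm}[{_key_str(cell)}]"] = p[k]
            for s, k in pp.mixture.kappa.items():
                row[f"kappa[{s}]"] = k
            truth_rows.append(row)
    else:
        raise TypeError("group_params must be ChoicePopulation or MixturePopulation")
    return Cohort(
        data=pd.concat(frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        group=group_params,
        schedules=schedules,
    )


def _key_str(key) -> str:
    if isinstance(key, tuple):
        return ",".join(map(str, key))
    return str(key)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset in the standard CSV schema (extra columns appended)."""
    cols = [c for c in DATASET_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS[:13]) - set(df.columns) - {"response_category", "response_deg"}
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    return df
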