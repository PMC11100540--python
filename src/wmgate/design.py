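"""Trial schedules for the four working-memory / episodic-LTM experiments.

The four designs share a two-phase logic: an LTM learning phase (word pairs
or colour-object conjunctions committed to episodic long-term memory) followed
by a working-memory task whose trials mix novel material with the pre-learned
material.

* E1 -- verbal 4AFC, WM load x LTM load: conditions 2+0, 4+0, 6+0, 0+2, 2+2,
  4+2 (new pairs + LTM pairs), 15 trials per condition in 15 blocks of 6,
  90 WM trials; 90 pairs learned per learning phase (two phases).
* E2 -- E1 without the 2+2 condition (75 trials, 15 blocks of 5).
* E3 -- verbal 4AFC, set size (2, 3, 4) x pair type (new-new / old-match /
  old-mismatch) with the fixed trial compositions below; 27 trials in
  3 blocks of 9; 54 pairs learned.
* E4 -- continuous colour reproduction with the same compositions; 81 trials
  in 9 blocks of 9; 120 colour-object conjunctions learned in groups of 10.

Set-size compositions (pair-type multisets) used by E3 and E4:

===== ==========================================================
SS    compositions
===== ==========================================================
2     {new_new, old_mismatch}, {old_mismatch, old_match},
      {new_new, old_match}
3     {new_new, old_mismatch, old_match}
4     {new_new, new_new, old_mismatch, old_match},
      {new_new, old_mismatch, old_mismatch, old_match},
      {new_new, old_mismatch, old_match, old_match}
===== ==========================================================

A block holds one trial per SS2 composition, three trials of the SS3
composition and one per SS4 composition (nine trials, three per set size),
shuffled within the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import wrap_angle

EXPERIMENTS = ("E1", "E2", "E3", "E4")

#: (wm_load, ltm_load) cells of the E1 working-memory task.
E1_CONDITIONS = ((2, 0), (4, 0), (6, 0), (0, 2), (2, 2), (4, 2))
#: E2 drops the 2+2 cell.
E2_CONDITIONS = tuple(c for c in E1_CONDITIONS if c != (2, 2))

NEW_NEW, OLD_MATCH, OLD_MISMATCH = "new_new", "old_match", "old_mismatch"

#: Trial compositions by set size (rows of the design table shared by E3/E4).
COMPOSITIONS = {
    2: (
        (NEW_NEW, OLD_MISMATCH),
        (OLD_MISMATCH, OLD_MATCH),
        (NEW_NEW, OLD_MATCH),
    ),
    3: ((NEW_NEW, OLD_MISMATCH, OLD_MATCH),),
    4: (
        (NEW_NEW, NEW_NEW, OLD_MISMATCH, OLD_MATCH),
        (NEW_NEW, OLD_MISMATCH, OLD_MISMATCH, OLD_MATCH),
        (NEW_NEW, OLD_MISMATCH, OLD_MATCH, OLD_MATCH),
    ),
}


@dataclass
class PairSpec:
    """One cue-target pairing inside a WM trial.

    ``pair_type`` is ``new``/``ltm`` for E1/E2 and ``new_new``/``old_match``/
    ``old_mismatch`` for E3/E4.  Colours (degrees on the wheel) are set for E4
    only; ``ltm_color`` for new-new and old-match pairs stays ``None`` until
    :func:`wmgate.simulate.assign_imaginary_ltm_colors` fills the imaginary
    baseline colours.
    """

    pair_type: str
    cue_id: int
    target_id: int
    target_color: float | None = None
    ltm_color: float | None = None
    ltm_lure_id: int | None = None  # original associate of an old-mismatch cue


@dataclass
class Trial:
    block: int
    index_in_block: int
    set_size: int
    wm_load: int
    ltm_load: int
    items: list[PairSpec] = field(default_factory=list)


@dataclass
class TrialSchedule:
    """A full experiment plan: learning material plus the WM trial sequence."""

    experiment_id: str
    trials: list[Trial]
    learning_pairs: pd.DataFrame  # columns: pair_id, cue_id, target_id[, color]
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per pair (serial position within its trial)."""
        rows = []
        for t in self.trials:
            for pos, p in enumerate(t.items):
                rows.append(
                    {
                        "experiment": self.experiment_id,
                        "block": t.block,
                        "trial": t.index_in_block,
                        "set_size": t.set_size,
                        "wm_load": t.wm_load,
                        "ltm_load": t.ltm_load,
                        "serial_position": pos,
                        "pair_type": p.pair_type,
                        "cue_id": p.cue_id,
                        "target_id": p.target_id,
                        "target_color_deg": p.target_color,
                        "ltm_color_deg": p.ltm_color,
                    }
                )
        return pd.DataFrame(rows)


class _IdFactory:
    """Opaque stimulus identifiers; new ids never repeat within an experiment."""

    def __init__(self, start: int = 0) -> None:
        self._next = start

    def take(self) -> int:
        self._next += 1
        return self._next - 1


def _learning_table(n_pairs: int, ids: _IdFactory, rng, with_colors: bool) -> pd.DataFrame:
    rec = {
        "pair_id": np.arange(n_pairs),
        "cue_id": [ids.take() for _ in range(n_pairs)],
        "target_id": [ids.take() for _ in range(n_pairs)],
    }
    if with_colors:
        rec["color"] = wrap_angle(rng.uniform(-180.0, 180.0, size=n_pairs))
    return pd.DataFrame(rec)


def _build_load_design(experiment_id: str, conditions, seed) -> TrialSchedule:
    """E1/E2: 15 blocks, one trial per (wm_load, ltm_load) cell per block."""
    rng = np.random.default_rng(seed)
    ids = _IdFactory()
    n_blocks, pairs_per_phase = 15, 90
    # Two learning phases ("mega-blocks") of 90 pairs each.
    phase1 = _learning_table(pairs_per_phase, ids, rng, with_colors=False)
    phase2 = _learning_table(pairs_per_phase, ids, rng, with_colors=False)
    phase1["phase"], phase2["phase"] = 1, 2
    learning = pd.concat([phase1, phase2], ignore_index=True)

    trials: list[Trial] = []
    pools = {1: list(phase1.index), 2: list(phase1.index.max() + 1 + phase2.index)}
    for ph in pools:
        rng.shuffle(pools[ph])
    half = (n_blocks + 1) // 2
    for block in range(n_blocks):
        phase = 1 if block < half else 2
        order = list(conditions)
        rng.shuffle(order)
        for idx, (wm, ltm) in enumerate(order):
            items: list[PairSpec] = []
            for _ in range(ltm):
                if not pools[phase]:  # pool exhausted: reuse learned pairs
                    pools[phase] = list(learning.index[learning["phase"] == phase])
                    rng.shuffle(pools[phase])
                row = learning.loc[pools[phase].pop()]
                items.append(PairSpec("ltm", int(row.cue_id), int(row.target_id)))
            for _ in range(wm):
                items.append(PairSpec("new", ids.take(), ids.take()))
            rng.shuffle(items)
            trials.append(Trial(block, idx, wm + ltm, wm, ltm, items))
    meta = {
        "n_blocks": n_blocks,
        "learning_set_size": pairs_per_phase,
        "n_learning_phases": 2,
        "conditions": tuple(conditions),
        "presentation_ms": {"learning": 4000, "learning_isi": 1000, "wm": 1000, "wm_isi": 500},
    }
    return TrialSchedule(experiment_id, trials, learning, meta)


def _block_compositions(rng) -> list[tuple[str, ...]]:
    comps = list(COMPOSITIONS[2]) + 3 * list(COMPOSITIONS[3]) + list(COMPOSITIONS[4])
    rng.shuffle(comps)
    return comps


def _build_composition_design(experiment_id: str, seed) -> TrialSchedule:
    """E3/E4: set-size x pair-type compositions, three per set size per block."""
    rng = np.random.default_rng(seed)
    ids = _IdFactory()
    if experiment_id == "E3":
        n_blocks, n_learned, with_colors = 3, 54, False
    else:
        n_blocks, n_learned, with_colors = 9, 120, True
    learning = _learning_table(n_learned, ids, rng, with_colors=with_colors)

    # Learned pairs are consumed without replacement; once the pool is empty the
    # earliest-used pairs are recycled (E4 reuses old objects in late blocks).
    pool = list(learning.index)
    rng.shuffle(pool)
    used: list[int] = []

    def next_old() -> pd.Series:
        nonlocal pool, used
        if not pool:
            pool, used = used, []
        i = pool.pop(0)
        used.append(i)
        return learning.loc[i]

    trials: list[Trial] = []
    for block in range(n_blocks):
        for idx, comp in enumerate(_block_compositions(rng)):
            items: list[PairSpec] = []
            for ptype in comp:
                if ptype == NEW_NEW:
                    p = PairSpec(ptype, ids.take(), ids.take())
                    if with_colors:
                        p.target_color = float(wrap_angle(rng.uniform(-180, 180)))
                elif ptype == OLD_MATCH:
                    row = next_old()
                    p = PairSpec(ptype, int(row.cue_id), int(row.target_id))
                    if with_colors:
                        p.target_color = float(row.color)
                        # true LTM colour equals the target colour here; the
                        # baseline imaginary colour is assigned later
                else:  # old_mismatch: learned cue, new associate
                    row = next_old()
                    p = PairSpec(ptype, int(row.cue_id), ids.take(),
                                 ltm_lure_id=int(row.target_id))
                    if with_colors:
                        p.target_color = float(wrap_angle(rng.uniform(-180, 180)))
                        p.ltm_color = float(row.color)
                rng_pos = p  # appended in composition order, shuffled below
                items.append(rng_pos)
            rng.shuffle(items)
            trials.append(Trial(block, idx, len(comp), len(comp), 0, items))
    meta = {
        "n_blocks": n_blocks,
        "learning_set_size": n_learned,
        "learning_group_size": 10 if experiment_id == "E4" else None,
        "compositions": COMPOSITIONS,
    }
    return TrialSchedule(experiment_id, trials, learning, meta)


def build_design(experiment_id: str, seed=None) -> TrialSchedule:
    """Build the trial schedule of one experiment, trial order randomized by seed."""
    if experiment_id == "E1":
        return _build_load_design("E1", E1_CONDITIONS, seed)
    if experiment_id == "E2":
        return _build_load_design("E2", E2_CONDITIONS, seed)
    if experiment_id in ("E3", "E4"):
        return _build_composition_design(experiment_id, seed)
    raise ValueError(f"unknown experiment id {experiment_id!r}")


def build_color_wheel() -> pd.DataFrame:
    """The 360-colour CIELAB wheel: centre L=70, a=20, b=38, radius 60.

    Entry ``i`` sits at hue angle ``wrap_angle(i)``; consecutive entries are one
    degree apart.
    """
    idx = np.arange(360)
    ang = wrap_angle(idx.astype(float))
    rad = np.deg2rad(ang)
    return pd.DataFrame(
        {
            "index": idx,
            "angle_deg": ang,
            "L": np.full(360, 70.0),
            "a": 20.0 + 60.0 * np.cos(rad),
            "b": 38.0 + 60.0 * np.sin(rad),
        }
    )
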