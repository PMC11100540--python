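"""Hierarchical von Mises mixture model for continuous colour reproduction.

Each response on the 360-degree wheel is modelled as a four-component
mixture:

* **memory** (``P_M``): a von Mises centred on the target colour,
* **swap** (``P_Swap``): a von Mises centred on one of the other items shown
  in the same trial (mass split evenly across them),
* **LTM intrusion** (``P_LTM``): a von Mises centred on the pre-learned
  colour of the cue object (an "imaginary", uniformly drawn colour for pairs
  that have no real pre-learned colour, serving as the baseline),
* **guessing** (``P_G``): the uniform density 1/360.

Component probabilities vary over set size and pair type through a SoftMax
link with the guessing logit fixed at zero; the concentration kappa varies
over set size through a log link and is shared by the three von Mises
components.  Participants deviate from the group on each component's
baseline logit and on log-kappa (normal deviations, non-centred).

Priors (overridable): Normal(0, 1) on group logits, Normal(log 10, 1) on
group log-kappa, half-Normal(0.5) on participant SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._kernels import mixture_core
from .circular import circ_diff, vm_density
from .sampler import PosteriorDraws, run_nuts, hdi

COMPONENTS = ("P_M", "P_Swap", "P_G", "P_LTM")
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class MixtureParams:
    """Mixture probabilities per (set_size, pair_type) cell and kappa per set size."""

    probs: dict  # (set_size, pair_type) -> array [P_M, P_Swap, P_G, P_LTM]
    kappa: dict  # set_size -> concentration

    def __post_init__(self):
        for cell, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (4,):
                raise ValueError(f"cell {cell}: need 4 probabilities")
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"cell {cell}: probabilities must be in [0,1] and sum to 1")
            self.probs[cell] = p
        for ss, k in self.kappa.items():
            if k < 0:
                raise ValueError(f"set size {ss}: kappa must be nonnegative")

    @classmethod
    def uniform_cells(cls, p, kappa, set_sizes=(2, 3, 4),
                      pair_types=("new_new", "old_match", "old_mismatch")):
        """Same probabilities in every cell (the reference recovery design)."""
        p = np.asarray(p, dtype=float)
        return cls(
            probs={(ss, pt): p.copy() for ss in set_sizes for pt in pair_types},
            kappa={ss: float(kappa) for ss in set_sizes},
        )


@dataclass
class ReproObservation:
    """One continuous-reproduction response with its trial context."""

    response: float
    target: float
    other_items: list
    ltm_color: float
    set_size: int
    pair_type: str

    def __post_init__(self):
        if len(self.other_items) != self.set_size - 1:
            raise ValueError("other_items must list the set_size - 1 non-target colours")


def mixture_density(obs: ReproObservation, params: MixtureParams) -> float:
    """Per-degree mixture density of one observation under ``params``."""
    cell = (obs.set_size, obs.pair_type)
    if cell not in params.probs:
        raise KeyError(f"cell {cell} missing from params")
    p_m, p_swap, p_g, p_ltm = params.probs[cell]
    kappa = params.kappa[obs.set_size]
    dens_m = vm_density(obs.response, obs.target, kappa)
    dens_s = float(np.mean([vm_density(obs.response, o, kappa) for o in obs.other_items]))
    dens_l = vm_density(obs.response, obs.ltm_color, kappa)
    return float(p_m * dens_m + p_swap * dens_s + p_g / 360.0 + p_ltm * dens_l)


def softmax_probs(logits_msl) -> np.ndarray:
    """Map free logits (memory, swap, LTM; guessing fixed at 0) to
    ``[P_M, P_Swap, P_G, P_LTM]``."""
    lm, ls, ll = np.asarray(logits_msl, dtype=float)
    z = np.array([lm, ls, 0.0, ll])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class MixturePriors:
    logit_sd: float = 1.0
    log_kappa_mean: float = float(np.log(10.0))
    log_kappa_sd: float = 1.0
    part_sd_scale: float = 0.5  # half-Normal scale on participant SDs


# --------------------------------------------------------------------------
# Data preparation
# --------------------------------------------------------------------------


@dataclass
class _MixtureData:
    cos_t: np.ndarray     # cos of response-target deviation (radians), (n,)
    cos_l: np.ndarray     # cos of response-LTM deviation, (n,)
    cos_o: np.ndarray     # cos of response-other deviations, (n, max_others)
    o_mask: np.ndarray    # validity mask for cos_o
    n_other: np.ndarray   # number of other items per observation
    cell_idx: np.ndarray
    ss_idx: np.ndarray
    part_idx: np.ndarray
    cells: list
    set_sizes: list
    participants: list


def _prepare(data: pd.DataFrame) -> _MixtureData:
    df = data.copy()
    required = {"participant", "block", "trial", "set_size", "pair_type",
                "target_color_deg", "ltm_color_deg", "response_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["ltm_color_deg"].isna().any():
        raise ValueError("every observation needs an ltm_color (assign imaginary colours first)")

    # other items = targets of the same trial's other pairs
    others = []
    for _, g in df.groupby(["participant", "block", "trial"], sort=False):
        cols = g["target_color_deg"].to_numpy()
        for i in range(len(g)):
            others.append(np.delete(cols, i))
    df["_others"] = others

    cells = sorted(df.groupby(["set_size", "pair_type"]).groups.keys())
    set_sizes = sorted(df["set_size"].unique())
    participants = sorted(df["participant"].unique())
    cmap = {c: i for i, c in enumerate(cells)}
    smap = {s: i for i, s in enumerate(set_sizes)}
    pmap = {p: i for i, p in enumerate(participants)}

    n = len(df)
    max_o = int(max(len(o) for o in df["_others"]))
    resp = df["response_deg"].to_numpy(dtype=float)
    cos_t = np.cos(np.deg2rad(circ_diff(resp, df["target_color_deg"].to_numpy(dtype=float))))
    cos_l = np.cos(np.deg2rad(circ_diff(resp, df["ltm_color_deg"].to_numpy(dtype=float))))
    cos_o = np.zeros((n, max_o))
    o_mask = np.zeros((n, max_o), dtype=bool)
    for i, (r, o) in enumerate(zip(resp, df["_others"])):
        m = len(o)
        if m:
            cos_o[i, :m] = np.cos(np.deg2rad(circ_diff(r, np.asarray(o, dtype=float))))
            o_mask[i, :m] = True
    return _MixtureData(
        cos_t=cos_t, cos_l=cos_l, cos_o=cos_o, o_mask=o_mask,
        n_other=o_mask.sum(axis=1).astype(float),
        cell_idx=df.apply(lambda r: cmap[(r["set_size"], r["pair_type"])], axis=1).to_numpy(),
        ss_idx=df["set_size"].map(smap).to_numpy(),
        part_idx=df["participant"].map(pmap).to_numpy(),
        cells=cells, set_sizes=set_sizes, participants=participants,
    )


# --------------------------------------------------------------------------
# Log posterior and gradient on the unconstrained vector
# --------------------------------------------------------------------------


class _MixtureModel:
    """Parameter layout:

    ``[L (C x 3), g (Z,), z_part (S x 4), log_sd (4,)]``

    where C = number of (set_size, pair_type) cells, Z = number of set sizes,
    S = number of participants; participant deviations are non-centred.
    """

    def __init__(self, md: _MixtureData, priors: MixturePriors):
        self.md = md
        self.priors = priors
        self.C = len(md.cells)
        self.Z = len(md.set_sizes)
        self.S = len(md.participants)
        self.dim = 3 * self.C + self.Z + 4 * self.S + 4

    def unpack(self, x):
        C, Z, S = self.C, self.Z, self.S
        L = x[: 3 * C].reshape(C, 3)
        g = x[3 * C: 3 * C + Z]
        z = x[3 * C + Z: 3 * C + Z + 4 * S].reshape(S, 4)
        log_sd = x[3 * C + Z + 4 * S:]
        return L, g, z, log_sd

    def init_point(self):
        x = np.zeros(self.dim)
        L, g, z, log_sd = self.unpack(x)
        g[:] = self.priors.log_kappa_mean
        log_sd[:] = np.log(0.2)
        return x

    def logp_grad(self, x):
        md, pri = self.md, self.priors
        L, g, z, log_sd = self.unpack(x)
        sd = np.exp(log_sd)
        n = md.cos_t.size

        # effective per-observation parameters
        dev = sd[None, :] * z                    # (S, 4)
        lM = L[md.cell_idx, 0] + dev[md.part_idx, 0]
        lS = L[md.cell_idx, 1] + dev[md.part_idx, 1]
        lL = L[md.cell_idx, 2] + dev[md.part_idx, 2]
        # kappa is constant within participant x set size: do the Bessel work
        # on those unique values only
        log_kappa_u = np.clip(
            g[None, :] + (sd[3] * z[:, 3])[:, None], -10.0, 12.0
        )                                         # (S, Z)
        kappa_u = np.exp(log_kappa_u)
        i0e_u = special.i0e(kappa_u)
        A_u = special.i1e(kappa_u) / i0e_u
        kappa = kappa_u[md.part_idx, md.ss_idx]
        A = A_u[md.part_idx, md.ss_idx]
        norm = (np.pi / 180.0) / (2.0 * np.pi * i0e_u[md.part_idx, md.ss_idx])

        loglik, dlogit, dlogkappa = mixture_core(
            md.cos_t, md.cos_l, md.cos_o, md.n_other, lM, lS, lL, kappa, A, norm
        )

        grad = np.zeros_like(x)
        gL, gg, gz, gls = self.unpack(grad)

        for k in range(3):
            gL[:, k] += np.bincount(md.cell_idx, weights=dlogit[:, k], minlength=self.C)
        gg += np.bincount(md.ss_idx, weights=dlogkappa, minlength=self.Z)

        per_part = np.empty((self.S, 4))
        for k in range(3):
            per_part[:, k] = np.bincount(md.part_idx, weights=dlogit[:, k], minlength=self.S)
        per_part[:, 3] = np.bincount(md.part_idx, weights=dlogkappa, minlength=self.S)
        gz += per_part * sd[None, :]
        gls += (per_part * z).sum(axis=0) * sd

        # priors
        logp = loglik
        logp += -0.5 * float((L ** 2).sum()) / pri.logit_sd ** 2
        gL -= L / pri.logit_sd ** 2
        logp += -0.5 * float(((g - pri.log_kappa_mean) ** 2).sum()) / pri.log_kappa_sd ** 2
        gg -= (g - pri.log_kappa_mean) / pri.log_kappa_sd ** 2
        logp += -0.5 * float((z ** 2).sum())
        gz -= z
        # half-Normal(scale) on sd, log-sd parameterization (+ Jacobian log sd)
        logp += float((-0.5 * sd ** 2 / pri.part_sd_scale ** 2 + log_sd).sum())
        gls += -sd ** 2 / pri.part_sd_scale ** 2 + 1.0
        return logp, grad


# --------------------------------------------------------------------------
# Fitting and summaries
# --------------------------------------------------------------------------


def fit_mixture_hierarchical(
    data: pd.DataFrame,
    priors: MixturePriors | None = None,
    *,
    n_chains: int = 4,
    n_warmup: int = 2000,
    n_samples: int = 3000,
    seed=None,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
):
    """Fit the hierarchical mixture model; returns (PosteriorDraws, ConvergenceReport).

    ``data`` follows the simulated-dataset CSV schema (one row per retrieval).
    Group-level probability draws per cell (``P_M[ss,pt]`` etc.) and
    ``kappa[ss]`` are derived from the group logits via SoftMax / exp.
    Non-convergence (any split-R-hat >= 1.01) is reported, never hidden.
    """
    priors = priors or MixturePriors()
    md = _prepare(data)
    model = _MixtureModel(md, priors)
    raw, info = run_nuts(
        model.logp_grad,
        model.init_point(),
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_samples=n_samples,
        seed=seed,
        target_accept=target_accept,
        max_treedepth=max_treedepth,
    )
    nc, nd, _ = raw.shape
    C, Z, S = model.C, model.Z, model.S
    L = raw[:, :, : 3 * C].reshape(nc, nd, C, 3)
    g = raw[:, :, 3 * C: 3 * C + Z]
    zpart = raw[:, :, 3 * C + Z: 3 * C + Z + 4 * S].reshape(nc, nd, S, 4)
    log_sd = raw[:, :, 3 * C + Z + 4 * S:]

    samples = {}
    # SoftMax of group logits -> group-level component probabilities per cell
    logits4 = np.concatenate(
        [L[..., :2], np.zeros((nc, nd, C, 1)), L[..., 2:]], axis=-1
    )
    mx = logits4.max(axis=-1, keepdims=True)
    ex = np.exp(logits4 - mx)
    probs = ex / ex.sum(axis=-1, keepdims=True)
    for ci, cell in enumerate(md.cells):
        ss, pt = cell
        for k, name in enumerate(COMPONENTS):
            samples[f"{name}[{ss},{pt}]"] = probs[:, :, ci, k]
        for k, name in enumerate(("logit_M", "logit_Swap", "logit_LTM")):
            samples[f"{name}[{ss},{pt}]"] = L[:, :, ci, k]
    for zi, ss in enumerate(md.set_sizes):
        samples[f"kappa[{ss}]"] = np.exp(g[:, :, zi])
        samples[f"log_kappa[{ss}]"] = g[:, :, zi]
    for k, name in enumerate(("M", "Swap", "LTM", "log_kappa")):
        samples[f"sd_{name}"] = np.exp(log_sd[:, :, k])
    samples["z_part"] = zpart

    meta = dict(info)
    meta.update({"cells": md.cells, "set_sizes": md.set_sizes,
                 "participants": md.participants})
    draws = PosteriorDraws(samples, meta)
    report = draws.convergence()
    return draws, report


def posterior_summary(draws, parameter: str | None = None, prob: float = 0.95) -> dict:
    """Posterior mean and highest-density interval of one parameter."""
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        if parameter not in draws.samples:
            raise KeyError(parameter)
        x = draws.flat(parameter)
    else:
        x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws")
    lo, hi = hdi(x, prob)
    return {"mean": float(np.mean(x)), "hdi": (lo, hi), "prob": prob}


def ltm_intrusion_test(draws: PosteriorDraws, set_size: int) -> np.ndarray:
    """Draws of P_LTM(old_mismatch) - P_LTM(new_new baseline) at one set size.

    Positive values indicate genuine LTM intrusions above the imaginary-colour
    baseline.
    """
    a = f"P_LTM[{set_size},old_mismatch]"
    b = f"P_LTM[{set_size},new_new]"
    for name in (a, b):
        if name not in draws.samples:
            raise KeyError(f"cell draws {name} not found")
    return draws.flat(a) - draws.flat(b)
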