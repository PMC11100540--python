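"""Aggregated binomial logistic hierarchical model for the 4AFC experiments.

Accuracy in each participant x design cell is the number of correct
retrievals ``k`` out of ``n``, modelled as Binomial with a logit-linked
linear predictor.  Fixed effects carry moderately informative Normal(0, 1)
priors (Normal(0, 1.5) on the intercept); every fixed-effect column also
gets a by-participant random slope (non-centred, independent across columns,
half-Student-t(3, 2.5) priors on the SDs).

Two fixed-effect codings are available:

* ``"cells"`` -- intercept plus sum-to-zero coding of the combined condition
  cell.  Always full rank, even for incomplete factorials such as the
  load-crossing design whose six cells do not fill the 4 x 2 grid.  All of
  the focal hypotheses are pairwise cell contrasts, which this coding
  represents exactly.
* ``"factorial"`` -- sum-to-zero main effects and their interaction, for
  complete factorial designs (set size x pair type).

Posterior cell means on the logit scale are attached to the draws as
``cell[<label>]``, so contrasts and Savage-Dickey tests can be formed
without re-deriving the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import special

from .sampler import PosteriorDraws, run_nuts

__all__ = [
    "GLMMSpec",
    "aggregate_cells",
    "fit_binomial_glmm",
    "contrast",
    "contrast_prior_sd",
    "pf_pi_contrasts",
]


@dataclass
class GLMMSpec:
    """Model specification: factors, coding, priors."""

    factors: tuple = ()
    coding: str = "cells"  # or "factorial"
    coef_sd: float = 1.0
    intercept_sd: float = 1.5
    re_scale: float = 2.5
    re_df: float = 3.0


def aggregate_cells(data: pd.DataFrame, factors) -> pd.DataFrame:
    """Collapse trial-level 4AFC responses to per-cell (k, n) counts.

    ``k`` counts ``target`` responses, ``n`` all retrievals in the
    participant x cell.  Cells a participant never saw are retained with
    ``n = 0`` (they contribute nothing to the likelihood).
    """
    factors = list(factors)
    if "response_category" not in data.columns:
        raise ValueError("response_category column required")
    df = data.copy()
    df["_correct"] = (df["response_category"] == "target").astype(int)
    grouped = df.groupby(["participant"] + factors, sort=True).agg(
        k=("_correct", "sum"), n=("_correct", "size")
    ).reset_index()
    if factors:
        # complete the participant x observed-cell grid with n = 0 rows
        cells = df.groupby(factors).size().reset_index()[factors]
        participants = sorted(df["participant"].unique())
        full = pd.DataFrame(
            [dict(zip(["participant"] + factors, (p, *tuple(c))))
             for p in participants for c in cells.itertuples(index=False)]
        )
        grouped = full.merge(grouped, on=["participant"] + factors, how="left")
        grouped[["k", "n"]] = grouped[["k", "n"]].fillna(0).astype(int)
    return grouped


def _sum_code(levels, value) -> np.ndarray:
    """Sum-to-zero (deviation) coding: len(levels) - 1 columns."""
    levels = list(levels)
    row = np.zeros(len(levels) - 1)
    i = levels.index(value)
    if i < len(levels) - 1:
        row[i] = 1.0
    else:
        row[:] = -1.0
    return row


def _design(cells, factors, coding):
    """Return (X_cells, column names); one row per design cell."""
    if not factors:
        return np.ones((1, 1)), ["intercept"], [()]
    labels = [tuple(c) for c in cells]
    if coding == "cells":
        rows = [np.concatenate([[1.0], _sum_code(labels, lab)]) for lab in labels]
        names = ["intercept"] + [f"cell_dev[{','.join(map(str, l))}]" for l in labels[:-1]]
        return np.asarray(rows), names, labels
    if coding == "factorial":
        level_sets = [sorted({lab[j] for lab in labels}) for j in range(len(factors))]
        expected = set(product(*level_sets))
        if set(labels) != expected:
            raise ValueError(
                "factorial coding needs a complete factorial; "
                f"missing cells: {sorted(expected - set(labels))}"
            )
        rows, names = [], None
        for lab in labels:
            mains = [_sum_code(level_sets[j], lab[j]) for j in range(len(factors))]
            inter = []
            if len(factors) == 2:
                inter = [np.outer(mains[0], mains[1]).ravel()]
            elif len(factors) > 2:
                raise ValueError("at most two factors supported")
            rows.append(np.concatenate([[1.0], *mains, *inter]))
        names = ["intercept"]
        for j, f in enumerate(factors):
            names += [f"{f}[{lv}]" for lv in level_sets[j][:-1]]
        if len(factors) == 2:
            names += [
                f"{factors[0]}[{a}]:{factors[1]}[{b}]"
                for a in level_sets[0][:-1] for b in level_sets[1][:-1]
            ]
        return np.asarray(rows), names, labels
    raise ValueError(f"unknown coding {coding!r}")


class _GLMM:
    """Layout: [beta (p), z (S x p) non-centred slopes, log_tau (p)]."""

    def __init__(self, X_rows, k, n, part_idx, n_part, spec):
        self.X, self.k, self.n = X_rows, k, n
        self.sidx, self.S = part_idx, n_part
        self.p = X_rows.shape[1]
        self.spec = spec
        self.prior_sd = np.full(self.p, spec.coef_sd)
        self.prior_sd[0] = spec.intercept_sd
        self.dim = self.p + self.S * self.p + self.p

    def unpack(self, x):
        p, S = self.p, self.S
        return x[:p], x[p: p + S * p].reshape(S, p), x[p + S * p:]

    def init_point(self):
        x = np.zeros(self.dim)
        x[-self.p:] = np.log(0.2)
        return x

    def logp_grad(self, x):
        beta, z, log_tau = self.unpack(x)
        tau = np.exp(log_tau)
        u = tau[None, :] * z                       # (S, p) random slopes
        eta = self.X @ beta + np.einsum("rj,rj->r", self.X, u[self.sidx])
        mu = special.expit(eta)
        # binomial loglik up to a constant
        loglik = float(np.sum(self.k * eta - self.n * np.logaddexp(0.0, eta)))
        G = self.k - self.n * mu                   # dloglik/deta

        grad = np.zeros_like(x)
        gb, gz, gt = self.unpack(grad)
        XG = self.X * G[:, None]
        gb += XG.sum(axis=0)
        per_part = np.zeros((self.S, self.p))
        np.add.at(per_part, self.sidx, XG)
        gz += per_part * tau[None, :]
        gt += (per_part * z).sum(axis=0) * tau

        logp = loglik
        logp += float(np.sum(-0.5 * beta ** 2 / self.prior_sd ** 2))
        gb -= beta / self.prior_sd ** 2
        logp += float(np.sum(-0.5 * z ** 2))
        gz -= z
        # half-Student-t(df, scale) on tau, log parameterization (+ Jacobian)
        nu, s = self.spec.re_df, self.spec.re_scale
        logp += float(np.sum(-(nu + 1) / 2 * np.log1p(tau ** 2 / (nu * s ** 2)) + log_tau))
        gt += -(nu + 1) * tau ** 2 / (nu * s ** 2 + tau ** 2) + 1.0
        return logp, grad


def fit_binomial_glmm(
    cells: pd.DataFrame,
    spec: GLMMSpec,
    *,
    n_chains: int = 4,
    n_warmup: int = 2000,
    n_samples: int = 3000,
    seed=None,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
):
    """Fit the hierarchical logistic model to aggregated counts.

    Returns (PosteriorDraws, ConvergenceReport).  Cell means on the logit
    scale are exposed as ``cell[<label>]`` draws; the prior SD of each design
    column is kept in the metadata so contrast priors are available
    analytically.
    """
    factors = list(spec.factors)
    observed = cells[cells["n"] > 0].reset_index(drop=True)
    if factors:
        cell_values = (
            cells.groupby(factors).size().reset_index()[factors]
            .itertuples(index=False, name=None)
        )
        cell_values = sorted(set(cell_values))
    else:
        cell_values = [()]
    Xc, colnames, labels = _design(cell_values, factors, spec.coding)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient on the supplied cells")
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    if factors:
        row_cells = [tuple(r) for r in observed[factors].itertuples(index=False, name=None)]
        rows = np.array([lab_idx[c] for c in row_cells])
    else:
        rows = np.zeros(len(observed), dtype=int)
    X = Xc[rows]
    participants = sorted(observed["participant"].unique())
    pmap = {p: i for i, p in enumerate(participants)}
    sidx = observed["participant"].map(pmap).to_numpy()

    model = _GLMM(
        X,
        observed["k"].to_numpy(dtype=float),
        observed["n"].to_numpy(dtype=float),
        sidx,
        len(participants),
        spec,
    )
    raw, info = run_nuts(
        model.logp_grad, model.init_point(),
        n_chains=n_chains, n_warmup=n_warmup, n_samples=n_samples,
        seed=seed, target_accept=target_accept, max_treedepth=max_treedepth,
    )
    nc, nd, _ = raw.shape
    p, S = model.p, model.S
    beta = raw[:, :, :p]
    zmat = raw[:, :, p: p + S * p].reshape(nc, nd, S, p)
    tau = np.exp(raw[:, :, p + S * p:])

    samples = {}
    for j, name in enumerate(colnames):
        samples[f"b[{name}]"] = beta[:, :, j]
        samples[f"tau[{name}]"] = tau[:, :, j]
    samples["z_part"] = zmat
    cell_rows = {}
    for lab in labels:
        key = ",".join(map(str, lab)) if lab else "overall"
        row = Xc[lab_idx[lab]]
        samples[f"cell[{key}]"] = np.einsum("cdj,j->cd", beta, row)
        cell_rows[key] = row
    meta = dict(info)
    meta.update({
        "columns": colnames,
        "cell_rows": cell_rows,
        "prior_sd": model.prior_sd,
        "factors": tuple(factors),
    })
    draws = PosteriorDraws(samples, meta)
    return draws, draws.convergence()


def _cell_key(label) -> str:
    if isinstance(label, str):
        return label
    if isinstance(label, (tuple, list)):
        return ",".join(map(str, label))
    return str(label)


def contrast(draws: PosteriorDraws, definition: dict) -> np.ndarray:
    """Draws of a linear combination of cell means (logit scale).

    ``definition`` maps cell labels (tuples or their string keys) to weights,
    e.g. ``{(2, 'old_match'): 1, (2, 'new_new'): -1}``.
    """
    out = None
    for label, w in definition.items():
        name = f"cell[{_cell_key(label)}]"
        if name not in draws.samples:
            raise KeyError(f"unknown cell {label!r}")
        term = w * draws.flat(name)
        out = term if out is None else out + term
    return out


def contrast_prior_sd(draws: PosteriorDraws, definition: dict) -> float:
    """Prior SD of the same contrast, implied by the coefficient priors."""
    cell_rows = draws.meta["cell_rows"]
    prior_sd = np.asarray(draws.meta["prior_sd"], dtype=float)
    c = None
    for label, w in definition.items():
        row = np.asarray(cell_rows[_cell_key(label)], dtype=float) * w
        c = row if c is None else c + row
    return float(np.sqrt(np.sum((c * prior_sd) ** 2)))


def pf_pi_contrasts(draws: PosteriorDraws, set_size) -> dict:
    """Proactive facilitation / interference contrasts at one set size.

    facilitation = old_match - new_new; interference = old_mismatch - new_new,
    both on the logit scale (negative interference values mean a performance
    cost for mismatch pairs).
    """
    defs = {
        "facilitation": {(set_size, "old_match"): 1.0, (set_size, "new_new"): -1.0},
        "interference": {(set_size, "old_mismatch"): 1.0, (set_size, "new_new"): -1.0},
    }
    out = {}
    for name, d in defs.items():
        try:
            out[name] = contrast(draws, d)
        except KeyError as e:
            raise KeyError(f"set size {set_size} absent from the fitted design") from e
    return out
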