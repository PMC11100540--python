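"""Gradient-based MCMC: a compact No-U-Turn sampler with adaptation.

The hierarchical models in this package expose a log posterior and its
analytic gradient on an unconstrained parameter vector; this module draws
from them with multinomial NUTS (dynamic trajectory lengths with a U-turn
termination criterion), dual-averaging step-size adaptation towards a target
acceptance statistic, and a diagonal mass matrix estimated during warmup in
doubling windows.  Convergence is assessed with the split-R-hat statistic
(via arviz); a fit passes when every parameter's R-hat is below 1.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PosteriorDraws", "ConvergenceReport", "run_nuts", "hdi"]

_DIVERGENCE = 1000.0  # energy error treated as a divergent transition


@dataclass
class ConvergenceReport:
    """Per-parameter split-R-hat and the R-hat < threshold pass flag."""

    rhat: dict
    threshold: float = 1.01
    n_divergent: int = 0

    @property
    def passed(self) -> bool:
        vals = np.asarray(list(self.rhat.values()), dtype=float)
        return bool(vals.size and np.all(np.isfinite(vals)) and np.all(vals < self.threshold))

    def max_rhat(self) -> float:
        return float(max(self.rhat.values()))


class PosteriorDraws:
    """Labeled MCMC draws: parameter name -> array of shape (chain, draw, ...)."""

    def __init__(self, samples: dict, meta: dict | None = None):
        self.samples = dict(samples)
        self.meta = dict(meta or {})
        first = next(iter(self.samples.values()))
        self.n_chains, self.n_draws = first.shape[0], first.shape[1]
        for name, arr in self.samples.items():
            if arr.shape[:2] != (self.n_chains, self.n_draws):
                raise ValueError(f"inconsistent chain/draw shape for {name!r}")

    def names(self):
        return list(self.samples)

    def get(self, name: str) -> np.ndarray:
        return self.samples[name]

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (chain*draw, ...)."""
        arr = self.samples[name]
        return arr.reshape(-1, *arr.shape[2:])

    def add(self, name: str, arr: np.ndarray) -> None:
        if arr.shape[:2] != (self.n_chains, self.n_draws):
            raise ValueError("shape mismatch")
        self.samples[name] = arr

    def convergence(self, threshold: float = 1.01) -> ConvergenceReport:
        import arviz as az

        rhat = {}
        for name, arr in self.samples.items():
            r = az.rhat(az.convert_to_dataset({name: arr}))[name].values
            rhat[name] = float(np.max(r))
        return ConvergenceReport(rhat, threshold, self.meta.get("n_divergent", 0))


def hdi(draws, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


# --------------------------------------------------------------------------
# NUTS internals
# --------------------------------------------------------------------------


@dataclass
class _Tree:
    x_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    lp_minus: float
    x_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    lp_plus: float
    x_prop: np.ndarray
    lp_prop: float
    logw: float
    sum_accept: float
    n_steps: int
    divergent: bool
    turning: bool


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    x_new = x + eps * inv_mass * p_half
    lp, grad_new = logp_grad(x_new)
    p_new = p_half + 0.5 * eps * grad_new
    return x_new, p_new, grad_new, lp


def _kinetic(p, inv_mass) -> float:
    return 0.5 * float(np.dot(p, inv_mass * p))


def _uturn(x_plus, x_minus, p_plus, p_minus, inv_mass) -> bool:
    dq = x_plus - x_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _build_tree(logp_grad, x, p, grad, lp, depth, direction, eps, H0, inv_mass, rng):
    if depth == 0:
        x1, p1, g1, lp1 = _leapfrog(logp_grad, x, p, grad, direction * eps, inv_mass)
        if np.isfinite(lp1):
            H = lp1 - _kinetic(p1, inv_mass)
        else:
            H = -np.inf
        logw = H - H0
        divergent = not np.isfinite(H) or (H0 - H) > _DIVERGENCE
        accept = 0.0 if not np.isfinite(logw) else float(min(1.0, np.exp(min(0.0, logw))))
        return _Tree(x1, p1, g1, lp1, x1, p1, g1, lp1, x1, lp1,
                     -np.inf if divergent else logw, accept, 1, divergent, False)

    inner = _build_tree(logp_grad, x, p, grad, lp, depth - 1, direction, eps, H0, inv_mass, rng)
    if inner.divergent or inner.turning:
        return inner
    if direction > 0:
        seed_x, seed_p, seed_g, seed_lp = inner.x_plus, inner.p_plus, inner.g_plus, inner.lp_plus
    else:
        seed_x, seed_p, seed_g, seed_lp = inner.x_minus, inner.p_minus, inner.g_minus, inner.lp_minus
    outer = _build_tree(logp_grad, seed_x, seed_p, seed_g, seed_lp, depth - 1,
                        direction, eps, H0, inv_mass, rng)

    sum_accept = inner.sum_accept + outer.sum_accept
    n_steps = inner.n_steps + outer.n_steps
    if outer.divergent or outer.turning:
        inner.sum_accept, inner.n_steps = sum_accept, n_steps
        inner.divergent, inner.turning = outer.divergent, outer.turning
        return inner

    logw = np.logaddexp(inner.logw, outer.logw)
    # multinomial sampling within the subtree
    if np.log(rng.uniform()) < outer.logw - logw:
        x_prop, lp_prop = outer.x_prop, outer.lp_prop
    else:
        x_prop, lp_prop = inner.x_prop, inner.lp_prop
    if direction > 0:
        xm, pm, gm, lpm = inner.x_minus, inner.p_minus, inner.g_minus, inner.lp_minus
        xp, pp, gp, lpp = outer.x_plus, outer.p_plus, outer.g_plus, outer.lp_plus
    else:
        xm, pm, gm, lpm = outer.x_minus, outer.p_minus, outer.g_minus, outer.lp_minus
        xp, pp, gp, lpp = inner.x_plus, inner.p_plus, inner.g_plus, inner.lp_plus
    turning = _uturn(xp, xm, pp, pm, inv_mass)
    return _Tree(xm, pm, gm, lpm, xp, pp, gp, lpp, x_prop, lp_prop,
                 logw, sum_accept, n_steps, False, turning)


def _nuts_step(logp_grad, x, lp, grad, eps, inv_mass, max_treedepth, rng):
    mass_sd = 1.0 / np.sqrt(inv_mass)
    p0 = rng.standard_normal(x.size) * mass_sd
    H0 = lp - _kinetic(p0, inv_mass)
    xm = xp = x
    pm = pp = p0
    gm = gp = grad
    lpm = lpp = lp
    logw_total = 0.0
    x_prop, lp_prop, g_prop = x, lp, grad
    sum_accept, n_steps = 0.0, 0
    divergent = False
    for depth in range(max_treedepth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction > 0:
            tree = _build_tree(logp_grad, xp, pp, gp, lpp, depth, 1, eps, H0, inv_mass, rng)
        else:
            tree = _build_tree(logp_grad, xm, pm, gm, lpm, depth, -1, eps, H0, inv_mass, rng)
        sum_accept += tree.sum_accept
        n_steps += tree.n_steps
        if tree.divergent:
            divergent = True
            break
        if tree.turning:
            break
        # biased progressive sampling favouring the new subtree
        if np.log(rng.uniform()) < tree.logw - logw_total:
            x_prop, lp_prop = tree.x_prop, tree.lp_prop
            g_prop = None
        logw_total = np.logaddexp(logw_total, tree.logw)
        if direction > 0:
            xp, pp, gp, lpp = tree.x_plus, tree.p_plus, tree.g_plus, tree.lp_plus
        else:
            xm, pm, gm, lpm = tree.x_minus, tree.p_minus, tree.g_minus, tree.lp_minus
        if _uturn(xp, xm, pp, pm, inv_mass):
            break
    if g_prop is None:
        _, g_prop = logp_grad(x_prop)
    accept_stat = sum_accept / max(n_steps, 1)
    return x_prop, lp_prop, g_prop, accept_stat, divergent


def _find_initial_eps(logp_grad, x, lp, grad, inv_mass, rng) -> float:
    eps = 1.0
    mass_sd = 1.0 / np.sqrt(inv_mass)
    p0 = rng.standard_normal(x.size) * mass_sd
    H0 = lp - _kinetic(p0, inv_mass)
    _, p1, _, lp1 = _leapfrog(logp_grad, x, p0, grad, eps, inv_mass)
    H1 = (lp1 - _kinetic(p1, inv_mass)) if np.isfinite(lp1) else -np.inf
    direction = 1 if (H1 - H0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, _, lp1 = _leapfrog(logp_grad, x, p0, grad, eps, inv_mass)
        H1 = (lp1 - _kinetic(p1, inv_mass)) if np.isfinite(lp1) else -np.inf
        crossed = (H1 - H0) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return float(eps)


def _adapt_windows(n_warmup: int):
    """Stan-style warmup schedule: fast start, doubling slow windows, fast end."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init = max(1, int(round(0.15 * n_warmup)))
    term = max(1, int(round(0.10 * n_warmup)))
    slow_total = n_warmup - init - term
    windows = []
    w = min(25, slow_total) if slow_total > 0 else 0
    remaining = slow_total
    while remaining > 0:
        cur = min(w, remaining)
        if remaining - cur < w and remaining - cur > 0:
            cur = remaining  # fold the tail into the last window
        windows.append(cur)
        remaining -= cur
        w *= 2
    return init, windows, term


def _run_chain(logp_grad, x0, n_warmup, n_samples, rng, target_accept, max_treedepth):
    x = np.array(x0, dtype=float)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")
    dim = x.size
    inv_mass = np.ones(dim)

    eps = _find_initial_eps(logp_grad, x, lp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    init, windows, term = _adapt_windows(n_warmup)
    boundaries = []
    pos = init
    for w in windows:
        pos += w
        boundaries.append(pos)
    window_buf = []
    n_div_warm = 0
    n_divergent = 0

    for it in range(n_warmup):
        x, lp, grad, accept, div = _nuts_step(
            logp_grad, x, lp, grad, eps, inv_mass, max_treedepth, rng
        )
        n_div_warm += div
        adapt_count += 1
        frac = 1.0 / (adapt_count + t0)
        h_bar = (1 - frac) * h_bar + frac * (target_accept - accept)
        log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
        eta = adapt_count ** (-kappa)
        log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
        eps = float(np.exp(log_eps))
        if it + 1 > init and boundaries:
            window_buf.append(x.copy())
            if it + 1 == boundaries[0]:
                boundaries.pop(0)
                draws = np.asarray(window_buf)
                n = draws.shape[0]
                if n >= 5:
                    var = np.var(draws, axis=0, ddof=1)
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    inv_mass = np.maximum(inv_mass, 1e-10)
                window_buf = []
                # restart step-size adaptation around the current value
                eps = _find_initial_eps(logp_grad, x, lp, grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0

    eps = float(np.exp(log_eps_bar)) if n_warmup else eps
    out = np.empty((n_samples, dim))
    for it in range(n_samples):
        x, lp, grad, _, div = _nuts_step(
            logp_grad, x, lp, grad, eps, inv_mass, max_treedepth, rng
        )
        n_divergent += div
        out[it] = x
    return out, {"step_size": eps, "inv_mass": inv_mass,
                 "n_divergent": n_divergent, "n_divergent_warmup": n_div_warm}


def run_nuts(
    logp_grad,
    x0,
    *,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_samples: int = 1000,
    seed=None,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    init_jitter: float = 0.5,
):
    """Sample with NUTS; returns ``(draws, info)`` with draws of shape
    (n_chains, n_samples, dim).

    ``x0`` may be a single vector (jittered per chain) or one vector per chain.
    """
    x0 = np.asarray(x0, dtype=float)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    draws = []
    n_divergent = 0
    infos = []
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if x0.ndim == 2:
            start = x0[c]
        else:
            start = x0 + init_jitter * rng.standard_normal(x0.size)
        chain, info = _run_chain(
            logp_grad, start, n_warmup, n_samples, rng, target_accept, max_treedepth
        )
        draws.append(chain)
        infos.append(info)
        n_divergent += info["n_divergent"]
    return np.asarray(draws), {
        "n_divergent": n_divergent,
        "chains": infos,
        "n_chains": n_chains,
        "n_warmup": n_warmup,
        "n_retained": n_samples,
    }
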