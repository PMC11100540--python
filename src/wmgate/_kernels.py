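"""Fused numerical kernel for the mixture-model likelihood.

The per-observation mixture density and its partial derivatives are the hot
path of the hierarchical fit; this module provides a numba-compiled loop
with a vectorized numpy fallback (same signature, same results to floating-
point precision) so the package works even where numba is unavailable.
"""

from __future__ import annotations

import numpy as np

_TINY = 1e-300
_GUESS = 1.0 / 360.0


def _mixture_core_numpy(cos_t, cos_l, cos_o, n_other, lM, lS, lL, kappa, A, norm):
    n = cos_t.size
    logits = np.stack([lM, lS, np.zeros(n), lL], axis=1)
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=1, keepdims=True)

    phi_t = np.exp(kappa * (cos_t - 1.0)) * norm
    phi_l = np.exp(kappa * (cos_l - 1.0)) * norm
    mask = np.arange(cos_o.shape[1])[None, :] < n_other[:, None]
    e_o = np.where(mask, np.exp(kappa[:, None] * (cos_o - 1.0)), 0.0)
    phi_s = (e_o.sum(axis=1) / n_other) * norm

    comp = np.stack([phi_t, phi_s, np.full(n, _GUESS), phi_l], axis=1)
    f = np.maximum((p * comp).sum(axis=1), _TINY)
    loglik = float(np.log(f).sum())
    dlogit = p[:, [0, 1, 3]] * (comp[:, [0, 1, 3]] - f[:, None]) / f[:, None]
    dphi_t = phi_t * (cos_t - A)
    dphi_l = phi_l * (cos_l - A)
    dphi_s = ((e_o * (cos_o - A[:, None])).sum(axis=1) / n_other) * norm
    dlogkappa = (p[:, 0] * dphi_t + p[:, 1] * dphi_s + p[:, 3] * dphi_l) / f * kappa
    return loglik, dlogit, dlogkappa


def _mixture_core_loop(cos_t, cos_l, cos_o, n_other, lM, lS, lL, kappa, A, norm):
    n = cos_t.size
    dlogit = np.empty((n, 3))
    dlogkappa = np.empty(n)
    loglik = 0.0
    for i in range(n):
        m = max(lM[i], lS[i], 0.0, lL[i])
        eM = np.exp(lM[i] - m)
        eS = np.exp(lS[i] - m)
        eG = np.exp(-m)
        eL = np.exp(lL[i] - m)
        tot = eM + eS + eG + eL
        pM, pS, pG, pL = eM / tot, eS / tot, eG / tot, eL / tot

        k = kappa[i]
        phi_t = np.exp(k * (cos_t[i] - 1.0)) * norm[i]
        phi_l = np.exp(k * (cos_l[i] - 1.0)) * norm[i]
        s = 0.0
        ds = 0.0
        mo = int(n_other[i])
        for j in range(mo):
            ej = np.exp(k * (cos_o[i, j] - 1.0))
            s += ej
            ds += ej * (cos_o[i, j] - A[i])
        phi_s = s / mo * norm[i]
        dphi_s = ds / mo * norm[i]

        f = pM * phi_t + pS * phi_s + pG * _GUESS + pL * phi_l
        if f < _TINY:
            f = _TINY
        loglik += np.log(f)
        dlogit[i, 0] = pM * (phi_t - f) / f
        dlogit[i, 1] = pS * (phi_s - f) / f
        dlogit[i, 2] = pL * (phi_l - f) / f
        dphi_t = phi_t * (cos_t[i] - A[i])
        dphi_l = phi_l * (cos_l[i] - A[i])
        dlogkappa[i] = (pM * dphi_t + pS * dphi_s + pL * dphi_l) / f * k
    return loglik, dlogit, dlogkappa


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    mixture_core = njit(cache=False, fastmath=False)(_mixture_core_loop)
except Exception:  # pragma: no cover
    mixture_core = _mixture_core_numpy
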