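"""Angle arithmetic and von Mises machinery on the 360-degree colour wheel.

All public angles are degrees on the half-open interval ``[-180, 180)``,
matching the response wheel of continuous colour reproduction (360 discrete
colours, one per degree).  Radians appear only inside the von Mises math.
"""

from __future__ import annotations

import numpy as np
from scipy import special

DEG_PER_RAD = 180.0 / np.pi

__all__ = [
    "wrap_angle",
    "circ_diff",
    "abs_circ_error",
    "vm_density",
    "vm_logpdf",
    "vm_sample",
]


def wrap_angle(x):
    """Wrap degrees onto ``[-180, 180)``.

    Idempotent; ``wrap_angle(180) == -180`` by the half-open convention.
    Accepts scalars or arrays; rejects non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.mod(x + 180.0, 360.0) - 180.0
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def circ_diff(a, b):
    """Signed shortest-arc difference ``a - b`` in degrees on ``[-180, 180)``."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def abs_circ_error(response, target):
    """Absolute circular deviation in degrees, on ``[0, 180]``.

    The mean of this quantity over uniform responses is 90 degrees -- the
    chance level of continuous reproduction.
    """
    return np.abs(circ_diff(response, target))


def _check_kappa(kappa) -> np.ndarray:
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    return kappa


def vm_density(x, mu, kappa, scale: str = "degree"):
    """Von Mises density at angle ``x`` (degrees) for centre ``mu``, concentration ``kappa``.

    ``scale="degree"`` integrates to 1 over 360 degrees (the likelihood scale
    used by the mixture model: kappa=0 gives the guessing density 1/360);
    ``scale="radian"`` is the textbook normalisation (factor 180/pi larger).
    Uses exponentially scaled Bessel functions so large kappa is stable.
    """
    kappa = _check_kappa(kappa)
    delta = np.deg2rad(circ_diff(x, mu))
    # exp(k cos d) / (2 pi I0(k)) = exp(k (cos d - 1)) / (2 pi I0e(k))
    dens = np.exp(kappa * (np.cos(delta) - 1.0)) / (2.0 * np.pi * special.i0e(kappa))
    if scale == "degree":
        dens = dens * (np.pi / 180.0)
    elif scale != "radian":
        raise ValueError(f"unknown scale {scale!r}")
    if np.ndim(dens) == 0:
        return float(dens)
    return dens


def vm_logpdf(x, mu, kappa, scale: str = "degree"):
    """Log of :func:`vm_density`; same conventions."""
    kappa = _check_kappa(kappa)
    delta = np.deg2rad(circ_diff(x, mu))
    logp = kappa * (np.cos(delta) - 1.0) - np.log(2.0 * np.pi) - np.log(special.i0e(kappa))
    if scale == "degree":
        logp = logp + np.log(np.pi / 180.0)
    elif scale != "radian":
        raise ValueError(f"unknown scale {scale!r}")
    return logp


def vm_sample(mu, kappa, n: int, rng) -> np.ndarray:
    """Draw ``n`` von Mises angles (degrees on [-180, 180)).

    ``rng`` is a ``numpy.random.Generator`` or a seed.  ``kappa=0`` yields the
    uniform circular distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_kappa(kappa)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = rng.vonmises(np.deg2rad(float(mu)), float(kappa), size=n)
    return wrap_angle(np.rad2deg(draws))
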