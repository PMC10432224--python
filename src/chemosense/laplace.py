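"""Numerical inversion of Laplace transforms.

Two independent schemes are provided for transforms that are analytic off
the negative real axis and whose originals are smooth and non-oscillatory
(the spherical-Bessel flux transforms evaluated here are of this kind):

* :func:`talbot` — the fixed-Talbot deformed-contour method of Abate &
  Valko; the primary scheme, accurate to ~1e-9 relative in double
  precision even where the original is exponentially small.
* :func:`euler` — Euler (binomial) acceleration of the Bromwich series
  (Abate & Whitt); an independent cross-check from a different algorithm
  family, accurate to ~1e-8.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.special import comb

__all__ = ["talbot", "euler", "LaplaceInversionError"]


class LaplaceInversionError(RuntimeError):
    """Raised when an inversion result fails its internal sanity checks."""


def talbot_nodes(t: float, n: int = 48):
    """Fixed-Talbot contour nodes and weights for time ``t``.

    Returns ``(s, w, scale)`` such that ``f(t) = scale * sum Re(w * F(s))``.
    """
    if t <= 0:
        raise ValueError(f"t must be positive, got {t!r}")
    r = 2.0 * n / (5.0 * t)
    theta = np.pi * np.arange(1, n) / n
    cot = 1.0 / np.tan(theta)
    s = np.concatenate([[r + 0j], r * theta * (cot + 1j)])
    sigma = theta + (theta * cot - 1.0) * cot
    w = np.concatenate([[0.5], 1.0 + 1j * sigma]) * np.exp(t * s)
    return s, w, r / n


def talbot(F: Callable[[np.ndarray], np.ndarray], t: float, n: int = 48) -> float:
    """Invert the transform ``F(s)`` at time ``t`` on a fixed Talbot contour.

    Parameters
    ----------
    F : callable
        Vectorized transform; receives a complex ndarray of contour nodes.
    t : float
        Evaluation time, ``t > 0``.
    n : int
        Number of contour nodes.  48 nodes put the method at the double
        precision round-off floor for smooth transforms.
    """
    s, w, scale = talbot_nodes(t, n)
    out = scale * float(np.sum(np.real(w * np.asarray(F(s)))))
    if not np.isfinite(out):
        raise LaplaceInversionError(
            f"Talbot inversion produced a non-finite value at t={t} (n={n})"
        )
    return out


@lru_cache(maxsize=8)
def euler_nodes_template(M: int):
    """Euler-acceleration node template: ``(beta, eta)`` with nodes beta/t."""
    xi = np.zeros(2 * M + 1)
    xi[0] = 0.5
    xi[1 : M + 1] = 1.0
    xi[2 * M] = 2.0 ** (-M)
    for k in range(1, M):
        xi[2 * M - k] = xi[2 * M - k + 1] + 2.0 ** (-M) * comb(M, k)
    k = np.arange(2 * M + 1)
    beta = M * np.log(10.0) / 3.0 + 1j * np.pi * k
    eta = (-1.0) ** k * xi * 10.0 ** (M / 3.0)
    return beta, eta


def euler(F: Callable[[np.ndarray], np.ndarray], t: float, M: int = 30) -> float:
    """Invert ``F(s)`` at ``t`` by Euler summation of the Bromwich series.

    ``M`` controls the truncation/round-off trade-off; errors scale roughly
    like ``10^(-0.6 M) + 10^(M/3) * eps``, so M around 24-30 is near the
    double-precision optimum.
    """
    if t <= 0:
        raise ValueError(f"t must be positive, got {t!r}")
    beta, eta = euler_nodes_template(M)
    vals = np.asarray(F(beta / t))
    out = float(np.sum(eta * np.real(vals)) / t)
    if not np.isfinite(out):
        raise LaplaceInversionError(
            f"Euler inversion produced a non-finite value at t={t} (M={M})"
        )
    return out
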