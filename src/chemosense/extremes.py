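"""Extreme-value statistics of the earliest receptor binding events.

Among ``M`` particles released at distance ``R``, the k-th fastest binding
time ``t_k`` obeys, for large M, a Gumbel-type limit

    (t_k - b_M) / a_M  ->  X_k,   P[X_k = x] = exp(k x - e^x) / (k-1)!,

where the centering ``b_M`` and scale ``a_M`` follow from the short-time
single-particle survival probability S(t) via

    S(b_M) = 1 - 1/M,      a_M = -1 / (M S'(b_M)).

The binding *location* of the k-th event is exponentially concentrated at
the source pole: ``1 - z_k ~ Exp(mean lambda_k)`` with
``lambda_k = (2 D / R)(b_M + a_M log k)``.  Averaging the first K
elevations gives a hypoexponential error law whose mean grows slowly with
K while its variance drops — the accuracy/precision trade-off this package
quantifies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq
from scipy.special import gammaln

from .homogenized import HomogenizedParams

__all__ = [
    "GumbelScaling",
    "ErrorLaw",
    "survival_short_time",
    "survival_prefactor_h",
    "nu_log_factor",
    "gumbel_scaling",
    "kth_arrival_density",
    "kth_arrival_mode",
    "sample_kth_arrival",
    "lambda_k",
    "lambda1_asymptotic",
    "hypoexponential_pdf",
    "hypoexponential_cdf",
    "sample_hypoexponential",
    "error_moments",
    "optimal_k",
]


# --------------------------------------------------------------------------
# Short-time survival
# --------------------------------------------------------------------------

def survival_prefactor_h(t, params: HomogenizedParams):
    """Prefactor h(t) of the short-time survival approximation.

        h(t) = sqrt(D/pi) * 4 kappa t^(3/2)
               / (R (R-1) ((R-1) + 2 (kappa + D) t))

    so that ``1 - S(t) ~ h(t) exp(-(R-1)^2 / (4 D t))`` as t -> 0+.
    """
    t_arr = np.asarray(t, dtype=float)
    R, D, kap = params.R, params.D, params.kappa
    out = (
        np.sqrt(D / np.pi)
        * 4.0 * kap * t_arr ** 1.5
        / (R * (R - 1.0) * ((R - 1.0) + 2.0 * (kap + D) * t_arr))
    )
    return out if out.ndim else float(out)


def survival_short_time(t, params: HomogenizedParams):
    """Single-particle survival probability, short-time approximation.

    ``S(t) = 1 - h(t) exp(-(R-1)^2/(4 D t))``: the probability that a
    particle released at distance R has not yet bound by time t.  Valid as
    ``t -> 0+``; a warning (not an error) is emitted if the approximation
    leaves [0, 1], which signals evaluation outside its asymptotic window.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0.0):
        raise ValueError("t must be positive")
    R, D = params.R, params.D
    S = 1.0 - survival_prefactor_h(t_arr, params) * np.exp(
        -((R - 1.0) ** 2) / (4.0 * D * t_arr)
    )
    if np.any(S < 0.0) or np.any(S > 1.0):
        warnings.warn(
            "short-time survival approximation left [0, 1]; requested t is "
            "outside its asymptotic validity window",
            RuntimeWarning,
            stacklevel=2,
        )
    return S if S.ndim else float(S)


def nu_log_factor(M: int, params: HomogenizedParams) -> float:
    """Asymptotic log factor nu in the leading-order centering time.

        nu = ln[(2/(27 pi))^(1/3) (M kappa (R-1) / (R D))^(2/3)]

    so that ``b_M ~ (R-1)^2 / (6 D nu)`` for M -> infinity.
    """
    R, D, kap = params.R, params.D, params.kappa
    return float(
        np.log(2.0 / (27.0 * np.pi)) / 3.0
        + (2.0 / 3.0) * np.log(M * kap * (R - 1.0) / (R * D))
    )


# --------------------------------------------------------------------------
# Gumbel centering and scale
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GumbelScaling:
    """Centering/scale pair (b_M, a_M) for the fastest-arrival limit law.

    ``method`` records whether the pair came from the numeric root solve
    of S(b_M) = 1 - 1/M ("numeric") or from the leading-order asymptotics
    in ``nu`` ("asymptotic").
    """

    M: int
    bM: float
    aM: float
    nu: float
    method: str
    params: HomogenizedParams

    def __post_init__(self) -> None:
        if self.bM <= 0 or self.aM <= 0:
            raise ValueError("bM and aM must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "M": int(self.M), "bM": self.bM, "aM": self.aM, "nu": self.nu,
            "method": self.method,
            "params": {"R": self.params.R, "D": self.params.D,
                       "kappa": self.params.kappa},
        }, indent=2))


def gumbel_scaling(
    M: int, params: HomogenizedParams, method: str = "numeric"
) -> GumbelScaling:
    """Compute (b_M, a_M) for M released particles.

    numeric
        Solves ``S(b_M) = 1 - 1/M`` by bracketed root-finding on the
        short-time survival form (in log space, where the equation
        ``ln h(b) - (R-1)^2/(4 D b) + ln M = 0`` is monotone), then
        ``a_M = -1/(M S'(b_M))`` with S' differentiated analytically.
    asymptotic
        Leading order ``b_M = (R-1)^2/(6 D nu)``, ``a_M = b_M / (3 nu / 2)``.

    Requires ``M >= 100`` (the limit law needs M >> 1).
    """
    if M < 100:
        raise ValueError(f"M must be at least 100 for the extreme-value limit, got {M}")
    R, D, kap = params.R, params.D, params.kappa
    c = (R - 1.0) ** 2 / (4.0 * D)
    nu = nu_log_factor(M, params)
    if nu <= 0:
        raise ValueError(f"asymptotic log factor nu={nu:.3g} <= 0: M too small")
    b_asym = (R - 1.0) ** 2 / (6.0 * D * nu)

    if method == "asymptotic":
        aM = b_asym / (1.5 * nu)
        return GumbelScaling(M=M, bM=b_asym, aM=aM, nu=nu, method=method, params=params)
    if method != "numeric":
        raise ValueError(f"method must be 'numeric' or 'asymptotic', got {method!r}")

    def log_eq(b):  # ln[M (1 - S(b))], strictly increasing in b
        return np.log(survival_prefactor_h(b, params)) - c / b + np.log(M)

    lo = b_asym / 10.0
    hi = b_asym
    while log_eq(hi) < 0.0:
        hi *= 2.0
        if hi > 1e6 * b_asym:
            raise RuntimeError("no sign change found when bracketing b_M")
    while log_eq(lo) > 0.0:
        lo /= 10.0
    bM = brentq(log_eq, lo, hi, rtol=1e-14)

    # S'(t) = -e^{-c/t} (h'(t) + h(t) c / t^2); with h e^{-c/b} = 1/M,
    # a_M = -1/(M S'(b_M)) = 1/(h'/h + c/b^2) evaluated at b_M.
    q = (R - 1.0) + 2.0 * (kap + D) * bM
    hprime_over_h = 1.5 / bM - 2.0 * (kap + D) / q
    aM = 1.0 / (hprime_over_h + c / bM**2)
    return GumbelScaling(M=M, bM=float(bM), aM=float(aM), nu=nu,
                         method="numeric", params=params)


# --------------------------------------------------------------------------
# k-th arrival limit law
# --------------------------------------------------------------------------

def kth_arrival_density(x, k: int):
    """Density of the scaled k-th arrival time, exp(kx - e^x)/(k-1)!.

    ``k = 1`` is the (minimum-form) Gumbel density; general k is the law of
    ``log(Gamma(k))``.  Vectorized over x.
    """
    if k < 1:
        raise ValueError(f"arrival rank k must be >= 1, got {k!r}")
    x_arr = np.asarray(x, dtype=float)
    out = np.exp(k * x_arr - np.exp(x_arr) - gammaln(k))
    return out if out.ndim else float(out)


def kth_arrival_mode(k: int, scaling: GumbelScaling | None = None) -> float:
    """Mode of the k-th arrival law: log k (scaled), b_M + a_M log k (unscaled)."""
    if k < 1:
        raise ValueError(f"arrival rank k must be >= 1, got {k!r}")
    m = float(np.log(k))
    if scaling is None:
        return m
    return scaling.bM + scaling.aM * m


def sample_kth_arrival(k: int, size: int, rng: np.random.Generator,
                       scaling: GumbelScaling | None = None) -> np.ndarray:
    """Draw samples of the k-th arrival law via X = log(Gamma(k, 1)).

    With ``scaling`` given, returns unscaled times ``b_M + a_M X``.
    """
    if k < 1:
        raise ValueError(f"arrival rank k must be >= 1, got {k!r}")
    x = np.log(rng.gamma(shape=k, scale=1.0, size=size))
    if scaling is None:
        return x
    return scaling.bM + scaling.aM * x


# --------------------------------------------------------------------------
# Angular error rates
# --------------------------------------------------------------------------

def lambda_k(k, scaling: GumbelScaling) -> np.ndarray | float:
    """Mean angular error of the k-th event: lambda_k = (2D/R)(b_M + a_M ln k).

    ``1 - z_k`` is asymptotically Exp with mean lambda_k; smaller lambda_k
    means the event points more accurately at the source.  Vectorized over k.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 1):
        raise ValueError("arrival ranks must be >= 1")
    p = scaling.params
    out = 2.0 * p.D / p.R * (scaling.bM + scaling.aM * np.log(k_arr))
    return out if out.ndim else float(out)


def lambda1_asymptotic(M: int, params: HomogenizedParams, form: str = "nu") -> float:
    """Leading-order first-event error rate.

    form="nu":   lambda_1 ~ (R-1)^2 / (3 R nu)
    form="logM": lambda_1 ~ (R-1)^2 / (2 R ln M)  (the cruder M -> inf form)
    """
    R = params.R
    if form == "nu":
        return (R - 1.0) ** 2 / (3.0 * R * nu_log_factor(M, params))
    if form == "logM":
        return (R - 1.0) ** 2 / (2.0 * R * np.log(M))
    raise ValueError(f"form must be 'nu' or 'logM', got {form!r}")


# --------------------------------------------------------------------------
# Hypoexponential law of the K-averaged error
# --------------------------------------------------------------------------

#: pairwise rate gap (relative to the largest rate) below which the
#: partial-fraction weights are numerically singular
_DEGENERATE_GAP = 1e-8

#: total weight magnitude above which partial-fraction cancellation would
#: cost more than ~8 significant digits
_WEIGHT_CAP = 1e8


def _is_degenerate(rates: np.ndarray) -> bool:
    """True when the partial-fraction form is numerically unusable.

    Either two rates (nearly) coincide, or the alternating weights are so
    large that their cancellation destroys double precision (the weights
    grow like (rate/gap)^(K-1) for K nearly equal rates).
    """
    gaps = np.abs(np.subtract.outer(rates, rates))
    np.fill_diagonal(gaps, np.inf)
    if gaps.min() < _DEGENERATE_GAP * rates.max():
        return True
    return bool(np.sum(np.abs(_hypo_weights(rates))) > _WEIGHT_CAP)


def _hypo_weights(rates: np.ndarray) -> np.ndarray:
    """Partial-fraction weights w_i = prod_{j != i} alpha_j / (alpha_j - alpha_i)."""
    K = rates.size
    w = np.empty(K)
    for i in range(K):
        others = np.delete(rates, i)
        w[i] = np.prod(others / (others - rates[i]))
    return w


def _phase_type_pdf(z: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Matrix-exponential (phase-type) evaluation, robust to equal rates."""
    K = rates.size
    T = np.diag(-rates) + np.diag(rates[:-1], 1)
    exit_rate = np.zeros(K)
    exit_rate[-1] = rates[-1]
    alpha = np.zeros(K)
    alpha[0] = 1.0
    return np.array([float(alpha @ expm(T * zi) @ exit_rate) for zi in z])


def _phase_type_cdf(z: np.ndarray, rates: np.ndarray) -> np.ndarray:
    K = rates.size
    T = np.diag(-rates) + np.diag(rates[:-1], 1)
    alpha = np.zeros(K)
    alpha[0] = 1.0
    ones = np.ones(K)
    return np.array([1.0 - float(alpha @ expm(T * zi) @ ones) for zi in z])


def hypoexponential_pdf(z, rates) -> np.ndarray | float:
    """Density of a sum of independent exponentials with the given rates.

    Uses the partial-fraction form
    ``sum_i w_i alpha_i e^(-alpha_i z)``, ``w_i = prod_{j != i} alpha_j /
    (alpha_j - alpha_i)``, which assumes pairwise-distinct rates; when two
    rates nearly coincide (relative gap < 1e-8) the numerically stable
    matrix-exponential (phase-type) form is used instead.  Vectorized
    over z; the density is zero for z < 0.
    """
    rates_arr = np.asarray(rates, dtype=float)
    if np.any(rates_arr <= 0.0):
        raise ValueError("all rates must be positive")
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.zeros_like(z_arr)
    pos = z_arr >= 0.0
    if _is_degenerate(rates_arr):
        out[pos] = _phase_type_pdf(z_arr[pos], rates_arr)
    else:
        w = _hypo_weights(rates_arr)
        out[pos] = np.sum(
            w[:, None] * rates_arr[:, None] * np.exp(-np.outer(rates_arr, z_arr[pos])),
            axis=0,
        )
    return out if np.ndim(z) else float(out[0])


def hypoexponential_cdf(z, rates) -> np.ndarray | float:
    """CDF of the hypoexponential law (see :func:`hypoexponential_pdf`)."""
    rates_arr = np.asarray(rates, dtype=float)
    if np.any(rates_arr <= 0.0):
        raise ValueError("all rates must be positive")
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.zeros_like(z_arr)
    pos = z_arr >= 0.0
    if _is_degenerate(rates_arr):
        out[pos] = _phase_type_cdf(z_arr[pos], rates_arr)
    else:
        w = _hypo_weights(rates_arr)
        out[pos] = np.sum(
            w[:, None] * (1.0 - np.exp(-np.outer(rates_arr, z_arr[pos]))), axis=0
        )
    return out if np.ndim(z) else float(out[0])


def sample_hypoexponential(rates, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw samples as the sum of independent exponentials (inverse CDF)."""
    rates_arr = np.asarray(rates, dtype=float)
    u = rng.random((rates_arr.size, size))
    return np.sum(-np.log(u) / rates_arr[:, None], axis=0)


# --------------------------------------------------------------------------
# Error moments and the optimal number of events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorLaw:
    """Hypoexponential law of the K-averaged angular error 1 - Z_K.

    ``rates`` are the per-event means (lambda_1 .. lambda_K); the averaged
    error is Hypo(K/lambda_1, ..., K/lambda_K) with mean ``sum lambda_i / K``
    and variance ``sum lambda_i^2 / K^2``.
    """

    K: int
    rates: np.ndarray = field(repr=False)  # lambda_1..lambda_K
    mean_error: float
    var_error: float

    @property
    def alphas(self) -> np.ndarray:
        """Hypoexponential rates alpha_i = K / lambda_i."""
        return self.K / self.rates

    @property
    def mse(self) -> float:
        """Mean squared error E[(1 - Z_K)^2] = var + mean^2."""
        return self.var_error + self.mean_error**2

    def pdf(self, z):
        return hypoexponential_pdf(z, self.alphas)

    def cdf(self, z):
        return hypoexponential_cdf(z, self.alphas)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "K": int(self.K), "rates": list(map(float, self.rates)),
            "mean_error": self.mean_error, "var_error": self.var_error,
        }, indent=2))


def error_moments(K: int, scaling: GumbelScaling) -> ErrorLaw:
    """Mean and variance of the K-averaged angular error 1 - Z_K.

    Both closed forms of the mean — ``sum_i lambda_i / K`` and
    ``(2D/R)(b_M + a_M ln(K!) / K)`` — are evaluated and must agree to
    machine precision (ln K! via the log-gamma function).
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K!r}")
    lam = np.asarray(lambda_k(np.arange(1, K + 1), scaling))
    mean = float(lam.sum() / K)
    p = scaling.params
    mean_alt = 2.0 * p.D / p.R * (scaling.bM + scaling.aM * gammaln(K + 1) / K)
    if not np.isclose(mean, mean_alt, rtol=1e-12):
        raise AssertionError(
            f"mean-error closed forms disagree: {mean!r} vs {mean_alt!r}"
        )
    var = float(np.sum(lam**2) / K**2)
    return ErrorLaw(K=K, rates=lam, mean_error=mean, var_error=var)


def optimal_k(
    scaling: GumbelScaling, K_max: int, criterion: str = "mse"
) -> int:
    """Number of averaged events K* minimizing the chosen error criterion.

    criterion="mse" (default) minimizes E[(1-Z_K)^2] = Var + Mean^2;
    "mean" and "var" minimize the individual moments (the mean is
    increasing in K, so "mean" always returns 1; the variance is
    decreasing on any practical range, so "var" returns K_max there).
    Exhaustive search over K = 1..K_max.
    """
    if K_max < 1:
        raise ValueError(f"K_max must be >= 1, got {K_max!r}")
    laws = [error_moments(K, scaling) for K in range(1, K_max + 1)]
    if criterion == "mse":
        vals = [law.mse for law in laws]
    elif criterion == "mean":
        vals = [law.mean_error for law in laws]
    elif criterion == "var":
        vals = [law.var_error for law in laws]
    else:
        raise ValueError(f"criterion must be 'mse', 'mean' or 'var', got {criterion!r}")
    return int(np.argmin(vals)) + 1
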