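"""Kinetic Monte Carlo simulation of ligand capture by surface receptors.

``M`` independent particles are released at the point source
``x0 = (0, 0, R)`` outside the unit sphere and diffuse with diffusivity
``D`` until they either bind to a receptor cap or escape to infinity.
The dynamics are split at a spherical shell of radius ``near_shell``:

far field (r > near_shell)
    A cascade of kinetic Monte Carlo jumps through concentric spheres,
    each spanning a radial ratio of at most 1.3.  Per jump: the particle
    escapes to infinity with the exact splitting probability ``1 - s'/r``;
    otherwise the elapsed time comes from the exact conditional
    first-passage law (a Levy density over the radial gap) and the hit
    angle is drawn *given that time* from a von Mises-Fisher law whose
    mean ``E[cos(gamma) | tau]`` is tabulated exactly from the
    absorbing-sphere spectral flux (the kappa -> infinity limit of the
    homogenized model).  Decomposing the passage into legs is exact for
    escape probabilities and times (the 1/|x| Doob conditioning is common
    to all legs); only the angular shape within a leg is approximated, by
    a distribution with the exact conditional mean.  Sampling the hit
    angle conditionally on the elapsed time preserves the strong
    time-angle correlation of early arrivals, which a time-marginal
    (harmonic measure) draw would destroy.  The single-jump marginal
    contract is still available as :func:`far_field_step`.

near field (1 < r <= near_shell)
    Brownian dynamics with Gaussian increments of step ``dt_near``.  A
    sub-step that crosses ``r = 1`` is resolved by linear interpolation:
    the crossing point either lies in a receptor cap (absorption — the
    binding event is recorded) or the particle reflects specularly off
    the sphere's tangent plane.  Crossing ``r = near_shell`` outward
    returns control to the far-field jump.

The hot loops are compiled with numba; each particle consumes its own
RNG stream (seeded from a SeedSequence spawn), so results for a fixed
seed do not depend on execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from numba import njit

from .geometry import ReceptorConfig, locate_receptor

__all__ = [
    "SimulationConfig",
    "EventTable",
    "FarFieldResult",
    "NearFieldResult",
    "far_field_step",
    "near_field_step",
    "simulate",
]

_STATUS_ESCAPED, _STATUS_ABSORBED, _STATUS_CENSORED = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    ``dt_near`` defaults to ``a^2 / (144 D)``, i.e. a Gaussian sub-step of
    r.m.s. size ``sqrt(4 D dt) = a/6`` — a sixth of the receptor radius.
    Convergence studies against an independent capacitance-matrix oracle
    show the bridge-corrected walk needs this resolution for percent-level
    capture accuracy; coarser (or finer) steps can be set explicitly.  ``near_shell`` is the hand-off
    radius between fine dynamics and KMC jumps; raising it toward the
    source gives the (slower) near-exact propagation used for audits.
    ``absorb_on_contact`` turns the whole sphere into an absorber
    (receptors ignored), which is the classical validation limit with
    capture probability 1/R.  ``t_max`` censors particles still in play.
    """

    M: int
    R: float
    D: float = 1.0
    receptors: ReceptorConfig | None = None
    seed: int = 0
    near_shell: float = 1.2
    dt_near: float | None = None
    t_max: float | None = None
    absorb_on_contact: bool = False

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"M must be positive, got {self.M!r}")
        if self.R <= 1.0:
            raise ValueError(f"source distance R must exceed 1, got {self.R!r}")
        if self.D <= 0.0:
            raise ValueError(f"D must be positive, got {self.D!r}")
        if self.near_shell <= 1.0:
            raise ValueError(f"near_shell must exceed 1, got {self.near_shell!r}")
        if self.receptors is None and not self.absorb_on_contact:
            # zero receptors: legal, nothing ever binds
            pass
        if self.dt_near is None:
            if self.receptors is not None:
                dt = self.receptors.a**2 / (144.0 * self.D)
            else:
                dt = 1e-4 / self.D
            object.__setattr__(self, "dt_near", float(dt))
        if self.dt_near <= 0.0:
            raise ValueError("dt_near must be positive")
        if self.receptors is not None and not self.absorb_on_contact:
            if np.sqrt(4.0 * self.D * self.dt_near) >= self.receptors.a:
                raise ValueError(
                    "receptor resolution condition violated: "
                    f"sqrt(4 D dt_near) = {np.sqrt(4 * self.D * self.dt_near):.3g} "
                    f"must be smaller than the cap radius a = {self.receptors.a:.3g}"
                )

    def to_dict(self) -> dict:
        d = {
            "M": int(self.M), "R": self.R, "D": self.D, "seed": int(self.seed),
            "near_shell": self.near_shell, "dt_near": self.dt_near,
            "t_max": self.t_max, "absorb_on_contact": self.absorb_on_contact,
        }
        if self.receptors is not None:
            d["receptors"] = {"N": int(self.receptors.N),
                              "sigma": float(self.receptors.sigma),
                              "a": float(self.receptors.a)}
        return d


class FarFieldResult(NamedTuple):
    escaped: bool
    point: np.ndarray | None  # hit point on the shell (when not escaped)
    elapsed: float            # elapsed time of the jump (0 for escape)


class NearFieldResult(NamedTuple):
    outcome: str              # "absorbed" | "reflected" | "exited" | "moved"
    position: np.ndarray
    elapsed: float
    receptor: int | None


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d (and to each other)."""
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def sample_shell_hit_angle(u: float, r: float, s: float) -> float:
    """Inverse CDF of the exterior harmonic measure, conditioned on hitting.

    Returns ``mu = cos(gamma)``, the cosine of the angle between the start
    direction and the hit point, for a walker at radius ``r`` hitting the
    sphere of radius ``s < r``.  The conditional density is
    ``f(mu) = r (r^2 - s^2) / (2 (r^2 + s^2 - 2 r s mu)^(3/2))``.
    """
    q = 2.0 * s * u / (r * r - s * s) + 1.0 / (r + s)
    return (r * r + s * s - q ** (-2.0)) / (2.0 * r * s)


def far_field_step(
    position: np.ndarray, rng: np.random.Generator, *, shell: float, D: float = 1.0
) -> FarFieldResult:
    """One KMC jump from outside the shell: escape, or first hit on it.

    Escape fires with the exact exterior splitting probability ``1 - s/r``;
    otherwise the hit point is drawn from the harmonic measure (inverse
    CDF) and the elapsed time from the conditional first-passage density
    ``(r-s)/sqrt(4 pi D t^3) exp(-(r-s)^2/(4 D t))`` (a Levy law, sampled
    as ``(r-s)^2 / (2 D Z^2)`` with Z standard normal).  Time and place
    are treated as independent; see the module docstring.
    """
    position = np.asarray(position, dtype=float)
    r = float(np.linalg.norm(position))
    if r < shell:
        raise ValueError(f"far-field step requires |position| >= shell ({r} < {shell})")
    if r == shell:
        return FarFieldResult(False, position.copy(), 0.0)
    if rng.random() < 1.0 - shell / r:
        return FarFieldResult(True, None, 0.0)
    mu = sample_shell_hit_angle(rng.random(), r, shell)
    phi = 2.0 * np.pi * rng.random()
    d = position / r
    e1, e2 = _orthonormal_frame(d)
    sin_g = np.sqrt(max(0.0, 1.0 - mu * mu))
    point = shell * (mu * d + sin_g * (np.cos(phi) * e1 + np.sin(phi) * e2))
    z = rng.standard_normal()
    while z == 0.0:
        z = rng.standard_normal()
    elapsed = (r - shell) ** 2 / (2.0 * D * z * z)
    return FarFieldResult(False, point, float(elapsed))


def _sphere_crossing(p0: np.ndarray, dp: np.ndarray) -> float:
    """Fraction alpha in [0, 1] where |p0 + alpha dp| = 1 (first crossing)."""
    a = float(dp @ dp)
    b = 2.0 * float(p0 @ dp)
    c = float(p0 @ p0) - 1.0
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return 1.0
    root = (-b - np.sqrt(disc)) / (2.0 * a)
    if root < 0.0:
        root = (-b + np.sqrt(disc)) / (2.0 * a)
    return float(root)


def near_field_step(
    position: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> NearFieldResult:
    """One Gaussian sub-step of the near-surface Brownian dynamics.

    Outcomes: ``absorbed`` (surface contact inside a receptor cap),
    ``reflected`` (specular bounce off the sphere), ``exited`` (crossed
    the shell outward) or ``moved`` (plain diffusion step).  The elapsed
    time is ``dt_near`` except for absorption, where the contact fraction
    interpolates the time of the binding event.

    A step whose endpoints both lie above the surface may still have
    touched it in between; that dip is recovered with the Brownian-bridge
    touch probability ``exp(-d0 d1 / (D dt))`` (d0, d1 the endpoint
    clearances), with the contact placed at the segment's closest approach.
    Without this correction the walk systematically under-detects contacts
    and the capture fraction is biased low by O(sqrt(dt)).
    """
    p0 = np.asarray(position, dtype=float)
    r0 = float(np.linalg.norm(p0))
    if not 1.0 <= r0 <= config.near_shell:
        raise ValueError(
            f"near-field step requires 1 <= |position| <= shell, got {r0}"
        )
    dt = config.dt_near
    step = rng.standard_normal(3) * np.sqrt(2.0 * config.D * dt)
    p1 = p0 + step
    r1 = float(np.linalg.norm(p1))
    if r1 >= 1.0:
        d0, d1 = r0 - 1.0, r1 - 1.0
        arg = d0 * d1 / (config.D * dt)
        if arg < 20.0 and rng.random() < np.exp(-arg):
            # bridge touched the surface: contact at closest approach
            alpha = min(1.0, max(0.0, -float(p0 @ step) / float(step @ step)))
            xc = p0 + alpha * step
            xc /= np.linalg.norm(xc)
            if config.absorb_on_contact:
                return NearFieldResult("absorbed", xc, alpha * dt, None)
            if config.receptors is not None:
                rid = locate_receptor(xc, config.receptors)
                if rid is not None:
                    return NearFieldResult("absorbed", xc, alpha * dt, rid)
        if r1 > config.near_shell:
            return NearFieldResult("exited", p1, dt, None)
        return NearFieldResult("moved", p1, dt, None)
    alpha = _sphere_crossing(p0, step)
    xc = p0 + alpha * step
    xc /= np.linalg.norm(xc)
    rid = None
    if config.absorb_on_contact:
        rid = -1
    elif config.receptors is not None:
        rid = locate_receptor(xc, config.receptors)
    if rid is not None:
        return NearFieldResult("absorbed", xc, alpha * dt,
                               None if rid == -1 else rid)
    v = (1.0 - alpha) * step
    v = v - 2.0 * float(v @ xc) * xc
    p1 = xc + v
    # a long curved step can re-enter; bounce until outside
    while np.linalg.norm(p1) < 1.0:
        alpha2 = _sphere_crossing(xc, p1 - xc)
        xc = xc + alpha2 * (p1 - xc)
        xc /= np.linalg.norm(xc)
        v = p1 - xc
        v = v - 2.0 * float(v @ xc) * xc
        p1 = xc + v
    return NearFieldResult("reflected", p1, dt, None)


# --------------------------------------------------------------------------
# Time-conditioned angular law of one far-field leg
# --------------------------------------------------------------------------

#: maximum radial ratio r / s' spanned by one far-field leg
_LEG_RATIO = 1.3

_ANGULAR_TABLE: tuple | None = None


def _angular_mean_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tabulate E[cos(gamma) | tau] for one first-passage leg.

    For a walker at radius ``rho`` (target sphere radius 1) that hits the
    target at elapsed time ``tau``, the polar angle gamma of the hit point
    about the start direction has mean ``psi_1(tau)/psi_0(tau)`` where
    psi_n are the flux coefficients of the *fully absorbing* sphere — the
    kappa -> infinity limit of the homogenized model.  Tabulated on a grid
    of ``log10(x)`` (x = D tau / s'^2) by ``log10(rho - 1)``; below the
    grid in x the exact short-time asymptote ``1 - 2x/rho`` applies.
    """
    global _ANGULAR_TABLE
    if _ANGULAR_TABLE is not None:
        return _ANGULAR_TABLE
    from .homogenized import HomogenizedParams, psi_spectrum

    lx = np.arange(-6.0, 3.51, 0.125)
    lg = np.linspace(-4.0, np.log10(_LEG_RATIO - 1.0 + 0.05), 29)
    m = np.empty((lx.size, lg.size))
    for j, g in enumerate(lg):
        rho = 1.0 + 10.0**g
        pp = HomogenizedParams(R=rho, D=1.0, kappa=1e12)
        for i, xl in enumerate(lx):
            x = 10.0**xl
            if (rho - 1.0) ** 2 / (4.0 * x) > 200.0:
                m[i, j] = 1.0 - 2.0 * x / rho
            else:
                ps = psi_spectrum(x, 1, pp)
                val = ps[1] / ps[0] if ps[0] > 0 else 0.0
                m[i, j] = min(1.0, max(-1.0, val))
    _ANGULAR_TABLE = (lx, lg, m)
    return _ANGULAR_TABLE


# --------------------------------------------------------------------------
# Compiled per-particle kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _vmf_cos(m, u):  # pragma: no cover - compiled helper
    """Sample cos(gamma) from a von Mises-Fisher law with mean m, u ~ U(0,1)."""
    if m <= 1e-12:
        return 2.0 * u - 1.0
    if m >= 1.0 - 1e-12:
        return 1.0
    if m > 0.95:
        k = 1.0 / (1.0 - m)  # coth(k) ~ 1 for k > 20
    else:
        k = m * (3.0 - m * m) / (1.0 - m * m)
        for _ in range(2):
            sh = np.sinh(k)
            f = np.cosh(k) / sh - 1.0 / k - m
            fp = 1.0 / (k * k) - 1.0 / (sh * sh)
            k -= f / fp
            if k <= 0.0:
                k = 1e-8
    if u < 1e-300:
        u = 1e-300
    if k < 1e-5:
        w = 2.0 * u - 1.0
    elif k > 35.0:
        w = 1.0 + np.log(u) / k
    else:
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * k)) / k
    if w < -1.0:
        w = -1.0
    elif w > 1.0:
        w = 1.0
    return w


@njit(cache=True)
def _run_particles(
    seeds, R, D, centers, cos_cap, absorb_all, shell, dt, t_max,
    lx, lg, mtab,
):  # pragma: no cover - exercised through simulate()
    M = seeds.shape[0]
    status = np.empty(M, dtype=np.int8)
    times = np.zeros(M)
    hits = np.zeros((M, 3))
    rids = np.full(M, -1, dtype=np.int64)
    ncent = centers.shape[0]
    sig = np.sqrt(2.0 * D * dt)

    for i in range(M):
        np.random.seed(seeds[i])
        px, py, pz = 0.0, 0.0, R
        t = 0.0
        st = np.int8(_STATUS_CENSORED)
        alive = True
        while alive:
            r = np.sqrt(px * px + py * py + pz * pz)
            if r > shell:
                # --- one far-field KMC leg: jump inward by <= _LEG_RATIO ---
                starget = r / 1.3
                if starget < shell:
                    starget = shell
                if np.random.random() < 1.0 - starget / r:
                    st = np.int8(_STATUS_ESCAPED)
                    break
                zn = np.random.standard_normal()
                while zn == 0.0:
                    zn = np.random.standard_normal()
                tau = (r - starget) ** 2 / (2.0 * D * zn * zn)
                t += tau
                if t_max > 0.0 and t > t_max:
                    break  # censored
                # angular displacement given tau: vMF with the exact mean
                x_nd = D * tau / (starget * starget)
                rho = r / starget
                lxx = np.log10(x_nd)
                lgg = np.log10(rho - 1.0) if rho > 1.0 + 1e-13 else lg[0]
                if lxx <= lx[0]:
                    mmean = 1.0 - 2.0 * x_nd / rho
                else:
                    if lxx >= lx[-1]:
                        lxx = lx[-1]
                    if lgg <= lg[0]:
                        lgg = lg[0]
                    elif lgg >= lg[-1]:
                        lgg = lg[-1]
                    i0 = int((lxx - lx[0]) / (lx[1] - lx[0]))
                    if i0 > lx.size - 2:
                        i0 = lx.size - 2
                    j0 = int((lgg - lg[0]) / (lg[1] - lg[0]))
                    if j0 > lg.size - 2:
                        j0 = lg.size - 2
                    fx = (lxx - lx[i0]) / (lx[1] - lx[0])
                    fg = (lgg - lg[j0]) / (lg[1] - lg[0])
                    mmean = (
                        mtab[i0, j0] * (1 - fx) * (1 - fg)
                        + mtab[i0 + 1, j0] * fx * (1 - fg)
                        + mtab[i0, j0 + 1] * (1 - fx) * fg
                        + mtab[i0 + 1, j0 + 1] * fx * fg
                    )
                mu = _vmf_cos(mmean, np.random.random())
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = px / r, py / r, pz / r
                # orthonormal frame around the radial direction
                if abs(dx) < 0.9:
                    ax, ay, az = 1.0, 0.0, 0.0
                else:
                    ax, ay, az = 0.0, 1.0, 0.0
                e1x = dy * az - dz * ay
                e1y = dz * ax - dx * az
                e1z = dx * ay - dy * ax
                n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x /= n1; e1y /= n1; e1z /= n1
                e2x = dy * e1z - dz * e1y
                e2y = dz * e1x - dx * e1z
                e2z = dx * e1y - dy * e1x
                sg = np.sqrt(max(0.0, 1.0 - mu * mu))
                cx = np.cos(phi) * sg
                sx = np.sin(phi) * sg
                px = starget * (mu * dx + cx * e1x + sx * e2x)
                py = starget * (mu * dy + cx * e1y + sx * e2y)
                pz = starget * (mu * dz + cx * e1z + sx * e2z)
                continue
            # --- near-field Gaussian dynamics ---
            while True:
                gx = np.random.standard_normal() * sig
                gy = np.random.standard_normal() * sig
                gz = np.random.standard_normal() * sig
                t += dt
                if t_max > 0.0 and t > t_max:
                    alive = False
                    break
                qx, qy, qz = px + gx, py + gy, pz + gz
                rq2 = qx * qx + qy * qy + qz * qz
                if rq2 < 1.0:
                    # resolve the r=1 crossing, bounce until outside
                    absorbed = False
                    while rq2 < 1.0:
                        sx_, sy_, sz_ = qx - px, qy - py, qz - pz
                        a_ = sx_ * sx_ + sy_ * sy_ + sz_ * sz_
                        b_ = 2.0 * (px * sx_ + py * sy_ + pz * sz_)
                        c_ = px * px + py * py + pz * pz - 1.0
                        disc = b_ * b_ - 4.0 * a_ * c_
                        if disc < 0.0:
                            break
                        al = (-b_ - np.sqrt(disc)) / (2.0 * a_)
                        if al < 0.0:
                            al = (-b_ + np.sqrt(disc)) / (2.0 * a_)
                        xcx = px + al * sx_
                        xcy = py + al * sy_
                        xcz = pz + al * sz_
                        nrm = np.sqrt(xcx * xcx + xcy * xcy + xcz * xcz)
                        xcx /= nrm; xcy /= nrm; xcz /= nrm
                        hit_id = -1
                        if absorb_all:
                            hit_id = ncent  # sentinel: any contact absorbs
                        else:
                            best = -2.0
                            bi = -1
                            for j in range(ncent):
                                dp = (xcx * centers[j, 0] + xcy * centers[j, 1]
                                      + xcz * centers[j, 2])
                                if dp > best:
                                    best = dp
                                    bi = j
                            if ncent > 0 and best >= cos_cap:
                                hit_id = bi
                        if hit_id >= 0:
                            t += (al - 1.0) * dt  # interpolate binding time
                            hits[i, 0] = xcx
                            hits[i, 1] = xcy
                            hits[i, 2] = xcz
                            rids[i] = hit_id if hit_id < ncent else -1
                            st = np.int8(_STATUS_ABSORBED)
                            absorbed = True
                            alive = False
                            break
                        # specular reflection of the remaining displacement
                        vx = (1.0 - al) * sx_
                        vy = (1.0 - al) * sy_
                        vz = (1.0 - al) * sz_
                        dvn = 2.0 * (vx * xcx + vy * xcy + vz * xcz)
                        vx -= dvn * xcx
                        vy -= dvn * xcy
                        vz -= dvn * xcz
                        px, py, pz = xcx, xcy, xcz
                        qx, qy, qz = px + vx, py + vy, pz + vz
                        rq2 = qx * qx + qy * qy + qz * qz
                    if absorbed:
                        break
                    px, py, pz = qx, qy, qz
                else:
                    # both endpoints above the surface: Brownian-bridge
                    # touch correction, exp(-d0 d1/(D dt)), contact at the
                    # segment's closest approach to the sphere
                    d0 = np.sqrt(px * px + py * py + pz * pz) - 1.0
                    d1 = np.sqrt(rq2) - 1.0
                    arg = d0 * d1 / (D * dt)
                    if arg < 20.0 and np.random.random() < np.exp(-arg):
                        a_ = gx * gx + gy * gy + gz * gz
                        al = -(px * gx + py * gy + pz * gz) / a_
                        if al < 0.0:
                            al = 0.0
                        elif al > 1.0:
                            al = 1.0
                        xcx = px + al * gx
                        xcy = py + al * gy
                        xcz = pz + al * gz
                        nrm = np.sqrt(xcx * xcx + xcy * xcy + xcz * xcz)
                        xcx /= nrm; xcy /= nrm; xcz /= nrm
                        hit_id = -1
                        if absorb_all:
                            hit_id = ncent
                        else:
                            best = -2.0
                            bi = -1
                            for j in range(ncent):
                                dp = (xcx * centers[j, 0] + xcy * centers[j, 1]
                                      + xcz * centers[j, 2])
                                if dp > best:
                                    best = dp
                                    bi = j
                            if ncent > 0 and best >= cos_cap:
                                hit_id = bi
                        if hit_id >= 0:
                            t += (al - 1.0) * dt
                            hits[i, 0] = xcx
                            hits[i, 1] = xcy
                            hits[i, 2] = xcz
                            rids[i] = hit_id if hit_id < ncent else -1
                            st = np.int8(_STATUS_ABSORBED)
                            alive = False
                            break
                    px, py, pz = qx, qy, qz
                    if rq2 > shell * shell:
                        break  # back to the far field
        times[i] = t
        status[i] = st
    return status, times, hits, rids


# --------------------------------------------------------------------------
# Driver and event table
# --------------------------------------------------------------------------

@dataclass
class EventTable:
    """Sorted binding events of one simulation run.

    ``events`` has one row per binding, ordered by time: columns
    ``k`` (rank, 1-based), ``t``, ``x``, ``y``, ``z_coord`` (the binding
    location on the unit sphere), ``cos_theta`` (= z_coord: elevation
    relative to the source direction e3) and ``receptor_id``.
    """

    events: pd.DataFrame
    Ma: int
    escaped: int
    censored: int
    seed: int
    config: SimulationConfig
    ties: int = 0

    @property
    def arrival_times(self) -> np.ndarray:
        return self.events["t"].to_numpy()

    @property
    def elevations(self) -> np.ndarray:
        return self.events["cos_theta"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """CSV of events plus a JSON sidecar with config and counts."""
        path = Path(path)
        self.events.to_csv(path, index=False)
        side = {
            "config": self.config.to_dict(),
            "seed": int(self.seed),
            "Ma": int(self.Ma),
            "escaped": int(self.escaped),
            "censored": int(self.censored),
            "ties": int(self.ties),
        }
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        path = Path(path)
        events = pd.read_csv(path)
        side = json.loads(path.with_suffix(".json").read_text())
        cfg = side["config"]
        rec = None
        if "receptors" in cfg:
            rec = ReceptorConfig.fibonacci(cfg["receptors"]["N"],
                                           cfg["receptors"]["sigma"])
        config = SimulationConfig(
            M=cfg["M"], R=cfg["R"], D=cfg["D"], receptors=rec,
            seed=cfg["seed"], near_shell=cfg["near_shell"],
            dt_near=cfg["dt_near"], t_max=cfg["t_max"],
            absorb_on_contact=cfg["absorb_on_contact"],
        )
        return cls(events=events, Ma=side["Ma"], escaped=side["escaped"],
                   censored=side["censored"], seed=side["seed"],
                   config=config, ties=side.get("ties", 0))


def simulate(config: SimulationConfig) -> EventTable:
    """Run M independent particles and collect the sorted binding events.

    Each particle owns an RNG stream seeded from
    ``SeedSequence(config.seed).generate_state(M)``, so the outcome is
    bitwise reproducible and independent of execution order.  Particles
    still in play at ``t_max`` (when set) are recorded as censored.
    Equal binding times (possible only through floating-point collision)
    are ordered stably by particle id and counted in ``ties``.
    """
    if config.receptors is not None:
        centers = np.ascontiguousarray(config.receptors.centers, dtype=np.float64)
        cos_cap = float(np.sqrt(1.0 - config.receptors.a**2))
    else:
        centers = np.zeros((0, 3))
        cos_cap = 2.0  # unattainable: nothing binds
    seeds = np.random.SeedSequence(config.seed).generate_state(config.M).astype(np.int64)
    t_max = -1.0 if config.t_max is None else float(config.t_max)
    lx, lg, mtab = _angular_mean_table()
    status, times, hits, rids = _run_particles(
        seeds, float(config.R), float(config.D), centers, cos_cap,
        config.absorb_on_contact, float(config.near_shell),
        float(config.dt_near), t_max, lx, lg, mtab,
    )
    bound = status == _STATUS_ABSORBED
    order = np.lexsort((np.arange(config.M)[bound], times[bound]))
    t_sorted = times[bound][order]
    xyz = hits[bound][order]
    events = pd.DataFrame({
        "k": np.arange(1, bound.sum() + 1),
        "t": t_sorted,
        "x": xyz[:, 0],
        "y": xyz[:, 1],
        "z_coord": xyz[:, 2],
        "cos_theta": xyz[:, 2],
        "receptor_id": rids[bound][order],
    })
    ties = int(np.sum(np.diff(t_sorted) == 0.0)) if t_sorted.size > 1 else 0
    return EventTable(
        events=events,
        Ma=int(bound.sum()),
        escaped=int(np.sum(status == _STATUS_ESCAPED)),
        censored=int(np.sum(status == _STATUS_CENSORED)),
        seed=int(config.seed),
        config=config,
        ties=ties,
    )
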