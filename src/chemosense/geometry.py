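"""Receptor configurations on the unit sphere.

The cell is modelled as the unit sphere carrying ``N`` static, circular,
non-overlapping surface receptors of common radius ``a`` (the planar/chord
radius of each small spherical cap).  Together the receptors occupy a
surface fraction ``sigma = N a^2 / 4`` and are centred on the Fibonacci
(golden-angle) spiral, a standard quasi-uniform covering of the sphere.

Lengths are nondimensional with the cell radius equal to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReceptorConfig",
    "fibonacci_points",
    "radius_from_sigma",
    "sigma_from_radius",
    "locate_receptor",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))  # 2*pi*(1 - 1/phi)

#: tolerance for "this vector lies on the unit sphere"
_UNIT_TOL = 1e-9


def fibonacci_points(N: int) -> np.ndarray:
    """Golden-angle (Fibonacci) spiral points on the unit sphere.

    Uses the offset lattice ``z_i = 1 - (2i+1)/N`` with azimuth incremented
    by the golden angle, which avoids placing points exactly at the poles.
    Deterministic: two calls with the same ``N`` return identical arrays.

    Parameters
    ----------
    N : int
        Number of points, ``N >= 1``.

    Returns
    -------
    (N, 3) ndarray of unit vectors.
    """
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ValueError(f"N must be a positive integer, got {N!r}")
    i = np.arange(N)
    z = 1.0 - (2.0 * i + 1.0) / N
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN_ANGLE * i
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # renormalise to kill rounding at the 1e-16 level
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def radius_from_sigma(N: int, sigma: float) -> float:
    """Cap radius ``a`` such that N caps occupy surface fraction sigma.

    Inverts ``sigma = N a^2 / 4`` (cap area ``pi a^2`` over sphere area
    ``4 pi``), giving ``a = 2 sqrt(sigma / N)``.
    """
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ValueError(f"N must be a positive integer, got {N!r}")
    if not 0.0 < sigma < 1.0:
        raise ValueError(f"sigma must lie in (0, 1), got {sigma!r}")
    return 2.0 * np.sqrt(sigma / N)


def sigma_from_radius(a: float, N: int) -> float:
    """Surface fraction ``sigma = N a^2 / 4`` covered by N caps of radius a."""
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ValueError(f"N must be a positive integer, got {N!r}")
    if a <= 0:
        raise ValueError(f"cap radius must be positive, got {a!r}")
    return N * a * a / 4.0


@dataclass(frozen=True)
class ReceptorConfig:
    """N receptor caps of common radius ``a`` on the unit sphere.

    Attributes
    ----------
    N : int
        Receptor count.
    a : float
        Cap radius (chord radius of the spherical cap); the geodesic
        angular radius is ``arcsin(a)``.
    sigma : float
        Combined surface fraction, ``sigma = N a^2 / 4``.
    centers : (N, 3) ndarray
        Unit vectors at the cap centres.
    """

    N: int
    a: float
    sigma: float
    centers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.shape != (self.N, 3):
            raise ValueError(f"centers must have shape ({self.N}, 3)")
        norms = np.linalg.norm(c, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("receptor centers must be unit vectors (tol 1e-12)")
        if not np.isclose(self.sigma, self.N * self.a**2 / 4.0, rtol=1e-12):
            raise ValueError("sigma = N a^2 / 4 must hold between stored fields")
        object.__setattr__(self, "centers", c)

    @classmethod
    def fibonacci(cls, N: int, sigma: float) -> "ReceptorConfig":
        """Standard construction: Fibonacci centres, radius from sigma."""
        a = radius_from_sigma(N, sigma)
        return cls(N=N, a=a, sigma=sigma, centers=fibonacci_points(N))

    @property
    def cap_angle(self) -> float:
        """Geodesic angular radius of each cap, ``arcsin(a)``."""
        return float(np.arcsin(self.a))

    def min_center_separation(self) -> float:
        """Minimum pairwise geodesic distance between cap centres (radians)."""
        g = np.clip(self.centers @ self.centers.T, -1.0, 1.0)
        np.fill_diagonal(g, -1.0)
        return float(np.arccos(g.max()))

    def is_nonoverlapping(self) -> bool:
        """True if no two caps overlap (centre separation > 2 arcsin a)."""
        return self.min_center_separation() > 2.0 * self.cap_angle

    # ---- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write centres as CSV (index, x, y, z) with a JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.centers, columns=["x", "y", "z"])
        df.index.name = "index"
        df.to_csv(path)
        meta = {"N": int(self.N), "a": float(self.a), "sigma": float(self.sigma)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReceptorConfig":
        path = Path(path)
        df = pd.read_csv(path, index_col="index")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(N=int(meta["N"]), a=float(meta["a"]), sigma=float(meta["sigma"]),
                   centers=df[["x", "y", "z"]].to_numpy())


def locate_receptor(x: np.ndarray, config: ReceptorConfig) -> int | None:
    """Index of the receptor cap containing the surface point ``x``.

    Membership uses the geodesic metric: ``x`` is inside cap ``i`` iff the
    angle to ``centers[i]`` is at most ``arcsin(a)``.  Caps are assumed
    non-overlapping, so the containing cap (if any) is unique; ties on the
    boundary resolve to the nearest centre.

    Returns ``None`` when ``x`` lies outside every cap.
    """
    x = np.asarray(x, dtype=float)
    nrm = np.linalg.norm(x)
    if abs(nrm - 1.0) > _UNIT_TOL:
        raise ValueError(f"x must be a unit vector (|x| = {nrm!r})")
    x = x / nrm
    dots = config.centers @ x
    i = int(np.argmax(dots))
    # cos(geodesic distance) >= cos(arcsin a) = sqrt(1 - a^2)
    if dots[i] >= np.sqrt(1.0 - config.a**2):
        return i
    return None
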