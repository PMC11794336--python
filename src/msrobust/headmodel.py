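"""Concentric four-shell spherical volume-conductor model.

The scalp potential of an intracranial current dipole is expanded in
spherical harmonics.  In each shell the potential is a combination of
``r**n`` and ``r**-(n+1)`` terms; continuity of potential and of radial
current density at the three inner interfaces, plus a no-current condition
at the scalp, fixes the coefficients per harmonic order ``n``.  The scalp
series is summed over orders 1..``n_max``; terms decay like
``(b/R)**(n-1)`` for a dipole at eccentricity ``b``.

Shells (brain, CSF gap, skull, scalp by radius) default to radii
71/72/79/85 mm with relative conductivities 0.33/0.0042/1/0.33.

``single_sphere_potential`` implements the classical closed-form
homogeneous-sphere surface solution (per-harmonic boundary factor
``(2n+1)/n`` on the infinite-medium expansion); it is kept independent of
the shell solver and serves as its degenerate-limit oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np

from .data_model import Montage, Topography

__all__ = ["HeadModel", "dipole_forward", "single_sphere_potential", "dipole_gain"]

DEFAULT_N_MAX = 60


@dataclass(frozen=True)
class HeadModel:
    """Four concentric shells: radii in mm (increasing), conductivities relative."""

    radii_mm: Tuple[float, float, float, float] = (71.0, 72.0, 79.0, 85.0)
    conductivities: Tuple[float, float, float, float] = (0.33, 0.0042, 1.0, 0.33)

    def __post_init__(self):
        r = self.radii_mm
        if not all(r[i] < r[i + 1] for i in range(3)):
            raise ValueError("shell radii must be strictly increasing")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius_mm(self) -> float:
        return self.radii_mm[0]

    @property
    def scalp_radius_mm(self) -> float:
        return self.radii_mm[-1]


@lru_cache(maxsize=32)
def _shell_gains(head: HeadModel, n_max: int) -> np.ndarray:
    """Surface gain S_n per harmonic order for a unit source coefficient.

    With radii scaled by the scalp radius, the shell-1 potential is
    ``A1*x**n + x**-(n+1)`` (unit source term); the returned ``S[n]`` is the
    scalp-surface value ``A4 + B4`` of the transmitted solution.
    """
    R = head.scalp_radius_mm
    rho = np.asarray(head.radii_mm) / R  # rho[3] == 1
    s = np.asarray(head.conductivities, float)
    S = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3, A4, B4
        M = np.zeros((7, 7))
        rhs = np.zeros(7)
        pw = rho ** n
        nw = rho ** (-(n + 1))
        # interface i (0,1,2) between shell i+1 and i+2
        cols = {1: (0, None), 2: (1, 2), 3: (3, 4), 4: (5, 6)}
        row = 0
        for i in range(3):
            jin, jout = i + 1, i + 2
            ain, bin_ = cols[jin]
            aout, bout = cols[jout]
            # potential continuity
            M[row, ain] += pw[i]
            if bin_ is not None:
                M[row, bin_] += nw[i]
            M[row, aout] -= pw[i]
            M[row, bout] -= nw[i]
            rhs[row] = -nw[i] if jin == 1 else 0.0
            row += 1
            # radial current continuity: sigma * dV/dr
            M[row, ain] += s[jin - 1] * n * pw[i] / rho[i]
            if bin_ is not None:
                M[row, bin_] += -s[jin - 1] * (n + 1) * nw[i] / rho[i]
            M[row, aout] -= s[jout - 1] * n * pw[i] / rho[i]
            M[row, bout] -= -s[jout - 1] * (n + 1) * nw[i] / rho[i]
            rhs[row] = s[0] * (n + 1) * nw[i] / rho[i] if jin == 1 else 0.0
            row += 1
        # insulating scalp: dV4/dr = 0 at rho=1
        M[row, 5] = n
        M[row, 6] = -(n + 1)
        sol = np.linalg.solve(M, rhs)
        S[n] = sol[5] + sol[6]
    return S


def _legendre_pair(x: np.ndarray, n_max: int):
    """P_n(x) and P_n^1(x) for n = 0..n_max, scipy (Condon-Shortley) phase."""
    x = np.asarray(x, float)
    P = np.zeros((n_max + 1,) + x.shape)
    P1 = np.zeros_like(P)
    P[0] = 1.0
    if n_max >= 1:
        P[1] = x
        sx = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
        P1[1] = -sx
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        P1[n + 1] = ((2 * n + 1) * x * P1[n] - (n + 1) * P1[n - 1]) / n
    return P, P1


def _dipole_frame(position_mm: np.ndarray, moment: np.ndarray):
    """Rotate into the frame with the dipole on +z; return (b, m_r, m_t, zhat, xhat)."""
    p = np.asarray(position_mm, float)
    m = np.asarray(moment, float)
    b = float(np.linalg.norm(p))
    if b < 1e-9:
        mr = float(np.linalg.norm(m))
        zhat = m / mr if mr > 0 else np.array([0.0, 0.0, 1.0])
        return 0.0, mr, 0.0, zhat, _any_orthogonal(zhat)
    zhat = p / b
    mr = float(m @ zhat)
    t = m - mr * zhat
    mt = float(np.linalg.norm(t))
    xhat = t / mt if mt > 1e-12 * max(1.0, np.linalg.norm(m)) else _any_orthogonal(zhat)
    return b, mr, mt, zhat, xhat


def _any_orthogonal(v: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    a = a - (a @ v) * v
    return a / np.linalg.norm(a)


def _series_potential(
    electrodes_mm: np.ndarray,
    position_mm,
    moment,
    sigma1: float,
    R: float,
    gains: np.ndarray,
    n_max: int,
) -> np.ndarray:
    """Sum the harmonic series with per-order surface gains ``gains[n]``."""
    b, mr, mt, zhat, xhat = _dipole_frame(position_mm, moment)
    e = np.asarray(electrodes_mm, float)
    ehat = e / np.linalg.norm(e, axis=1, keepdims=True)
    cos_t = np.clip(ehat @ zhat, -1.0, 1.0)
    tang = ehat - cos_t[:, None] * zhat
    tnorm = np.linalg.norm(tang, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_phi = np.where(tnorm > 1e-12, (tang @ xhat) / np.where(tnorm > 0, tnorm, 1.0), 0.0)
    P, P1 = _legendre_pair(cos_t, n_max)
    ns = np.arange(1, n_max + 1, dtype=float)
    bh = b / R
    with np.errstate(divide="ignore"):
        ecc = np.where(ns - 1 == 0, 1.0, bh ** (ns - 1))
    coef = gains[1:] * ecc / (4.0 * np.pi * sigma1 * R * R)
    # tangential sign: with scipy's P_n^1 (Condon-Shortley), the infinite-medium
    # expansion is  V = sum_n (b^{n-1}/r^{n+1}) [ n m_r P_n - m_t P_n^1 cos(phi) ]
    V = (coef * ns * mr) @ P[1:] - (coef * mt) @ (P1[1:] * cos_phi[None, :])
    return V


def dipole_forward(
    position_mm,
    moment,
    head: HeadModel,
    montage: Montage,
    n_max: int = DEFAULT_N_MAX,
) -> Topography:
    """Scalp topography of a current dipole in the four-shell head model.

    The result is average-referenced.  ``position_mm`` must lie strictly
    inside the brain shell.
    """
    p = np.asarray(position_mm, float)
    if np.linalg.norm(p) >= head.brain_radius_mm:
        raise ValueError(
            f"dipole at |r|={np.linalg.norm(p):.1f} mm is outside the "
            f"{head.brain_radius_mm:.0f} mm brain shell"
        )
    gains = _shell_gains(head, n_max)
    V = _series_potential(
        montage.positions, p, moment, head.conductivities[0],
        head.scalp_radius_mm, gains, n_max,
    )
    return Topography(V - V.mean(), montage)


def single_sphere_potential(
    position_mm,
    moment,
    radius_mm: float,
    sigma: float,
    montage: Montage,
    n_max: int = DEFAULT_N_MAX,
) -> Topography:
    """Closed-form surface potential in a homogeneous conducting sphere.

    Independent of the shell solver: uses the published per-order boundary
    factor (2n+1)/n directly.  Average-referenced.
    """
    ns = np.arange(0, n_max + 1, dtype=float)
    gains = np.zeros(n_max + 1)
    gains[1:] = (2 * ns[1:] + 1) / ns[1:]
    V = _series_potential(
        montage.positions, position_mm, moment, sigma, radius_mm, gains, n_max
    )
    return Topography(V - V.mean(), montage)


def dipole_gain(
    position_mm, head: HeadModel, montage: Montage, n_max: int = DEFAULT_N_MAX
) -> np.ndarray:
    """(n_channels, 3) gain matrix: scalp maps of unit x/y/z moments."""
    cols = [
        dipole_forward(position_mm, m, head, montage, n_max).values
        for m in np.eye(3)
    ]
    return np.column_stack(cols)
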