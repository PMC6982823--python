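"""Convective and diffusive mass transfer around the extraction bed.

Dimensionless groups (Re, Sc, Sh), the packed-bed film-transfer power law
Sh = c0 * Re^c1 * Sc^(1/3), its calibration from observed Sherwood numbers,
a dense-gas estimate of the solute/CO2 binary diffusivity, and the unit
conversions between kf, kf*a0, Sh and D_AB that tie the kinetic fit to the
correlation. The characteristic length everywhere is the particle
diameter d_p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import (ALPHA_PINENE, CO2, FluidProperties, LAB_ASPECT_RATIO,
                        LAB_BULK_DENSITY, REYNOLDS_RANGE, SCHMIDT_RANGE)

__all__ = [
    "ValidityWindowWarning",
    "SherwoodCorrelation",
    "TransportState",
    "bed_diameter_from_feed",
    "reynolds",
    "schmidt",
    "sherwood",
    "kf_from_sherwood",
    "dab_from_kf",
    "a0_spheres",
    "dab_catchpole_king",
    "kfa0_from_correlation",
    "fit_sherwood",
]


class ValidityWindowWarning(UserWarning):
    """A dimensionless group left the stated validity window of the
    correlation (2 <= Re <= 60, 2 <= Sc <= 12)."""


@dataclass(frozen=True)
class SherwoodCorrelation:
    """Power-law film-transfer correlation Sh = c0 * Re^c1 * Sc^c2.

    The Schmidt exponent is fixed at 1/3; the Reynolds exponent is
    physically constrained to [0.5, 0.8].
    """

    c0: float
    c1: float
    c2: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if not 0.5 <= self.c1 <= 0.8:
            raise ValueError("c1 must lie in [0.5, 0.8]")
        if abs(self.c2 - 1.0 / 3.0) > 1e-12:
            raise ValueError("c2 is fixed at 1/3")


#: Correlation calibrated on the ten leaf-extraction runs.
FITTED_CORRELATION = SherwoodCorrelation(c0=0.0349, c1=0.58)


@dataclass(frozen=True)
class TransportState:
    """Bundle of transport quantities for one run."""

    Re: float
    Sc: float
    Sh: float
    D_AB: float
    u: float
    kf: float
    a0: float

    def __post_init__(self) -> None:
        for name in ("Re", "Sc", "Sh", "D_AB", "u", "kf", "a0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        _check_window(self.Re, self.Sc)


def _check_window(Re=None, Sc=None) -> None:
    if Re is not None and not REYNOLDS_RANGE[0] <= Re <= REYNOLDS_RANGE[1]:
        warnings.warn(f"Re = {Re:.3g} outside correlation validity window "
                      f"{REYNOLDS_RANGE}", ValidityWindowWarning,
                      stacklevel=3)
    if Sc is not None and not SCHMIDT_RANGE[0] <= Sc <= SCHMIDT_RANGE[1]:
        warnings.warn(f"Sc = {Sc:.3g} outside correlation validity window "
                      f"{SCHMIDT_RANGE}", ValidityWindowWarning,
                      stacklevel=3)


def bed_diameter_from_feed(N: float, bulk_density: float = LAB_BULK_DENSITY,
                           aspect_ratio: float = LAB_ASPECT_RATIO) -> float:
    """Bed diameter of a cylindrical bed holding ``N`` kg of solid at the
    given apparent density and aspect ratio H/d."""
    if N <= 0 or bulk_density <= 0 or aspect_ratio <= 0:
        raise ValueError("feed, density and aspect ratio must be positive")
    volume = N / bulk_density
    return (4.0 * volume / (np.pi * aspect_ratio)) ** (1.0 / 3.0)


def reynolds(system, bed_diameter: float) -> float:
    """Particle Reynolds number Re = rho_f * u * d_p / mu_f with the
    superficial velocity u = Q / (rho_f * pi * d_bed^2 / 4)."""
    if bed_diameter <= 0:
        raise ValueError("bed diameter must be positive")
    area = np.pi * bed_diameter ** 2 / 4.0
    u = system.Q / (system.rho_f * area)
    Re = system.rho_f * u * system.d_p / system.mu_f
    _check_window(Re=Re)
    return Re


def superficial_velocity(system, bed_diameter: float) -> float:
    """Superficial (empty-tube) solvent velocity, m/s."""
    if bed_diameter <= 0:
        raise ValueError("bed diameter must be positive")
    return system.Q / (system.rho_f * np.pi * bed_diameter ** 2 / 4.0)


def schmidt(mu_f: float, rho_f: float, D_AB: float) -> float:
    """Schmidt number Sc = mu_f / (rho_f * D_AB)."""
    if mu_f <= 0 or rho_f <= 0 or D_AB <= 0:
        raise ValueError("mu_f, rho_f and D_AB must be positive")
    Sc = mu_f / (rho_f * D_AB)
    _check_window(Sc=Sc)
    return Sc


def sherwood(Re: float, Sc: float, corr: SherwoodCorrelation) -> float:
    """Sh = c0 * Re^c1 * Sc^c2 for positive Re and Sc."""
    if Re <= 0 or Sc <= 0:
        raise ValueError("Re and Sc must be positive")
    return corr.c0 * Re ** corr.c1 * Sc ** corr.c2


def kf_from_sherwood(Sh: float, D_AB: float, d_p: float) -> float:
    """Film coefficient kf = Sh * D_AB / d_p, m/s."""
    if Sh <= 0 or D_AB <= 0 or d_p <= 0:
        raise ValueError("Sh, D_AB and d_p must be positive")
    return Sh * D_AB / d_p


def dab_from_kf(kf: float, Sh: float, d_p: float) -> float:
    """Inverse of :func:`kf_from_sherwood`: D_AB = kf * d_p / Sh."""
    if kf <= 0 or Sh <= 0 or d_p <= 0:
        raise ValueError("kf, Sh and d_p must be positive")
    return kf * d_p / Sh


def a0_spheres(d_p: float, eps: float, basis: str = "bed") -> float:
    """Specific interfacial area of a bed of spheres, m-1.

    basis="bed" gives a0 = 6*(1-eps)/d_p per unit bed volume (default);
    basis="particle" gives a0 = 6/d_p per unit particle volume.
    """
    if d_p <= 0:
        raise ValueError("d_p must be positive")
    if not 0 < eps < 1:
        raise ValueError("eps must lie in (0, 1)")
    if basis == "bed":
        return 6.0 * (1.0 - eps) / d_p
    if basis == "particle":
        return 6.0 / d_p
    raise ValueError("basis must be 'bed' or 'particle'")


def dab_catchpole_king(T: float, rho_f: float,
                       solute: FluidProperties = ALPHA_PINENE,
                       solvent: FluidProperties = CO2) -> float:
    """Dense-gas estimate of the solute/solvent binary diffusivity, m2/s.

    Near-critical self-diffusivity of the solvent scaled to the binary
    pair:

        D11 = 5.152 * Dc * Tr * (rho_r^(-2/3) - 0.4510)
        D12 = D11 / X,   X = (1 + (Vc2/Vc1)^(1/3))^2 / (1 + M1/M2)^(1/2)

    with Dc = 4.300e-7 * Tc^0.75 / (M^0.5 * rho_c^(2/3)) (SI units, molar
    mass in g/mol). The reduced-density term carries the whole pressure
    dependence; it is validated for 1 < rho_r < 2.5 and the size/mass
    ratio X for 2 < X < 10 — values outside are flagged, not rejected.
    """
    if T <= 0 or rho_f <= 0:
        raise ValueError("T and rho_f must be positive")
    Tr = T / solvent.Tc
    rho_r = rho_f / solvent.rho_c
    if not 1.0 <= rho_r <= 2.5:
        warnings.warn(f"reduced density {rho_r:.2f} outside the stated "
                      "validity range of the dense-gas correlation",
                      ValidityWindowWarning, stacklevel=2)
    term = rho_r ** (-2.0 / 3.0) - 0.4510
    if term <= 0:
        raise ValueError("density too high for the dense-gas correlation")
    M_g_mol = solvent.M * 1e3
    Dc = 4.300e-7 * solvent.Tc ** 0.75 / (M_g_mol ** 0.5
                                          * solvent.rho_c ** (2.0 / 3.0))
    D11 = 5.152 * Dc * Tr * term
    X = (1.0 + (solute.Vc / solvent.Vc) ** (1.0 / 3.0)) ** 2 / (
        1.0 + solvent.M / solute.M) ** 0.5
    if not 2.0 <= X <= 10.0:
        warnings.warn(f"size/mass ratio X = {X:.2f} outside [2, 10]",
                      ValidityWindowWarning, stacklevel=2)
    return D11 / X


def kfa0_from_correlation(system, bed_diameter: float | None = None,
                          corr: SherwoodCorrelation = FITTED_CORRELATION,
                          D_AB: float | None = None,
                          a0_basis: str = "bed") -> TransportState:
    """External volumetric transfer parameter kf*a0 predicted from the
    film correlation for one run.

    Chains D_AB -> Sc, bed geometry -> Re, the correlation -> Sh -> kf,
    and the spheres rule -> a0. Returns the full :class:`TransportState`;
    the product ``state.kf * state.a0`` is the kfa0 to hold fixed in the
    correlation-based kinetic fit.
    """
    if bed_diameter is None:
        bed_diameter = bed_diameter_from_feed(system.N)
    if D_AB is None:
        D_AB = dab_catchpole_king(system.T, system.rho_f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWindowWarning)
        Re = reynolds(system, bed_diameter)
        Sc = schmidt(system.mu_f, system.rho_f, D_AB)
        Sh = sherwood(Re, Sc, corr)
        kf = kf_from_sherwood(Sh, D_AB, system.d_p)
        a0 = a0_spheres(system.d_p, system.eps, basis=a0_basis)
        u = superficial_velocity(system, bed_diameter)
        return TransportState(Re=Re, Sc=Sc, Sh=Sh, D_AB=D_AB, u=u, kf=kf,
                              a0=a0)


def fit_sherwood(points, clip: bool = True) -> tuple[SherwoodCorrelation,
                                                     dict]:
    """Calibrate (c0, c1) of the power law from (Re, Sc, Sh) triples.

    A power law is linear in logs, so the fit is ordinary least squares of
    log(Sh / Sc^(1/3)) on log(Re). The Schmidt exponent stays fixed at
    1/3. If the slope falls outside the physical window [0.5, 0.8] it is
    clipped there and the prefactor re-estimated with the slope held
    fixed. Returns the correlation and a diagnostics dict.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("need at least two (Re, Sc, Sh) points")
    if np.any(pts <= 0):
        raise ValueError("Re, Sc and Sh must all be positive")
    Re, Sc, Sh = pts.T
    if np.ptp(np.log(Re)) < 1e-12:
        raise ValueError("all Re equal: exponent not identifiable")
    y = np.log(Sh) - np.log(Sc) / 3.0
    A = np.column_stack([np.ones_like(Re), np.log(Re)])
    (b0, b1), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    clipped = False
    if clip and not 0.5 <= b1 <= 0.8:
        b1 = float(np.clip(b1, 0.5, 0.8))
        b0 = float(np.mean(y - b1 * np.log(Re)))
        clipped = True
    corr = SherwoodCorrelation(c0=float(np.exp(b0)), c1=float(b1))
    resid = y - (b0 + b1 * np.log(Re))
    diagnostics = {"n": int(pts.shape[0]), "clipped": clipped,
                   "rmse_log": float(np.sqrt(np.mean(resid ** 2)))}
    return corr, diagnostics
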