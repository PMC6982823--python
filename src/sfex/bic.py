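"""Broken-and-intact-cell (BIC) model of packed-bed supercritical extraction.

Milling breaks a fraction ``G`` of the plant cells; their solute is freely
accessible and leaves through the fluid film, while solute in intact cells
must first diffuse through the solid. The cumulative extraction curve
``e(psi) = E/(N*x0)`` is the classical three-period analytical solution:

1. film-limited (constant-rate) period for ``psi < G/Z``,
2. transition period while the broken/intact boundary ``h_k`` travels up
   the bed, ``G/Z <= psi < psi_k``,
3. diffusion-limited period for ``psi >= psi_k``.

``psi`` is extraction time scaled by the solvent's carrying capacity,
``Z`` and ``Y`` are the external and internal volumetric transfer groups.
All curve functions are vectorised over ``psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtractionSystem",
    "BICParameters",
    "DimensionlessState",
    "ExtractionCurve",
    "dimensionless_time",
    "transfer_groups",
    "psi_k",
    "h_k",
    "extraction_fraction",
    "simulate_curve",
    "yield_percent",
]

# exp() overflow guard for the Y*(psi - G/Z) exponent
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class ExtractionSystem:
    """Bed, feed, solvent and solubility constants defining one run.

    Parameters
    ----------
    N : float
        Feed mass of milled solid, kg.
    x0 : float
        Initial extractable-oil mass fraction of the solid, kg/kg.
    ys : float
        Oil solubility in the solvent, kg oil per kg CO2.
    Q : float
        Solvent mass flow, kg/s.
    eps : float
        Bed void fraction.
    rho_s : float
        Solid (true) density, kg/m3.
    rho_f : float
        Solvent density at extraction conditions, kg/m3.
    d_p : float
        Mean particle diameter, m.
    T : float
        Temperature, K.
    P : float
        Pressure, Pa.
    mu_f : float
        Solvent dynamic viscosity, kg m-1 s-1.
    """

    N: float
    x0: float
    ys: float
    Q: float
    eps: float
    rho_s: float
    rho_f: float
    d_p: float
    T: float = 313.15
    P: float = 22.0e6
    mu_f: float = 8.18e-5

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("feed mass N must be positive")
        if not 0 < self.x0 < 1:
            raise ValueError("x0 must lie in (0, 1)")
        if self.ys <= 0:
            raise ValueError("solubility ys must be positive")
        if self.Q <= 0:
            raise ValueError("solvent flow Q must be positive")
        if not 0 < self.eps < 1:
            raise ValueError("void fraction eps must lie in (0, 1)")
        if not self.rho_s > self.rho_f > 0:
            raise ValueError("densities must satisfy rho_s > rho_f > 0")
        if self.d_p <= 0:
            raise ValueError("particle diameter d_p must be positive")


@dataclass(frozen=True)
class BICParameters:
    """The three adjustable kinetic parameters.

    G is the grinding efficiency (fraction of broken cells); ksa0 and kfa0
    are the internal and external volumetric mass-transfer parameters, s-1.
    """

    G: float
    ksa0: float
    kfa0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.G <= 1.0:
            raise ValueError("G must lie in [0, 1]")
        if self.ksa0 <= 0:
            raise ValueError("ksa0 must be positive")
        if self.kfa0 <= 0:
            raise ValueError("kfa0 must be positive")


@dataclass(frozen=True)
class DimensionlessState:
    """Dimensionless groups of one run: psi, Z, Y, psi_k and h_k."""

    psi: float
    Z: float
    Y: float
    psi_k: float
    h_k: float


@dataclass
class ExtractionCurve:
    """Sampled cumulative extract mass versus time.

    provenance is one of ``measured``, ``synthetic`` (noisy generator
    output) or ``simulated`` (noiseless forward model).
    """

    times: np.ndarray
    masses: np.ndarray
    system: ExtractionSystem
    provenance: str = "measured"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.shape != self.masses.shape or self.times.ndim != 1:
            raise ValueError("times and masses must be 1-D and equal length")
        if self.times.size and (self.times[0] < 0
                                or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be strictly increasing and >= 0")
        if self.provenance not in ("measured", "synthetic", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if np.any(self.masses < 0):
            raise ValueError("masses must be non-negative")
        if self.provenance == "simulated":
            limit = self.system.N * self.system.x0
            if np.any(np.diff(self.masses) < -1e-15) or np.any(
                    self.masses > limit * (1 + 1e-12)):
                raise ValueError("simulated masses must be non-decreasing "
                                 "and bounded by N*x0")

    @property
    def fractions(self) -> np.ndarray:
        """e = E/(N*x0), the extracted fraction at each sample."""
        return self.masses / (self.system.N * self.system.x0)


def dimensionless_time(t, system: ExtractionSystem):
    """psi = t*Q*ys/(N*x0); linear and homogeneous in t (t in seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    psi = t * system.Q * system.ys / (system.N * system.x0)
    return psi if psi.ndim else float(psi)


def time_from_psi(psi, system: ExtractionSystem):
    """Inverse of :func:`dimensionless_time`."""
    return np.asarray(psi, dtype=float) * system.N * system.x0 / (
        system.Q * system.ys)


def transfer_groups(system: ExtractionSystem,
                    params: BICParameters) -> tuple[float, float]:
    """External and internal transfer groups.

    Z = N*kfa0*rho_f / (Q*(1-eps)*rho_s)
    Y = N*ksa0*x0   / (Q*(1-eps)*ys)
    """
    denom = system.Q * (1.0 - system.eps)
    Z = system.N * params.kfa0 * system.rho_f / (denom * system.rho_s)
    Y = system.N * params.ksa0 * system.x0 / (denom * system.ys)
    return Z, Y


def psi_k(G: float, Z: float, Y: float) -> float:
    """Dimensionless time at which the broken/intact boundary reaches the
    bed outlet (onset of the diffusion-limited period).

    psi_k = G/Z + (1/Y)*ln(1 + G*(e^Y - 1)); the log argument is >= 1 for
    valid inputs, so psi_k >= G/Z always.
    """
    if Z <= 0 or Y <= 0:
        raise ValueError("Z and Y must be positive")
    if not 0.0 <= G <= 1.0:
        raise ValueError("G must lie in [0, 1]")
    return G / Z + np.log1p(G * np.expm1(min(Y, _EXP_CLIP))) / Y


def h_k(psi, G: float, Z: float, Y: float):
    """Dimensionless bed coordinate of the broken/intact boundary.

    h_k = (1/Y)*ln(1 + (e^{Y*(psi - G/Z)} - 1)/G), defined on
    psi in [G/Z, psi_k]. Substituting psi = psi_k gives
    (1/Y)*ln(1 + G*(e^Y-1)/G) = 1 exactly, which is the boundary identity
    the period-2/period-3 continuity of the curve rests on.
    """
    if G <= 0:
        raise ValueError("h_k requires G > 0")
    pk = psi_k(G, Z, Y)
    psi = np.asarray(psi, dtype=float)
    lo, hi = G / Z, pk
    tol = 1e-9 * max(1.0, hi)
    if np.any(psi < lo - tol) or np.any(psi > hi + tol):
        raise ValueError("psi outside [G/Z, psi_k]")
    arg = np.clip(Y * (psi - lo), None, _EXP_CLIP)
    out = np.log1p(np.expm1(arg) / G) / Y
    return out if out.ndim else float(out)


def extraction_fraction(psi, G: float, Z: float, Y: float):
    """Extracted fraction e = E/(N*x0) of the three-period solution.

    period 1: e = psi*(1 - e^{-Z})                       for psi <  G/Z
    period 2: e = psi - (G/Z)*e^{Z*(h_k - 1)}            for G/Z <= psi < psi_k
    period 3: e = 1 - (1/Y)*ln{1 + (e^Y - 1)*e^{Y*(G/Z - psi)}*(1 - G)}
                                                         for psi >= psi_k

    Boundary points belong to the later period; the branches agree there,
    so the curve is continuous and non-decreasing with e(0)=0 and e->1.
    """
    if not 0.0 <= G <= 1.0:
        raise ValueError("G must lie in [0, 1]")
    if Z <= 0 or Y <= 0:
        raise ValueError("Z and Y must be positive")
    scalar = np.ndim(psi) == 0
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    if np.any(psi < 0):
        raise ValueError("psi must be non-negative")

    lo = G / Z
    pk = psi_k(G, Z, Y)
    e = np.empty_like(psi)

    m1 = psi < lo
    m3 = psi >= pk
    m2 = ~m1 & ~m3

    e[m1] = psi[m1] * -np.expm1(-Z)
    if np.any(m2):
        hk = h_k(psi[m2], G, Z, Y)
        e[m2] = psi[m2] - lo * np.exp(Z * (np.asarray(hk) - 1.0))
    if np.any(m3):
        expY = np.expm1(min(Y, _EXP_CLIP))
        decay = np.exp(np.clip(Y * (lo - psi[m3]), -_EXP_CLIP, 0.0))
        e[m3] = 1.0 - np.log1p(expY * decay * (1.0 - G)) / Y
    return float(e[0]) if scalar else e


def simulate_curve(time_grid, system: ExtractionSystem,
                   params: BICParameters) -> ExtractionCurve:
    """Forward-simulate the cumulative extract mass on a time grid (s)."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing and >= 0")
    Z, Y = transfer_groups(system, params)
    psi = dimensionless_time(t, system)
    e = extraction_fraction(psi, params.G, Z, Y)
    masses = system.N * system.x0 * np.asarray(e)
    # clip the 1e-16-level negatives of the branch arithmetic
    masses = np.clip(masses, 0.0, system.N * system.x0)
    np.maximum.accumulate(masses, out=masses)
    return ExtractionCurve(times=t, masses=masses, system=system,
                           provenance="simulated")


def yield_percent(mass_extract: float, mass_raw: float) -> float:
    """Gravimetric yield, wt% = 100 * extract mass / raw feed mass."""
    if mass_raw <= 0:
        raise ValueError("raw-material mass must be positive")
    if mass_extract < 0:
        raise ValueError("extract mass must be non-negative")
    return 100.0 * mass_extract / mass_raw
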