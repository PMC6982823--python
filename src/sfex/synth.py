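"""Synthetic-data generators.

The study's raw kinetic weighings were never deposited, so the package
generates stand-in extraction curves with the statistical structure the
analysis assumes: the BIC forward model sampled every 30 min over 8 h
plus additive Gaussian weighing noise on the cumulative mass. A
design-table generator plays the same role for the response-surface
stage. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .bic import (BICParameters, ExtractionCurve, ExtractionSystem,
                  simulate_curve, transfer_groups)
from .constants import (LAB_FEED_KG, LAB_SOLID_DENSITY, LAB_TEMPERATURE,
                        LAB_VOID_FRACTION, SAMPLING_INTERVAL_S)

__all__ = ["CurveGenSpec", "DoeGenSpec", "gen_curve",
           "gen_paper_fixture_curves", "experiment_system", "gen_doe",
           "DEFAULT_DURATION_S"]

#: Default run length of a synthetic kinetic experiment, s (8 h).
DEFAULT_DURATION_S = 8 * 3600.0
#: Fraction of the run spent in the film-limited first period in the
#: packaged fixture curves (places the period-1/2 crossover at 2 h so all
#: three extraction periods fall inside the sampled window).
_FIXTURE_CER_FRACTION = 0.25


@dataclass(frozen=True)
class CurveGenSpec:
    """Recipe for one synthetic extraction curve."""

    system: ExtractionSystem
    params: BICParameters
    sampling_interval: float = SAMPLING_INTERVAL_S
    duration: float = DEFAULT_DURATION_S
    noise_sigma: float = 0.01       # fraction of N*x0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0 or self.duration <= 0:
            raise ValueError("interval and duration must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class DoeGenSpec:
    """Recipe for a synthetic design-of-experiments response."""

    coefficients: dict
    coded: pd.DataFrame = field(hash=False)
    noise_sigma: float = 0.0        # % yield
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def gen_curve(spec: CurveGenSpec) -> ExtractionCurve:
    """Sample the forward model and add i.i.d. Gaussian weighing noise.

    Noise applies to the cumulative mass (each weighing is independent),
    so noisy curves are NOT re-monotonised; values are clipped at zero.
    Reproducible from the seed.
    """
    t = np.arange(spec.sampling_interval, spec.duration
                  + 0.5 * spec.sampling_interval, spec.sampling_interval)
    clean = simulate_curve(t, spec.system, spec.params)
    if spec.noise_sigma == 0:
        return ExtractionCurve(times=t, masses=clean.masses,
                               system=spec.system, provenance="synthetic")
    rng = np.random.default_rng(spec.seed)
    scale = spec.noise_sigma * spec.system.N * spec.system.x0
    masses = np.clip(clean.masses + rng.normal(0.0, scale, t.size),
                     0.0, None)
    return ExtractionCurve(times=t, masses=masses, system=spec.system,
                           provenance="synthetic")


def _fixture_ys(G: float, Z: float, N: float, x0: float, Q: float,
                t_cer: float) -> float:
    """Solubility placeholder putting the period-1/2 crossover at t_cer.

    psi(t_cer) = G/Z  <=>  ys = (G/Z) * N * x0 / (Q * t_cer).
    """
    return (G / Z) * N * x0 / (Q * t_cer)


def experiment_system(exp: int,
                      conditions: pd.DataFrame | None = None,
                      yields: pd.DataFrame | None = None,
                      params: BICParameters | None = None,
                      duration: float = DEFAULT_DURATION_S
                      ) -> tuple[ExtractionSystem, BICParameters]:
    """Bed/solvent description of one study run, with its curve-fitted
    kinetic parameters.

    x0 is the asymptotic-extraction convention (final yield / 100); the
    unpublished solubility ys is set so the film-limited period ends a
    quarter into the run, keeping all three periods inside the sampled
    window (see the methods note).
    """
    conditions = datasets.load_conditions() if conditions is None \
        else conditions
    yields = datasets.load_yields() if yields is None else yields
    crow = conditions.set_index("experiment").loc[exp]
    yrow = yields.set_index("experiment").loc[exp]

    if params is None:
        prow = datasets.load_bic_parameters().set_index("experiment")\
            .loc[exp]
        krow = datasets.load_external_transfer().set_index("experiment")\
            .loc[exp]
        params = BICParameters(G=float(prow["G_fitted"]),
                               ksa0=float(prow["ksa0_1e5_fitted"]) * 1e-5,
                               kfa0=float(krow["kfa0_1e3_fitted"]) * 1e-3)

    N = LAB_FEED_KG
    x0 = float(yrow["yield_pct"]) / 100.0
    Q = float(crow["q_co2_kg_h"]) / 3600.0
    rho_f = float(crow["rho_co2_kg_m3"])
    # Z does not involve ys, so the crossover time can be pinned first
    denom = Q * (1.0 - LAB_VOID_FRACTION)
    Z = N * params.kfa0 * rho_f / (denom * LAB_SOLID_DENSITY)
    ys = _fixture_ys(params.G, Z, N, x0, Q,
                     t_cer=_FIXTURE_CER_FRACTION * duration)
    system = ExtractionSystem(
        N=N, x0=x0, ys=ys, Q=Q, eps=LAB_VOID_FRACTION,
        rho_s=LAB_SOLID_DENSITY, rho_f=rho_f,
        d_p=float(crow["dp_um"]) * 1e-6, T=LAB_TEMPERATURE,
        P=float(crow["pressure_bar"]) * 1e5,
        mu_f=float(crow["mu_co2_kg_m_s"]))
    return system, params


def gen_paper_fixture_curves(param_table: pd.DataFrame | None = None,
                             conditions_table: pd.DataFrame | None = None,
                             duration: float = DEFAULT_DURATION_S,
                             sampling_interval: float = SAMPLING_INTERVAL_S,
                             noise_sigma: float = 0.0, seed: int = 0
                             ) -> list[tuple[int, ExtractionCurve,
                                             BICParameters]]:
    """One synthetic curve per study run (default: noiseless, 8 h,
    30 min sampling), generated from each run's curve-fitted parameters
    under its bed conditions. Returns (experiment, curve, truth) tuples.
    """
    conditions = datasets.load_conditions() if conditions_table is None \
        else conditions_table
    if param_table is not None:
        param_table = param_table.set_index("experiment") \
            if "experiment" in param_table.columns else param_table
    out = []
    for i, exp in enumerate(conditions["experiment"]):
        params = None
        if param_table is not None:
            prow = param_table.loc[exp]
            params = BICParameters(G=float(prow["G"]),
                                   ksa0=float(prow["ksa0"]),
                                   kfa0=float(prow["kfa0"]))
        system, params = experiment_system(int(exp),
                                           conditions=conditions,
                                           params=params,
                                           duration=duration)
        spec = CurveGenSpec(system=system, params=params,
                            sampling_interval=sampling_interval,
                            duration=duration, noise_sigma=noise_sigma,
                            seed=seed + i)
        out.append((int(exp), gen_curve(spec), params))
    return out


def gen_doe(spec: DoeGenSpec):
    """Synthetic design-table response: yields = X*a + noise.

    Returns an :class:`sfex.rsm.DesignTable`; the coefficient dict keys
    follow the model-term names (a0 ... a23), missing terms default to 0.
    """
    from .rsm import DesignTable, TERMS, model_matrix
    coded = pd.DataFrame(spec.coded, columns=["x1", "x2", "x3"])
    a = np.array([float(spec.coefficients.get(t, 0.0)) for t in TERMS])
    X = model_matrix(coded)
    y = X @ a
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sigma, y.size)
    return DesignTable(coded=coded, yields=y)
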