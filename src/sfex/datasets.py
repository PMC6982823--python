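"""Packaged study tables.

The design, yield, kinetic-parameter, transport and cost tables of the
ten-run leaf-extraction study ship as small CSV fixtures so every stage
of the pipeline can be exercised offline. Loaders return fresh pandas
DataFrames.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["available", "load", "checksum",
           "load_conditions", "load_factor_levels", "load_vessel_costs",
           "load_yields", "load_coded_design", "load_rsm_coefficients",
           "load_coef_correlations", "load_bic_parameters",
           "load_external_transfer", "load_sherwood_fit",
           "load_com_reference"]

_FILES = (
    "sfe_conditions.csv",
    "factor_levels.csv",
    "vessel_costs.csv",
    "yields.csv",
    "coded_design.csv",
    "rsm_coefficients.csv",
    "coef_correlations.csv",
    "bic_parameters.csv",
    "external_transfer.csv",
    "sherwood_fit.csv",
    "com_reference.csv",
)


def available() -> tuple[str, ...]:
    """Names of the packaged tables."""
    return _FILES


def _path(name: str):
    if name not in _FILES:
        raise KeyError(f"unknown dataset {name!r}; see available()")
    return resources.files("sfex.data").joinpath(name)


@lru_cache(maxsize=None)
def _load_cached(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p)


def load(name: str) -> pd.DataFrame:
    """Load a packaged table by file name."""
    return _load_cached(name).copy()


def checksum(name: str) -> str:
    """SHA-256 of the packaged CSV bytes."""
    return hashlib.sha256(_path(name).read_bytes()).hexdigest()


def load_conditions() -> pd.DataFrame:
    """Run conditions: pressure, particle size, flow, CO2 density and
    viscosity for the ten experiments."""
    df = load("sfe_conditions.csv")
    df["mu_co2_kg_m_s"] = df.pop("mu_co2_1e5_kg_m_s") * 1e-5
    return df


def load_factor_levels() -> pd.DataFrame:
    """Coded-factor ranges (low/high per factor)."""
    return load("factor_levels.csv")


def load_vessel_costs() -> pd.DataFrame:
    """Installed cost and geometry of each SFE vessel size (CEPCI 580)."""
    return load("vessel_costs.csv")


def load_yields() -> pd.DataFrame:
    """Observed extraction yields (3 decimals) with natural factors."""
    return load("yields.csv")


def load_coded_design() -> pd.DataFrame:
    """Coded design (x1=pressure, x2=particle size, x3=flow) with the
    2-decimal design yields."""
    return load("coded_design.csv")


def load_rsm_coefficients() -> pd.DataFrame:
    """Published regression coefficients and t statistics."""
    return load("rsm_coefficients.csv")


def load_coef_correlations() -> pd.DataFrame:
    """Published 6x6 between-term correlation matrix."""
    return load("coef_correlations.csv").set_index("term")


def load_bic_parameters() -> pd.DataFrame:
    """G and ksa0 per experiment (correlation-based and curve-fitted
    columns); ksa0 columns are scaled by 1e5."""
    return load("bic_parameters.csv")


def load_external_transfer() -> pd.DataFrame:
    """kfa0 (x1e3 s-1) and D_AB (x1e9 m2/s) per experiment for both
    estimation routes."""
    return load("external_transfer.csv")


def load_sherwood_fit() -> pd.DataFrame:
    """Sherwood numbers and kinetic-fit R^2 (%) per experiment."""
    return load("sherwood_fit.csv")


def load_com_reference() -> pd.DataFrame:
    """Published specific manufacturing cost over volume x yield."""
    return load("com_reference.csv").set_index("volume_m3")
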