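"""Cost-of-manufacturing (COM) model for scaled-up batch SFE plants.

Annualised production cost by the fixed-multiplier method,

    COM = 0.340*FCI + 2.73*C_OL + 1.23*(C_UT + C_WT + C_RM),

with FCI the installed fixed capital of a two-vessel plant (tabulated per
vessel volume at CEPCI 580), C_OL the operating-labor payroll, C_UT the
electricity bill of the solvent cycle, C_WT the waste-treatment cost
(zero: CO2 is recycled and spent leaves are reused) and C_RM the raw
materials (leaves, make-up CO2, cleaning ethanol). Dividing by the annual
extract mass gives the specific cost in USD per kg of extract; because
COM itself does not depend on the yield, the specific cost is exactly
inversely proportional to it.

The solvent flow of the large vessel comes from the kinetic-similarity
scale-up rule Q2/Q1 = (F2/F1)^2 * (HB1/HB2) * (dB1/dB2) anchored at the
laboratory bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .constants import (CEPCI_REF, DEFAULT_ANNUAL_HOURS, DEFAULT_CO2_LOSS,
                        DEFAULT_PRICES, LAB_ASPECT_RATIO, LAB_BULK_DENSITY,
                        LAB_FEED_KG, SCALE_BED_DENSITY, SCALE_LAB_FLOW,
                        SPECIFIC_ENERGIES_KJ_KG)
from .transport import bed_diameter_from_feed

__all__ = ["CostScenario", "CostBreakdown", "fci_lookup", "vessel_geometry",
           "scale_up_flow", "scaled_solvent_flow", "annual_balance",
           "cost_breakdown", "com_matrix"]

KJ_PER_MWH = 3.6e6


@dataclass(frozen=True)
class CostScenario:
    """Plant geometry, schedule, prices and energies for one COM case."""

    vessel_volume: float = 0.1            # m3
    n_vessels: int = 2
    batch_time: float = 1.0               # h
    annual_hours: float = DEFAULT_ANNUAL_HOURS
    bed_density: float = SCALE_BED_DENSITY
    yield_pct: float = 0.3
    prices: dict = field(default_factory=lambda: dict(DEFAULT_PRICES))
    specific_energies: dict = field(
        default_factory=lambda: dict(SPECIFIC_ENERGIES_KJ_KG))
    co2_loss_frac: float = DEFAULT_CO2_LOSS
    workers_per_shift: int = 2
    shifts_per_day: int = 3
    labor_convention: str = "on_duty"     # or "headcount"
    ethanol_kg_per_year: float = 0.0
    cepci_ref: float = CEPCI_REF
    cepci_now: float = CEPCI_REF
    solvent_flow: float | None = None     # kg/s; None -> scale-up rule

    def __post_init__(self) -> None:
        if min(self.vessel_volume, self.batch_time, self.annual_hours,
               self.bed_density, self.yield_pct, self.cepci_now) <= 0:
            raise ValueError("scenario quantities must be positive")
        if not 0 <= self.co2_loss_frac < 1:
            raise ValueError("co2_loss_frac must lie in [0, 1)")
        if self.labor_convention not in ("on_duty", "headcount"):
            raise ValueError("labor_convention must be on_duty|headcount")


@dataclass(frozen=True)
class CostBreakdown:
    """Annual cost categories and the resulting specific cost."""

    fci_usd: float
    c_ol: float
    c_ut: float
    c_wt: float
    c_rm: float
    com: float
    extract_kg: float
    com_per_kg: float

    def shares(self) -> dict:
        """Percentage contribution of each weighted category to COM."""
        parts = {"FCI": 0.340 * self.fci_usd, "labor": 2.73 * self.c_ol,
                 "utilities": 1.23 * self.c_ut, "waste": 1.23 * self.c_wt,
                 "raw_material": 1.23 * self.c_rm}
        return {k: 100.0 * v / self.com for k, v in parts.items()}


def fci_lookup(vessel_volume: float,
               cepci_now: float = CEPCI_REF) -> float:
    """Installed fixed capital of one SFE unit, USD.

    Exact tabulated value at the tabulated vessel volumes, log-log
    interpolation between them, scaled linearly by CEPCI from the
    reference index 580. Volumes outside [0.1, 1.0] m3 are rejected.
    """
    if vessel_volume <= 0 or cepci_now <= 0:
        raise ValueError("volume and CEPCI must be positive")
    table = datasets.load_vessel_costs()
    vols = table["volume_l"].to_numpy(dtype=float) / 1e3
    fci = table["fci_usd"].to_numpy(dtype=float)
    if not vols[0] - 1e-12 <= vessel_volume <= vols[-1] + 1e-12:
        raise ValueError(f"volume {vessel_volume} m3 outside the tabulated "
                         f"range [{vols[0]}, {vols[-1]}]")
    base = float(np.exp(np.interp(np.log(vessel_volume), np.log(vols),
                                  np.log(fci))))
    return base * cepci_now / CEPCI_REF


def vessel_geometry(vessel_volume: float) -> tuple[float, float]:
    """(height, diameter) in m of a tabulated vessel volume."""
    table = datasets.load_vessel_costs()
    vols = table["volume_l"].to_numpy(dtype=float) / 1e3
    H = float(np.interp(vessel_volume, vols, table["height_m"]))
    d = float(np.interp(vessel_volume, vols, table["diameter_m"]))
    return H, d


def scale_up_flow(Q1: float, F1: float, F2: float, HB1: float, HB2: float,
                  dB1: float, dB2: float) -> float:
    """Solvent flow preserving the laboratory kinetics in a larger bed:

    Q2 = Q1 * (F2/F1)^2 * (HB1/HB2) * (dB1/dB2)
    """
    vals = (Q1, F1, F2, HB1, HB2, dB1, dB2)
    if min(vals) <= 0:
        raise ValueError("all scale-up anchors must be positive")
    return Q1 * (F2 / F1) ** 2 * (HB1 / HB2) * (dB1 / dB2)


def scaled_solvent_flow(scenario: CostScenario) -> float:
    """CO2 flow (kg/s) of one scaled vessel from the laboratory anchors,
    unless the scenario pins an explicit flow."""
    if scenario.solvent_flow is not None:
        return scenario.solvent_flow
    d_lab = bed_diameter_from_feed(LAB_FEED_KG)
    H_lab = LAB_ASPECT_RATIO * d_lab
    H2, d2 = vessel_geometry(scenario.vessel_volume)
    F2 = scenario.bed_density * scenario.vessel_volume
    return scale_up_flow(SCALE_LAB_FLOW, LAB_FEED_KG, F2, H_lab, H2,
                         d_lab, d2)


def annual_balance(scenario: CostScenario) -> dict:
    """Yearly mass and schedule balance of the plant.

    The two vessels alternate extraction and reconditioning, so one bed
    is always extracting: batches/yr = annual_hours / batch_time.
    """
    batches = scenario.annual_hours / scenario.batch_time
    feed_per_batch = scenario.bed_density * scenario.vessel_volume
    feed = batches * feed_per_batch
    extract = feed * scenario.yield_pct / 100.0
    Q2 = scaled_solvent_flow(scenario)
    circulated = Q2 * scenario.batch_time * 3600.0 * batches
    return {
        "batches_per_year": batches,
        "feed_kg_per_batch": feed_per_batch,
        "feed_kg_per_year": feed,
        "extract_kg_per_year": extract,
        "solvent_flow_kg_s": Q2,
        "co2_circulated_kg_per_year": circulated,
        "co2_makeup_kg_per_year": scenario.co2_loss_frac * circulated,
    }


def cost_breakdown(scenario: CostScenario) -> CostBreakdown:
    """Evaluate every cost category and the COM of one scenario."""
    bal = annual_balance(scenario)
    fci = fci_lookup(scenario.vessel_volume, scenario.cepci_now)
    prices = scenario.prices

    if scenario.labor_convention == "on_duty":
        # 2 workers on duty at all times
        paid_hours = scenario.workers_per_shift * scenario.annual_hours
    else:
        # full headcount (workers_per_shift * shifts) each paid for every
        # operating hour
        paid_hours = (scenario.workers_per_shift * scenario.shifts_per_day
                      * scenario.annual_hours)
    c_ol = prices["labor_usd_h"] * paid_hours

    energy_kj_per_kg = sum(abs(v) for v in
                           scenario.specific_energies.values())
    mwh = energy_kj_per_kg * bal["co2_circulated_kg_per_year"] / KJ_PER_MWH
    c_ut = prices["electricity_usd_mwh"] * mwh

    c_wt = 0.0
    c_rm = (prices["leaves_usd_kg"] * bal["feed_kg_per_year"]
            + prices["co2_usd_kg"] * bal["co2_makeup_kg_per_year"]
            + prices["ethanol_usd_kg"] * scenario.ethanol_kg_per_year)

    com = 0.340 * fci + 2.73 * c_ol + 1.23 * (c_ut + c_wt + c_rm)
    return CostBreakdown(fci_usd=fci, c_ol=c_ol, c_ut=c_ut, c_wt=c_wt,
                         c_rm=c_rm, com=com,
                         extract_kg=bal["extract_kg_per_year"],
                         com_per_kg=com / bal["extract_kg_per_year"])


def com_matrix(volumes, yields, base: CostScenario | None = None
               ) -> pd.DataFrame:
    """Specific manufacturing cost (USD/kg extract) over a vessel-volume
    by yield grid; category shares are attached as ``.attrs['shares']``."""
    base = base or CostScenario()
    rows = {}
    shares = {}
    for v in volumes:
        row = {}
        for y in yields:
            bd = cost_breakdown(replace(base, vessel_volume=v,
                                        yield_pct=y))
            row[y] = bd.com_per_kg
        rows[v] = row
        shares[v] = bd.shares()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "volume_m3"
    out.columns.name = "yield_pct"
    out.attrs["shares"] = shares
    return out
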