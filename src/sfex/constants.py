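"""Physical constants and study-default process values.

These are *inputs* to the models, not results: critical properties come
from standard property compilations, and the process/cost defaults are the
laboratory and plant conditions the package's worked examples assume.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FluidProperties:
    """Critical-point properties of a pure compound.

    M is the molar mass in kg/mol; Tc in K; Pc in Pa; Vc in m3/mol;
    rho_c in kg/m3 (only needed for the solvent).
    """

    name: str
    M: float
    Tc: float
    Pc: float
    Vc: float
    rho_c: float | None = None


#: Carbon dioxide (solvent). Span–Wagner critical point.
CO2 = FluidProperties(name="CO2", M=0.04401, Tc=304.13, Pc=7.377e6,
                      Vc=94.07e-6, rho_c=467.6)

#: alpha-Pinene, the dominant component of the leaf extract, used as the
#: pseudo-solute for diffusion estimates. Tc/Pc/Vc are literature estimates
#: (group-contribution values commonly quoted for monoterpenes).
ALPHA_PINENE = FluidProperties(name="alpha-pinene", M=0.136234, Tc=632.7,
                               Pc=2.76e6, Vc=504e-6)

# ---------------------------------------------------------------------------
# Laboratory bed (23 g of milled Pistacia lentiscus leaves, 40 degC)
# ---------------------------------------------------------------------------

#: Feed mass of milled solid per laboratory run, kg.
LAB_FEED_KG = 0.023
#: Bulk (apparent) density of the milled leaf bed, kg/m3.
LAB_BULK_DENSITY = 291.0
#: Bed void fraction of the laboratory extractor bed.
LAB_VOID_FRACTION = 0.53
#: True density of the milled leaf solid, kg/m3. The bed relation
#: bulk/(1 - eps) would give 619 kg/m3, below the CO2 density at 220 bar
#: (a settled bed of such a solid could not exist in that solvent), so the
#: printed bulk density and void fraction cannot describe the same packing
#: state; a typical lignocellulosic leaf true density is used instead.
LAB_SOLID_DENSITY = 1400.0
#: Extraction temperature, K (40 degC in every run).
LAB_TEMPERATURE = 313.15
#: Laboratory bed aspect ratio H/d.
LAB_ASPECT_RATIO = 3.6
#: Sample-collection interval, s (extract weighed every 30 min).
SAMPLING_INTERVAL_S = 1800.0

#: Default solubility placeholder, kg oil / kg CO2. The study never reports
#: y_s; the dimensionless time only rescales t by it, so any positive value
#: gives an equivalent re-parameterised fit. Override from config when a
#: measured solubility is available.
DEFAULT_YS = 1.0e-4

# ---------------------------------------------------------------------------
# Cost model defaults (regional 2016 prices, CEPCI-2014 equipment costs)
# ---------------------------------------------------------------------------

#: CEPCI index year of the tabulated vessel costs.
CEPCI_REF = 580.0

#: Specific energies of the solvent cycle, kJ per kg of circulated CO2.
#: Cooling is a heat removal and is tabulated negative.
SPECIFIC_ENERGIES_KJ_KG = {"cooling": -261.29, "heating": 219.2,
                           "pumping": 55.0196}

DEFAULT_PRICES = {
    "leaves_usd_kg": 1.35,
    "co2_usd_kg": 0.15,
    "ethanol_usd_kg": 0.97,
    "electricity_usd_mwh": 217.10,
    "labor_usd_h": 6.60,
}

#: Fraction of circulated CO2 lost per extraction cycle.
DEFAULT_CO2_LOSS = 0.02
#: Plant operating hours per year.
DEFAULT_ANNUAL_HOURS = 8000.0
#: Bed apparent density assumed for the scaled-up vessels, kg/m3.
SCALE_BED_DENSITY = 296.0
#: Laboratory anchor flow for the kinetic-similarity scale-up rule, kg/s.
SCALE_LAB_FLOW = 3.36e-5

#: Validity window of the fitted film mass-transfer correlation.
REYNOLDS_RANGE = (2.0, 60.0)
SCHMIDT_RANGE = (2.0, 12.0)
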