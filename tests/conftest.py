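import numpy as np
import pandas as pd
import pytest

from sfex import datasets
from sfex.bic import BICParameters, ExtractionSystem
from sfex.rsm import DesignTable


@pytest.fixture(scope="session")
def exp2_system() -> ExtractionSystem:
    """Bed/solvent description of the highest-yield study run (220 bar,
    220 um, 0.602 kg/h)."""
    return ExtractionSystem(N=0.023, x0=0.00285, ys=1e-4,
                            Q=0.602 / 3600, eps=0.53, rho_s=1400.0,
                            rho_f=857.2, d_p=220e-6, T=313.15, P=220e5,
                            mu_f=8.18e-5)


@pytest.fixture(scope="session")
def exp2_params() -> BICParameters:
    """Curve-fitted kinetic parameters of that run."""
    return BICParameters(G=0.61, ksa0=7.01e-5, kfa0=1.72e-3)


@pytest.fixture(scope="session")
def study_design() -> DesignTable:
    """Coded ten-run design with the 3-decimal observed yields."""
    coded = datasets.load_coded_design()[["x1", "x2", "x3"]]
    yields = datasets.load_yields()["yield_pct"].to_numpy()
    return DesignTable(coded=coded, yields=yields)


@pytest.fixture(scope="session")
def factorial_design() -> pd.DataFrame:
    """Orthogonal 2^3 full factorial, coded."""
    levels = [-1.0, 1.0]
    rows = [(a, b, c) for a in levels for b in levels for c in levels]
    return pd.DataFrame(rows, columns=["x1", "x2", "x3"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200103)
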