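"""Run configuration: a validated YAML schema for the pipeline and CLI.

One structured-text format carries every tunable of the pipeline. Unknown
keys are rejected so typos fail loudly; every default equals the package
default documented in the module it configures.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import DEFAULT_YS, SAMPLING_INTERVAL_S

__all__ = ["RunConfig", "load_config"]


@dataclass
class BicConfig:
    ys: float = DEFAULT_YS
    fit_x0: bool = False


@dataclass
class TransportConfig:
    a0_basis: str = "bed"            # or "particle"
    bed_diameter: float | None = None


@dataclass
class FittingConfig:
    approach: str = "fitted_kf"      # or "correlation_kf"
    seed: int = 20200103
    n_starts: int = 8
    fraction_loss: bool = False


@dataclass
class RsmConfig:
    alpha: float = 0.05


@dataclass
class EconomicsConfig:
    volumes: list = field(default_factory=lambda: [0.1, 0.2, 0.4, 0.6,
                                                   1.0])
    yields: list = field(default_factory=lambda: [0.3, 0.5, 0.7, 1.0,
                                                  1.5])
    labor_convention: str = "on_duty"
    ethanol_kg_per_year: float = 0.0
    cepci_now: float = 580.0


@dataclass
class SynthConfig:
    noise_sigma: float = 0.0
    duration_s: float = 8 * 3600.0
    sampling_interval_s: float = SAMPLING_INTERVAL_S


@dataclass
class RunConfig:
    """Umbrella configuration of one pipeline run."""

    outdir: str = "sfex_out"
    seed: int = 20200103
    log_level: str = "INFO"
    bic: BicConfig = field(default_factory=BicConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    rsm: RsmConfig = field(default_factory=RsmConfig)
    economics: EconomicsConfig = field(default_factory=EconomicsConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {"bic": BicConfig, "transport": TransportConfig,
             "fitting": FittingConfig, "rsm": RsmConfig,
             "economics": EconomicsConfig, "synth": SynthConfig}


def _build(cls, data: dict, where: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: "
                         f"{sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from YAML or a dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_dict or {})
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    top = {k: v for k, v in data.items() if k not in _SECTIONS}
    unknown = set(top) - {"outdir", "seed", "log_level"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: "
                         f"{sorted(unknown)}")
    cfg = RunConfig(**top)
    for name, cls in _SECTIONS.items():
        if name in data:
            setattr(cfg, name, _build(cls, data[name] or {}, name))
    return cfg
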