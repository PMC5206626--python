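"""Pipeline configuration.

All defaults are the published constants of the upscaling analysis
(regression coefficients, the 0.89 calibration factor, the 0.7 m s-1
velocity cap, 0.5 m reach drop, 20% despike threshold, GWP 28); every
override supplied through a config file is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .network import K600_MODEL, VELOCITY_MODEL, RegressionModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunable constants of the emission upscaling pipeline."""

    dz: float = 0.5  # m elevation drop per reach
    slope_floor: float = 0.05  # % floor before log10
    velocity_model: RegressionModel = field(default_factory=lambda: VELOCITY_MODEL)
    k600_model: RegressionModel = field(default_factory=lambda: K600_MODEL)
    calibration: float = 0.89  # measured-vs-modelled k600 rescaling
    v_cap: float = 0.7  # m s-1
    refit: bool = True  # refit models and calibration from injections
    despike_threshold: float = 0.2
    despike_window: str = "12h"
    gwp: float = 28.0
    atm_ch4_ppm: float = 2.0
    atm_co2_ppm: float = 405.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("velocity_model", "k600_model"):
            d[key]["slopes"] = list(d[key]["slopes"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config file; unspecified keys keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r} in {path}")
            if key in ("velocity_model", "k600_model"):
                value = RegressionModel(
                    intercept=value["intercept"],
                    slopes=tuple(value["slopes"]),
                    mse=value["mse"],
                    adj_r2=value.get("adj_r2"),
                    n=value.get("n"),
                )
            logger.info("config override from %s: %s = %r", path, key, value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
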