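"""Declarative run configuration: schema, validation, defaults.

A single YAML file describes genotypes (by preset name), media fractions,
kinetic-parameter overrides (dotted names, e.g. ``bacterium.mu``), the batch
protocol and the fit/sweep settings.  Unknown keys are rejected with their
location; the fully resolved configuration is echoed to the log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError, IdcsimError
from .genotypes import PAIRING_PRESETS
from .inference import apply_theta
from .media import MediaConfig
from .model import BatchProtocol
from .params import ModelParams

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MediaSection(_Strict):
    f_L: float = 1.0
    f_W: float = 1.0
    f_U: float = 1.0
    f_H: float = 1.0
    glucose_gL: float = 20.0
    mannose: bool = False


class ProtocolSection(_Strict):
    n_days: int = 6
    day_length_h: float = 24.0
    fresh_fraction: float = 0.9
    carryover_fraction: float = 0.1
    sampling_interval_h: float = 0.25
    plating_volume_uL: float = 100.0
    well_volume_uL: float = 200.0
    mannose_switch_day: Optional[int] = None


class FitSection(_Strict):
    n_samples: int = 500
    n_rounds: int = 3
    keep_fraction: float = 0.2
    condition: str = "Ecross-Scross_lw15"


class SweepSection(_Strict):
    axis: str = "gamma"
    grid: Optional[List[float]] = None
    observable: str = "transconjugants_per_plated_volume"


class RunConfig(_Strict):
    seed: int = 0
    pairing: str = "Ecross-Scross"
    n_donor: float = 1e7
    n_recipient: float = 1e7
    collision_norm: str = "per_total_cell"
    media: MediaSection = MediaSection()
    protocol: ProtocolSection = ProtocolSection()
    params: Dict[str, float] = {}
    fit: FitSection = FitSection()
    sweep: SweepSection = SweepSection()
    log_level: str = "INFO"

    # -- builders ----------------------------------------------------------
    def to_media(self) -> MediaConfig:
        return MediaConfig(**self.media.model_dump())

    def to_protocol(self) -> BatchProtocol:
        return BatchProtocol(**self.protocol.model_dump())

    def to_params(self) -> ModelParams:
        base = ModelParams(collision_norm=self.collision_norm)
        return apply_theta(base, self.params)

    def to_pairing(self):
        if self.pairing not in PAIRING_PRESETS:
            raise ConfigError(
                f"pairing must be one of {sorted(PAIRING_PRESETS)}, "
                f"got {self.pairing!r}")
        return PAIRING_PRESETS[self.pairing]


def load_config(path: Union[str, Path, None] = None,
                overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML config; defaults fill every omitted key.

    The resolved configuration (defaults included) is echoed to the log so
    any run can be replayed.
    """
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"no such config file: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{p}: top level must be a mapping")
    if overrides:
        raw.update(overrides)
    try:
        cfg = RunConfig(**raw)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"config key {loc!r}: {first['msg']}") from None
    try:  # surface domain violations (e.g. negative fractions) at load time
        cfg.to_media()
        cfg.to_protocol()
        cfg.to_params()
        cfg.to_pairing()
    except IdcsimError as err:
        raise ConfigError(str(err)) from None
    logger.info("resolved config: %s", cfg.model_dump())
    return cfg


def dump_defaults() -> str:
    """YAML text of the fully resolved default configuration."""
    return yaml.safe_dump(RunConfig().model_dump(), sort_keys=False)
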