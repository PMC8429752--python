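"""Run configuration: every analysis constant lives here, never inline.

Defaults carry the standard values for the diamondback moth analysis:
cold threshold 11.0 degC, developmental band 7.4–33 degC, survival
cutoffs 5% / 1%, host-presence cutoff 0.3, resistance quantile 0.85 and
warming scenarios +1..+6 degC.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .degree_days import ThermalConfig
from .errors import InvalidInputError


@dataclass
class RunConfig:
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    permanent_cutoff: float = 0.05
    marginal_cutoff: float = 0.01
    host_cutoff: float = 0.3
    quantile_tau: float = 0.85
    scenario_deltas: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    seed: int = 0
    # synthetic design sizes
    n_lab_regimes: int = 10
    n_field_sites: int = 12
    n_resistance_records: int = 600
    grid_n_lat: int = 24
    grid_n_lon: int = 6
    grid_year_start: int = 1990
    grid_year_end: int = 2010
    out_dir: str = "coldrange_run"

    def __post_init__(self) -> None:
        if not (0 < self.marginal_cutoff < self.permanent_cutoff < 1):
            raise InvalidInputError("need 0 < marginal_cutoff < permanent_cutoff < 1")
        if not (0 <= self.host_cutoff <= 1):
            raise InvalidInputError("host_cutoff must be in [0, 1]")
        if not (0 < self.quantile_tau < 1):
            raise InvalidInputError("quantile_tau must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario_deltas"] = list(self.scenario_deltas)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thermal = ThermalConfig(**raw.pop("thermal", {}))
        if "scenario_deltas" in raw:
            raw["scenario_deltas"] = tuple(raw["scenario_deltas"])
        try:
            return cls(thermal=thermal, **raw)
        except TypeError as exc:
            raise InvalidInputError(f"bad config key: {exc}") from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
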