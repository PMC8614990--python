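"""Run configuration with the published default settings.

Defaults: a 10-point grid over each screening range, 1000 Monte-Carlo
cycles per grid point, a 5% critical OOA level, a 0.95 confidence level for
the SD inflation, and the 0.8/0.5/0.3 → 10/7/3/1 ranking rubric.  Every
value can be overridden from a YAML/JSON document or the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .fmea import RankingRubric

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    chain_path: str | None = None
    doe_dir: str | None = None
    mfg_runs_path: str | None = None
    grid_size: int = 10
    n_cycles: int = 1000
    critical_ooa: float = 5.0
    gamma: float = 0.95
    ranking_bands: list[list[float]] = field(
        default_factory=lambda: [[0.8, 10], [0.5, 7], [0.3, 3], [0.0, 1]])
    seed: int = 0
    out_dir: str = "ipm_out"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.grid_size < 2:
            raise ConfigurationError("grid_size must be >= 2")
        if self.n_cycles < 2:
            raise ConfigurationError("n_cycles must be >= 2")
        if not 0 < self.critical_ooa < 100:
            raise ConfigurationError("critical_ooa must be in (0, 100)")
        if not 0 < self.gamma < 1:
            raise ConfigurationError("gamma must be in (0, 1)")
        self.rubric()  # validates the bands

    def rubric(self) -> RankingRubric:
        try:
            bands = tuple((float(lo), int(rank))
                          for lo, rank in self.ranking_bands)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"malformed ranking bands {self.ranking_bands!r}") from exc
        return RankingRubric(bands=bands)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ConfigurationError("config document must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)
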