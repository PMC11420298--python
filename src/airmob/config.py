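"""Pipeline configuration: YAML-backed, validated, defaults-filled.

Unknown keys are rejected (with a nearest-valid-key hint) rather than
ignored, so a typo never silently reverts a parameter to its default.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .pollutants import POLLUTANTS


class ConfigError(ValueError):
    """All configuration problems, reported at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Block):
    simulate: bool = True
    ingest: bool = True
    aggregate: bool = True
    decompose: bool = True
    exceedance: bool = True
    hotspots: bool = True


class SimulateBlock(_Block):
    n_days: int = 2
    start_date: str = "2021-05-17"
    pollutants: list[str] = ["PM2.5", "NO2"]
    missingness_fraction: float = 0.3
    cell_size_m: float = 100.0
    hotspot_cells: list[int] = []
    hotspot_rate_multiplier: float = 1.0

    @field_validator("pollutants")
    @classmethod
    def _known_pollutants(cls, v: list[str]) -> list[str]:
        unknown = [p for p in v if p not in POLLUTANTS]
        if unknown:
            raise ValueError(f"unknown pollutants {unknown}; choose from {list(POLLUTANTS)}")
        return v


class IngestBlock(_Block):
    resolution: str = "1s"
    key_variables: Optional[list[str]] = None
    lod_table: Optional[str] = None  # YAML path; built-in placeholders if None


class AggregateBlock(_Block):
    min_samples: int = 4
    min_hours: int = 3
    daytime_source: str = "segments"


class DecomposeBlock(_Block):
    baseline_mode: str = "percentile"
    baseline_percentile: float = 5.0
    baseline_window: str = "1h"


class ExceedanceBlock(_Block):
    precision: int = 1


class HotspotsBlock(_Block):
    pollutant: str = "NO2"
    cell_size_m: float = 100.0
    band_distance_m: Optional[float] = None
    min_count: int = 5
    correction: str = "benjamini_hochberg"
    per_day: bool = False


class PipelineConfig(_Block):
    seed: int = 0
    out_dir: str = "airmob_out"
    input_path: Optional[str] = None  # external observations; otherwise simulate
    stages: StageToggles = StageToggles()
    simulate: SimulateBlock = SimulateBlock()
    ingest: IngestBlock = IngestBlock()
    aggregate: AggregateBlock = AggregateBlock()
    decompose: DecomposeBlock = DecomposeBlock()
    exceedance: ExceedanceBlock = ExceedanceBlock()
    hotspots: HotspotsBlock = HotspotsBlock()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _valid_keys(model: type[BaseModel]) -> list[str]:
    return list(model.model_fields)


_BLOCKS = {
    "stages": StageToggles, "simulate": SimulateBlock, "ingest": IngestBlock,
    "aggregate": AggregateBlock, "decompose": DecomposeBlock,
    "exceedance": ExceedanceBlock, "hotspots": HotspotsBlock,
}


def validate_config(source) -> PipelineConfig:
    """Build a validated PipelineConfig from a dict, YAML path, or YAML text.

    Collects every problem into one ConfigError; unknown keys carry a
    nearest-valid-key suggestion.
    """
    if isinstance(source, PipelineConfig):
        source = source.model_dump(mode="json")
    elif isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        source = yaml.safe_load(text) or {}
    if not isinstance(source, dict):
        raise ConfigError([f"config root must be a mapping, got {type(source).__name__}"])
    try:
        config = PipelineConfig(**source)
    except ValidationError as exc:
        problems = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            if err["type"] == "extra_forbidden":
                parent = _BLOCKS.get(err["loc"][0]) if len(err["loc"]) > 1 else PipelineConfig
                candidates = _valid_keys(parent) if parent else []
                near = difflib.get_close_matches(str(err["loc"][-1]), candidates, n=1)
                hint = f" (did you mean {near[0]!r}?)" if near else ""
                problems.append(f"unknown key {loc!r}{hint}")
            else:
                problems.append(f"{loc}: {err['msg']}")
        raise ConfigError(problems) from None
    if config.input_path is not None and not Path(config.input_path).exists():
        raise ConfigError([f"input_path {config.input_path!r} does not exist"])
    return config
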