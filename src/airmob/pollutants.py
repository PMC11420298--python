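"""Pollutant registry: canonical names, units, and placeholder detection limits.

The six species measured by the mobile platform. Limits of detection (LOD)
are instrument properties; the values shipped here are plausible placeholders
for a 1 Hz mobile platform and are fully overridable via :class:`LodTable`
YAML input — they are not authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

#: Canonical pollutant column names and reporting units.
POLLUTANT_UNITS: dict[str, str] = {
    "PM2.5": "ug/m3",
    "NO2": "ppb",
    "NO": "ppb",
    "O3": "ug/m3",
    "CO": "ppm",
    "CO2": "ppm",
}

POLLUTANTS: tuple[str, ...] = tuple(POLLUTANT_UNITS)

#: Placeholder LODs per pollutant at the two working resolutions.
#: The 8-s value is lower than the 1-s value (median filtering reduces noise).
DEFAULT_LODS: dict[str, dict[str, float]] = {
    "PM2.5": {"1s": 1.0, "8s": 0.5},
    "NO2": {"1s": 5.0, "8s": 2.5},
    "NO": {"1s": 5.0, "8s": 2.5},
    "O3": {"1s": 4.0, "8s": 2.0},
    "CO": {"1s": 0.05, "8s": 0.025},
    "CO2": {"1s": 10.0, "8s": 5.0},
}

RESOLUTIONS = ("1s", "8s")


@dataclass(frozen=True)
class LodTable:
    """Limit-of-detection lookup per pollutant and time resolution.

    Values strictly positive; below-LOD observations are later replaced by
    half the LOD (the standard censoring substitution).
    """

    lods: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_LODS
    )

    def __post_init__(self) -> None:
        for pollutant, by_res in self.lods.items():
            for res, value in by_res.items():
                if res not in RESOLUTIONS:
                    raise ValueError(f"unknown resolution {res!r} for {pollutant}")
                if not value > 0:
                    raise ValueError(
                        f"LOD for {pollutant} at {res} must be > 0, got {value}"
                    )

    def lod(self, pollutant: str, resolution: str) -> float:
        try:
            return float(self.lods[pollutant][resolution])
        except KeyError:
            raise KeyError(
                f"no LOD entry for pollutant {pollutant!r} at resolution "
                f"{resolution!r}"
            ) from None

    def covers(self, pollutants: Iterable[str], resolution: str) -> bool:
        return all(
            p in self.lods and resolution in self.lods[p] for p in pollutants
        )

    @classmethod
    def from_yaml(cls, path) -> "LodTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(lods={p: dict(v) for p, v in data.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({p: dict(v) for p, v in self.lods.items()}, fh)
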