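"""Run configuration: one structured file drives every pipeline stage.

Segmentation windows and shape-filter thresholds are instrument- and
protocol-specific and must be optimised per scanner; they therefore live in
an explicit TOML or JSON config artifact, never hidden in code.  Every
output embeds a full parameter echo so a run can be reproduced from its own
results.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .burden import ConversionFactors
from .detect import SegmentationParams, FilterParams
from .phantom import PhantomSpec

__all__ = ["RunConfig", "load_config", "default_config_dict"]


@dataclass
class RunConfig:
    """Everything a counting run needs, validated on construction."""

    inputs: list[str] = field(default_factory=list)
    voxel_size: float = 0.332
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    filters: FilterParams = field(default_factory=FilterParams)
    conversion: ConversionFactors = field(default_factory=ConversionFactors)
    chunk_planes: int | None = None
    overlap: int | None = None
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.chunk_planes is not None and self.chunk_planes < 1:
            raise ValueError("chunk_planes must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "filters" in d:
            d["filters"] = FilterParams(**d["filters"])
        if "conversion" in d:
            d["conversion"] = ConversionFactors(**d["conversion"])
        return cls(**d)


def _read_structured(path: Path) -> dict:
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a TOML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    return RunConfig.from_dict(_read_structured(path))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Load a :class:`~abtomo.phantom.PhantomSpec` from TOML or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such phantom spec file: {path}")
    return PhantomSpec.from_dict(_read_structured(path))


def default_config_dict() -> dict:
    """All defaults, JSON-ready — what ``abtomo show-config`` prints."""
    return {
        "run": RunConfig().to_dict(),
        "phantom": PhantomSpec().to_dict(),
    }
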