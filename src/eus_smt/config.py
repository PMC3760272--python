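"""YAML configuration bundling all pipeline parameters.

Schema (all sections and keys optional; omitted keys take the shipped
defaults)::

    gist:     { bright_floor: 30, link_threshold: 130, dark_cutoff: 40, ... }
    lipoma:   { dark_zero_cutoff: 75, equalize_first: false, ... }
    fuzzy:    { mean_breakpoints: [...], output_vertices: [...], ... }
    evaluate: { iou_success: 0.5 }
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

from .fuzzy import FuzzyConfig
from .gist_extract import ExtractionConfig
from .lipoma_extract import LipomaConfig


@dataclass
class PipelineConfig:
    gist: ExtractionConfig = field(default_factory=ExtractionConfig)
    lipoma: LipomaConfig = field(default_factory=LipomaConfig)
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    iou_success: float = 0.5  # IoU at/above which an extraction counts as successful

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {"gist", "lipoma", "fuzzy", "evaluate"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        ev = d.get("evaluate") or {}
        if set(ev) - {"iou_success"}:
            raise ValueError(f"unknown evaluate config keys: {sorted(set(ev) - {'iou_success'})}")
        return cls(
            gist=ExtractionConfig.from_dict(d.get("gist") or {}),
            lipoma=LipomaConfig.from_dict(d.get("lipoma") or {}),
            fuzzy=FuzzyConfig.from_dict(d.get("fuzzy") or {}),
            iou_success=float(ev.get("iou_success", 0.5)),
        )

    def to_dict(self) -> dict:
        return {
            "gist": asdict(self.gist),
            "lipoma": asdict(self.lipoma),
            "fuzzy": asdict(self.fuzzy),
            "evaluate": {"iou_success": self.iou_success},
        }


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Load a pipeline configuration; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {os.fspath(path)!r} must contain a mapping")
    return PipelineConfig.from_dict(data)


def dump_config(cfg: PipelineConfig, path: str | os.PathLike) -> None:
    """Write a configuration (e.g. the defaults) as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
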