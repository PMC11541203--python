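"""Run configuration: YAML files mirroring the parameter dataclasses.

Unknown keys are rejected rather than ignored, so a typo in a config
file fails loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError
from .response_stats import DEFAULT_RESPONDER_THRESHOLD
from .segmentation import SegmentationParams

_LOG_LEVELS = ("debug", "info", "warning")


@dataclass
class RunConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    pixel_size_mm: float | None = None
    responder_threshold: float = DEFAULT_RESPONDER_THRESHOLD
    seed: int = 0
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.pixel_size_mm is not None and not self.pixel_size_mm > 0:
            raise ValidationError("pixel_size_mm must be > 0 when given")
        if not self.responder_threshold > 0:
            raise ValidationError("responder_threshold must be > 0")
        if self.log_level not in _LOG_LEVELS:
            raise ValidationError(f"log_level must be one of {_LOG_LEVELS}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; segmentation keys nest under ``segmentation:``."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError(f"could not read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")

    seg_raw = raw.get("segmentation", {}) or {}
    if not isinstance(seg_raw, dict):
        raise ConfigError(f"{path}: 'segmentation' must be a mapping")
    seg_fields = {f.name for f in dataclasses.fields(SegmentationParams)}
    unknown_seg = set(seg_raw) - seg_fields
    if unknown_seg:
        raise ConfigError(f"{path}: unknown segmentation keys: {sorted(unknown_seg)}")

    try:
        segmentation = SegmentationParams(**seg_raw)
        kwargs = {k: v for k, v in raw.items() if k != "segmentation"}
        return RunConfig(segmentation=segmentation, **kwargs)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
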