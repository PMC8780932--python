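"""Run configuration: every setting of a batch run, fully serializable.

A run's effective config (all defaults resolved) is written next to its
outputs so any result can be reproduced from the snapshot alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError
from .segmentation import SegmentationParams

DEFAULT_OVERLAY_COLORS = (
    (0, 255, 0),
    (255, 0, 255),
    (0, 255, 255),
    (255, 255, 0),
    (255, 128, 0),
)


@dataclass
class RunConfig:
    input: str = ""
    palette: str = ""
    output: str = "out"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    denominator_mode: str = "whole_image"
    overlay: bool = True
    overlay_opacity: float = 0.5
    overlay_colors: dict[str, tuple[int, int, int]] | None = None
    edge_filter: bool = False
    edge_max_background_fraction: float = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.denominator_mode not in ("whole_image", "tissue_only"):
            raise ConfigurationError(f"unknown denominator_mode {self.denominator_mode!r}")
        if not 0.0 <= self.overlay_opacity <= 1.0:
            raise ConfigurationError("overlay_opacity must be in [0, 1]")

    def resolve_overlay_colors(self, classes: tuple[str, ...]) -> dict[str, tuple[int, int, int]]:
        colors = dict(self.overlay_colors or {})
        for i, name in enumerate(classes):
            colors.setdefault(name, DEFAULT_OVERLAY_COLORS[i % len(DEFAULT_OVERLAY_COLORS)])
        return colors

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"]["morphology"] = [list(s) for s in self.segmentation.morphology]
        if self.overlay_colors is not None:
            d["overlay_colors"] = {k: list(v) for k, v in self.overlay_colors.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        if isinstance(seg, Mapping):
            seg = dict(seg)
            seg["morphology"] = tuple(tuple(s) for s in seg.get("morphology", ()))
            seg = SegmentationParams(**seg)
        colors = d.pop("overlay_colors", None)
        if colors is not None:
            colors = {k: tuple(int(c) for c in v) for k, v in colors.items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(segmentation=seg, overlay_colors=colors, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
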