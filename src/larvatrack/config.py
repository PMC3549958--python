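"""Run configuration for the tracking pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class StopGoParams:
    """Thresholds for stop/go bout segmentation.

    A frame belongs to a go phase when the centroid displacement over
    ``t_window`` frames exceeds ``v`` pixels and the bending angle stays
    below ``beta`` degrees; go runs shorter than ``t_go`` frames are erased.
    """

    t_window: int = 15
    v: float = 10.0
    beta: float = 20.0
    t_go: int = 7

    def __post_init__(self) -> None:
        if min(self.t_window, self.v, self.beta, self.t_go) <= 0:
            raise ValueError("stop/go parameters must all be positive")


@dataclass
class RunConfig:
    """Everything a tracking run needs besides the frames themselves.

    ``threshold=None`` requests self-calibration: the Otsu threshold of the
    first frame's bimodal grey-value histogram.  Size-filter bounds default
    to 0.3x-3x of the nominal body area implied by ``body_length`` (an
    animal of length L is roughly L x 0.15 L).
    """

    fps: float = 10.0
    mm_per_px: float | None = None
    threshold: int | None = None
    body_length: float = 40.0
    min_area: float | None = None
    max_area: float | None = None
    d_max: float | None = None          # assignment gate; default body_length / 2
    suspend_max: int = 25               # frames a lost track may wait for a blob
    stop_go: StopGoParams = field(default_factory=StopGoParams)
    spine_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        nominal_area = 0.15 * self.body_length**2
        if self.min_area is None:
            self.min_area = 0.3 * nominal_area
        if self.max_area is None:
            self.max_area = 3.0 * nominal_area
        if self.d_max is None:
            self.d_max = self.body_length / 2.0
        if self.threshold is not None and not 0 <= self.threshold <= 255:
            raise ValueError("threshold must be in [0, 255]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sg = d.pop("stop_go", None)
        cfg = cls(**d)
        if sg is not None:
            cfg.stop_go = StopGoParams(**sg) if isinstance(sg, dict) else sg
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
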