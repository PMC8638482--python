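"""Reconstruction configuration: nested dataclasses with YAML round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .focuss import FocussConfig

__all__ = ["NLGConfig", "MetricsConfig", "ReconConfig"]

METHODS = ("proposed", "cs_only", "zero_filled")


@dataclass
class NLGConfig:
    """Stage-2 kernel settings (see :class:`ktjoint.nlgrappa.KernelGeometry`)."""

    b1: int = -1
    b2: int = 2
    h1: int = -2
    h2: int = 2
    reg_rel: float = 1e-6
    edge_mode: str = "zero"
    second_order: bool = True
    per_frame_kernel: bool = False


@dataclass
class MetricsConfig:
    """ROI as (y0, y1, x0, x1) half-open bounds; None = full frame."""

    roi: tuple | None = None


@dataclass
class ReconConfig:
    focuss: FocussConfig = field(default_factory=FocussConfig)
    nlgrappa: NLGConfig = field(default_factory=NLGConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    method: str = "proposed"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)

    @classmethod
    def from_yaml(cls, path) -> "ReconConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ReconConfig":
        kwargs = {}
        if "focuss" in raw:
            kwargs["focuss"] = FocussConfig(**raw["focuss"])
        if "nlgrappa" in raw:
            kwargs["nlgrappa"] = NLGConfig(**raw["nlgrappa"])
        if "metrics" in raw:
            m = dict(raw["metrics"])
            if m.get("roi") is not None:
                m["roi"] = tuple(m["roi"])
            kwargs["metrics"] = MetricsConfig(**m)
        for key in ("method", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)
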