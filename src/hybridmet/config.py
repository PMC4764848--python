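"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Knobs shared across pipeline stages.

    vip_threshold : retention cut on Factor-1 VIP (>= keeps).
    hd_sign_flip : negate heading-date heterosis so earlier heading is positive.
    reciprocal_mode : 'duplicate' (one design row per ordered hybrid) or
        'average' (one per pair with averaged responses).
    latent_cap : optional ceiling on the latent-number search.
    encodings : parental encodings used for the predictor matrix.
    """

    random_seed: int = 0
    vip_threshold: float = 1.0
    hd_sign_flip: bool = True
    reciprocal_mode: str = "duplicate"
    latent_cap: int | None = None
    encodings: tuple[str, ...] = ("ratio",)

    def __post_init__(self) -> None:
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be positive")
        if self.reciprocal_mode not in ("duplicate", "average"):
            raise ValueError("reciprocal_mode must be 'duplicate' or 'average'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "encodings" in data:
            data["encodings"] = tuple(data["encodings"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["encodings"] = list(data["encodings"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)
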