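"""Pipeline configuration: defaults, YAML loading and validation.

Every default is the system's standard operating point: uniform sampling rate
360 Hz, bandpass 2-50 Hz, 800-ms beat windows with the mu - 0.5*sigma outlier
threshold, db3 5-level DWT with level set S2, ML-5 fiducial features, and a
gate threshold Pth = 0.15 in front of a 500-tree random forest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

log = logging.getLogger("ecgid")


@dataclass
class PipelineConfig:
    target_fs: float = 360.0
    band_low: float = 2.0
    band_high: float = 50.0
    pth: float = 0.15
    feature_mode: str = "ml5"
    level_set: str = "S2"
    n_trees: int = 500
    max_features: str = "sqrt"
    bootstrap: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.target_fs <= 0:
            raise ValueError("target_fs must be > 0")
        if not 0 <= self.band_low < self.band_high < self.target_fs / 2:
            raise ValueError("need 0 <= band_low < band_high < target_fs / 2")
        if not 0 <= self.pth < 1:
            raise ValueError("pth must be in [0, 1)")
        if self.feature_mode.lower() not in {"ml3", "ml5", "ml9"}:
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.level_set.upper() not in {"S1", "S2", "S3"}:
            raise ValueError(f"unknown level_set {self.level_set!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        return self

    def log_resolved(self) -> None:
        """Log the fully resolved configuration so runs are replayable."""
        log.info("resolved config: %s", asdict(self))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; missing keys fall back to defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg.validate()
    path = Path(path)
    if not path.exists():
        raise ValueError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f for f in cfg.__dataclass_fields__ if f != "extra"}
    for key, value in data.items():
        if key in known:
            setattr(cfg, key, value)
        else:
            cfg.extra[key] = value
    return cfg.validate()
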