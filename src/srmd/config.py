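"""Study configuration: the knobs of the disturbance-identification method.

Defaults follow the method's published operating point where one exists
(significance level 0.05, relative perturbation bias 0.001); everything the
method leaves open (network width, learning rate, kernel bandwidth) is an
explicit, documented parameter here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "load_config", "save_config", "get_logger"]


@dataclass
class StudyConfig:
    """Configuration for one end-to-end run.

    Attributes
    ----------
    years
        All analysed years.
    no_mining_years
        Subset of ``years`` with no mining activity; used to calibrate the
        attribution noise (virtual contribution).
    alpha
        One-sided significance level of the disturbance test (default 0.05).
    bias_factor
        Relative perturbation applied to a normalized driver in the
        finite-difference attribution (default 0.001).
    kernel / bandwidth_m
        Geographic weighting kernel and its bandwidth in metres. A
        bandwidth of ``None`` means "quarter of the grid diagonal",
        resolved when the grid is known.
    hidden_sizes, learning_rate, max_epochs, tolerance
        Network architecture and trainer settings.
    anchor_budget
        Maximum number of output-layer anchor locations; above it, anchors
        are a regular stride subsample of the pixels.
    training_scope
        ``per_year`` (one model per year, the default) or ``pooled``.
    share_convention
        ``signed`` — contribution shares C_i / sum(C_k) with the signed
        denominator; ``magnitude`` — |C_i| / sum(|C_k|).
    """

    years: list[int] = field(default_factory=list)
    no_mining_years: list[int] = field(default_factory=list)
    alpha: float = 0.05
    bias_factor: float = 0.001
    kernel: str = "gaussian"
    bandwidth_m: float | None = None
    hidden_sizes: list[int] = field(default_factory=lambda: [16])
    learning_rate: float = 0.5
    max_epochs: int = 200
    tolerance: float = 1e-9
    seed: int = 0
    training_scope: str = "per_year"
    distance_units: str = "km"
    anchor_budget: int = 256
    share_convention: str = "magnitude"
    update_mode: str = "batch"
    mre_floor: float = 0.01

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.bias_factor > 0:
            raise ValueError(f"bias_factor must be > 0, got {self.bias_factor}")
        if self.bandwidth_m is not None and not self.bandwidth_m > 0:
            raise ValueError(f"bandwidth_m must be > 0, got {self.bandwidth_m}")
        if any(h <= 0 for h in self.hidden_sizes) or not self.hidden_sizes:
            raise ValueError(f"hidden_sizes must be positive, got {self.hidden_sizes}")
        if not self.learning_rate > 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.training_scope not in ("per_year", "pooled"):
            raise ValueError(f"unknown training_scope {self.training_scope!r}")
        if self.share_convention not in ("signed", "magnitude"):
            raise ValueError(f"unknown share_convention {self.share_convention!r}")
        if self.update_mode not in ("batch", "online"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")
        if self.distance_units not in ("km", "m"):
            raise ValueError(f"unknown distance_units {self.distance_units!r}")
        if set(self.no_mining_years) - set(self.years):
            extra = sorted(set(self.no_mining_years) - set(self.years))
            raise ValueError(f"no_mining_years not within years: {extra}")

    @property
    def mining_years(self) -> list[int]:
        return [y for y in self.years if y not in set(self.no_mining_years)]

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML config, applying defaults for unset fields and validating."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return StudyConfig(**data)


def save_config(config: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def get_logger(name: str = "srmd") -> logging.Logger:
    """Package logger with timestamped, stage-named lines."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger
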