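"""Run configuration: validated parameters with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError

__all__ = ["RunConfig", "MODELS"]

MODELS = ("ss", "cass", "cass-dsm")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one detection run.

    Defaults follow the method's reference settings: detection scale
    ``sigma = 1.0``, hysteresis quantile ``p = 0.2``, inhibition level
    ``alpha = 0.1`` with ``max_iters = 20`` dynamic iterations, and jump
    threshold ``Thr = 30`` (intensity^2 units, assuming a [0, 255] range).
    ``h`` and ``sigma_m`` default to the surface estimator's adaptive
    choices (``max(4*sigma, 4)`` and the median residual level).
    """

    sigma: float = 1.0
    p: float = 0.2
    alpha: float = 0.1
    Thr: float = 30.0
    h: float | None = None
    sigma_m: float | None = None
    max_iters: int = 20
    eps_rel: float = 0.01
    stop_fraction: float = 0.05
    model: str = "cass-dsm"
    tolerance: int = 1
    seed: int = 0
    input_path: str | None = None
    output_path: str | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 < self.p < 1.0:
            raise InvalidParameterError(f"p must be in (0, 1), got {self.p}")
        if self.alpha < 0:
            raise InvalidParameterError(f"alpha must be nonnegative, got {self.alpha}")
        if self.max_iters < 1:
            raise InvalidParameterError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.eps_rel <= 0:
            raise InvalidParameterError(f"eps_rel must be positive, got {self.eps_rel}")
        if not 0.0 <= self.stop_fraction <= 1.0:
            raise InvalidParameterError(
                f"stop_fraction must be in [0, 1], got {self.stop_fraction}"
            )
        if self.model not in MODELS:
            raise InvalidParameterError(
                f"model must be one of {MODELS}, got {self.model!r}"
            )
        if self.tolerance < 0:
            raise InvalidParameterError(f"tolerance must be >= 0, got {self.tolerance}")
        if self.h is not None and self.h < 2:
            raise InvalidParameterError(f"h must be >= 2 pixels, got {self.h}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **kw) -> "RunConfig":
        d = self.to_dict()
        d.update(kw)
        return RunConfig.from_dict(d)
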