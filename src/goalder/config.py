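"""Run configuration: defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .selection import DEFAULT_LAMBDA_EXPONENTS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable knobs of the estimation pipeline in one serializable place."""

    seed: int = 0
    lambda_exponents: list[float] = field(
        default_factory=lambda: list(DEFAULT_LAMBDA_EXPONENTS)
    )
    ridge_penalty: float = 0.1
    weight_floor: float = 0.0
    penalty_direction: str = "inverse"
    cdc_eval_points: int = 40
    bandwidth: float | None = None
    fast: bool = False
    folds: int = 5
    bootstrap_B: int = 100
    degree: int = 1
    ci_level: float = 0.95

    def __post_init__(self):
        if self.penalty_direction not in ("inverse", "direct"):
            raise ValueError("penalty_direction must be 'inverse' or 'direct'")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.ridge_penalty < 0 or self.weight_floor < 0:
            raise ValueError("ridge_penalty and weight_floor must be nonnegative")
        if self.folds < 2 or self.degree < 1 or self.bootstrap_B < 2:
            raise ValueError("folds >= 2, degree >= 1, bootstrap_B >= 2 required")

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    # -- model plumbing --------------------------------------------------------
    def model_kwargs(self, method: str = "goaldr") -> dict:
        common = dict(fast=self.fast, folds=self.folds, degree=self.degree,
                      ci_level=self.ci_level, seed=self.seed)
        if method.lower() == "goaldr":
            common.update(
                lambda_exponents=tuple(self.lambda_exponents),
                cdc_eval_points=self.cdc_eval_points, bandwidth=self.bandwidth,
                penalty_direction=self.penalty_direction,
                ridge_penalty=self.ridge_penalty, weight_floor=self.weight_floor,
            )
        return common
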