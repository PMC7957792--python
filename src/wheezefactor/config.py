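"""YAML-backed configuration for the classification pipeline.

Flat key-value file holding the decomposition hyperparameters plus the
front-end and peak-detection knobs; CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class CLRNMFConfig:
    """All pipeline hyperparameters with their recommended defaults.

    kw/kr are the wheeze/respiratory component counts (2 <= kw <= 6 and
    kr >= 32 recommended); alpha, beta and lam weight the sparseness and
    smoothness penalties (0.5 each by default, tied but free); max_iter
    is the multiplicative-update budget M = 50.
    """

    kw: int = 4
    kr: int = 32
    alpha: float = 0.5
    beta: float = 0.5
    lam: float = 0.5
    max_iter: int = 50
    seed: int | None = None
    epsilon: float = 1e-12
    tol: float = 0.0
    prominence_fraction: float = 0.05

    def validate(self) -> None:
        if self.kw < 1 or self.kr < 1:
            raise ValueError("kw and kr must be >= 1")
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.max_iter < 1 or not self.epsilon > 0 or self.tol < 0:
            raise ValueError("need max_iter >= 1, epsilon > 0, tol >= 0")

    def classifier_params(self) -> dict:
        """Map config keys onto :class:`WheezeClassifier` parameters."""
        return {
            "n_wheeze_components": self.kw,
            "n_resp_components": self.kr,
            "alpha": self.alpha,
            "beta": self.beta,
            "lam": self.lam,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "epsilon": self.epsilon,
            "prominence_fraction": self.prominence_fraction,
            "random_state": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CLRNMFConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
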