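"""Model contracts, hyperparameter spaces and the model registry.

Two kinds of prediction model flow through the same pipeline: *searchable*
models expose a :class:`HyperparamSpace` consumed by the Bayesian
optimizer, while *param_free* models (e.g. RR-BLUP, whose shrinkage comes
from REML) are simply fitted once. Every model declares its default and
allowed genotype encodings and which trait types it supports, so the
pipeline can validate a request before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "CategoricalDim",
    "IntDim",
    "RealDim",
    "HyperparamSpace",
    "ModelContract",
    "register_model",
    "get_model",
    "list_models",
]


@dataclass(frozen=True)
class CategoricalDim:
    name: str
    choices: tuple

    def __post_init__(self):
        if len(self.choices) == 0:
            raise ValueError(f"categorical dimension {self.name!r} has no choices")


@dataclass(frozen=True)
class IntDim:
    name: str
    lo: int
    hi: int
    log: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"dimension {self.name!r}: lo must be < hi")
        if self.log and self.lo <= 0:
            raise ValueError(f"dimension {self.name!r}: log scale requires lo > 0")


@dataclass(frozen=True)
class RealDim:
    name: str
    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"dimension {self.name!r}: lo must be < hi")
        if self.log and self.lo <= 0:
            raise ValueError(f"dimension {self.name!r}: log scale requires lo > 0")


Dim = CategoricalDim | IntDim | RealDim


@dataclass
class HyperparamSpace:
    """Declarative search space: a named set of categorical/int/real dimensions."""

    dims: list[Dim]

    def __post_init__(self):
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")

    def __len__(self) -> int:
        return len(self.dims)

    def sample(self, rng: np.random.Generator) -> dict:
        """One uniform random assignment (log dims uniform in log space)."""
        params = {}
        for d in self.dims:
            if isinstance(d, CategoricalDim):
                params[d.name] = d.choices[rng.integers(len(d.choices))]
            elif isinstance(d, IntDim):
                if d.log:
                    v = np.exp(rng.uniform(np.log(d.lo), np.log(d.hi)))
                    params[d.name] = int(np.clip(round(v), d.lo, d.hi))
                else:
                    params[d.name] = int(rng.integers(d.lo, d.hi + 1))
            else:
                if d.log:
                    params[d.name] = float(np.exp(rng.uniform(np.log(d.lo), np.log(d.hi))))
                else:
                    params[d.name] = float(rng.uniform(d.lo, d.hi))
        return params


@dataclass
class ModelContract:
    """What a model supports and how the pipeline may drive it.

    ``factory(params, trait_type)`` must return an estimator exposing
    ``fit(X, y) -> self``, ``predict(X)`` and, when
    ``supports_importance``, ``feature_importance()`` (one score per
    feature column).
    """

    name: str
    trait_types: tuple[str, ...]  # subset of ('continuous', 'discrete')
    default_encoding: str
    allowed_encodings: tuple[str, ...]
    kind: str  # 'searchable' | 'param_free'
    factory: Callable[[dict, str], object]
    space: HyperparamSpace | None = None
    supports_importance: bool = True

    def __post_init__(self):
        if self.kind not in ("searchable", "param_free"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "searchable" and (self.space is None or len(self.space) == 0):
            raise ValueError(f"searchable model {self.name!r} must expose a non-empty HyperparamSpace")
        if self.kind == "param_free" and self.space is not None:
            raise ValueError(f"param_free model {self.name!r} must not expose a HyperparamSpace")
        if self.default_encoding not in self.allowed_encodings:
            raise ValueError(f"default encoding {self.default_encoding!r} not in allowed encodings")


_REGISTRY: dict[str, ModelContract] = {}


def register_model(contract: ModelContract) -> ModelContract:
    """Add a model to the registry, making it selectable by name everywhere."""
    if contract.name in _REGISTRY:
        raise ValueError(f"model name {contract.name!r} already registered")
    _REGISTRY[contract.name] = contract
    return contract


def get_model(name: str) -> ModelContract:
    if name not in _REGISTRY:
        raise KeyError(f"unknown model {name!r}; registered models: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def aggregate_importance(col_scores: np.ndarray, feature_to_marker: np.ndarray, n_markers: int) -> np.ndarray:
    """Collapse per-column scores to per-marker scores (sum of |score| per block)."""
    out = np.zeros(n_markers)
    np.add.at(out, feature_to_marker, np.abs(col_scores))
    return out
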