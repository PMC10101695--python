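"""Prediction models and the registry the pipeline selects them from.

Built-in registry names: ``rrblup``, ``bayesA``, ``bayesB``, ``bayesC``
(parameter-free, continuous traits, additive encoding) and the searchable
penalized baselines ``linreg-l1``, ``linreg-l2``, ``elasticnet``
(continuous and discrete traits). New models are added through
:func:`register_model` with a :class:`ModelContract`.
"""

from __future__ import annotations

import numpy as np

from .base import (
    CategoricalDim,
    HyperparamSpace,
    IntDim,
    ModelContract,
    RealDim,
    aggregate_importance,
    get_model,
    list_models,
    register_model,
)
from .bayes import BayesAlphabet, BayesAlphabetResults
from .linear import PenalizedLinear, PenalizedLinearResults
from .rrblup import RRBLUP, RRBLUPResults

__all__ = [
    "CategoricalDim",
    "IntDim",
    "RealDim",
    "HyperparamSpace",
    "ModelContract",
    "register_model",
    "get_model",
    "list_models",
    "aggregate_importance",
    "RRBLUP",
    "RRBLUPResults",
    "BayesAlphabet",
    "BayesAlphabetResults",
    "PenalizedLinear",
    "PenalizedLinearResults",
]


class _RRBLUPEstimator:
    """Registry adapter around :class:`RRBLUP` (REML-fit, no hyperparameters)."""

    def __init__(self, params: dict, trait_type: str):
        if trait_type != "continuous":
            raise ValueError("rrblup supports continuous traits only")
        self.params = params
        self.results: RRBLUPResults | None = None

    def fit(self, X, y):
        self.results = RRBLUP(y, X).fit(lam=self.params.get("lam"))
        return self

    def predict(self, X):
        return self.results.predict(X)

    def feature_importance(self):
        return self.results.feature_importance()

    def to_state(self) -> dict:
        return self.results.to_state()


class _BayesEstimator:
    """Registry adapter around :class:`BayesAlphabet`.

    Recognized entries in ``params``: ``pi``, ``n_iter``, ``burn_in``,
    ``thin``, ``chain_seed`` (all optional; defaults are the package
    chain defaults).
    """

    def __init__(self, variant: str, params: dict, trait_type: str):
        if trait_type != "continuous":
            raise ValueError(f"bayes{variant} supports continuous traits only")
        self.variant = variant
        self.params = params
        self.results: BayesAlphabetResults | None = None

    def fit(self, X, y):
        p = self.params
        kwargs = {}
        if self.variant in ("B", "C"):
            kwargs["pi"] = p.get("pi", 0.95)
        model = BayesAlphabet(y, X, variant=self.variant, **kwargs)
        self.results = model.fit(
            n_iter=p.get("n_iter", 6000),
            burn_in=p.get("burn_in", 1000),
            thin=p.get("thin", 5),
            seed=p.get("chain_seed", 0),
        )
        return self

    def predict(self, X):
        return self.results.predict(X)

    def feature_importance(self):
        return self.results.feature_importance()

    def to_state(self) -> dict:
        return self.results.to_state()


class _LinearEstimator:
    """Registry adapter around :class:`PenalizedLinear`."""

    def __init__(self, penalty: str, params: dict, trait_type: str):
        self.penalty = penalty
        self.params = params
        self.trait_type = trait_type
        self.results: PenalizedLinearResults | None = None

    def fit(self, X, y):
        model = PenalizedLinear(y, X, penalty=self.penalty, trait_type=self.trait_type)
        self.results = model.fit(
            strength=self.params.get("strength", 1.0),
            mix=self.params.get("mix", 0.5),
        )
        return self

    def predict(self, X):
        return self.results.predict(X)

    def feature_importance(self):
        return self.results.feature_importance()

    def to_state(self) -> dict:
        return self.results.to_state()


def _register_builtins() -> None:
    register_model(ModelContract(
        name="rrblup",
        trait_types=("continuous",),
        default_encoding="additive_012",
        allowed_encodings=("additive_012",),
        kind="param_free",
        factory=lambda params, trait_type: _RRBLUPEstimator(params, trait_type),
    ))
    for variant in ("A", "B", "C"):
        register_model(ModelContract(
            name=f"bayes{variant}",
            trait_types=("continuous",),
            default_encoding="additive_012",
            allowed_encodings=("additive_012",),
            kind="param_free",
            factory=(lambda v: lambda params, trait_type: _BayesEstimator(v, params, trait_type))(variant),
        ))
    strength = RealDim("strength", 1e-3, 1e3, log=True)
    register_model(ModelContract(
        name="linreg-l1",
        trait_types=("continuous", "discrete"),
        default_encoding="additive_012",
        allowed_encodings=("additive_012", "onehot"),
        kind="searchable",
        factory=lambda params, trait_type: _LinearEstimator("l1", params, trait_type),
        space=HyperparamSpace([strength]),
    ))
    register_model(ModelContract(
        name="linreg-l2",
        trait_types=("continuous", "discrete"),
        default_encoding="additive_012",
        allowed_encodings=("additive_012", "onehot"),
        kind="searchable",
        factory=lambda params, trait_type: _LinearEstimator("l2", params, trait_type),
        space=HyperparamSpace([strength]),
    ))
    register_model(ModelContract(
        name="elasticnet",
        trait_types=("continuous", "discrete"),
        default_encoding="additive_012",
        allowed_encodings=("additive_012", "onehot"),
        kind="searchable",
        factory=lambda params, trait_type: _LinearEstimator("elastic-net", params, trait_type),
        space=HyperparamSpace([strength, RealDim("mix", 0.05, 0.95)]),
    ))


_register_builtins()
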