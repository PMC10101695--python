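"""Regularized linear / logistic baselines (L1, L2, elastic net).

Continuous traits get penalized least squares, discrete traits the
corresponding penalized logistic regression. The estimation itself is
delegated to scikit-learn; this module fixes the parameterization used
throughout the package: ``strength`` is the penalty weight (lambda), and
for L2 on centered data the coefficients coincide with the RR-BLUP /
ridge solution at the same lambda. ``strength = 0`` falls back to the
unpenalized fit.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LinearRegression,
    LogisticRegression,
    Ridge,
)

__all__ = ["PenalizedLinear", "PenalizedLinearResults"]

_PENALTIES = ("l1", "l2", "elastic-net")


class PenalizedLinear:
    """Penalized linear (continuous y) or logistic (discrete y) regression.

    Parameters
    ----------
    y, X : response and feature matrix.
    penalty : 'l1', 'l2' or 'elastic-net'.
    trait_type : 'continuous' or 'discrete'.
    """

    def __init__(self, y, X, penalty: str = "l2", trait_type: str = "continuous"):
        if penalty not in _PENALTIES:
            raise ValueError(f"penalty must be one of {_PENALTIES}")
        self.y = np.asarray(y)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        self.penalty = penalty
        self.trait_type = trait_type

    def fit(self, strength: float = 1.0, mix: float = 0.5) -> "PenalizedLinearResults":
        """Fit at penalty weight ``strength``; ``mix`` is the elastic-net
        L1 proportion (ignored otherwise)."""
        if strength < 0:
            raise ValueError("penalty strength must be >= 0")
        n = self.X.shape[0]
        if self.trait_type == "continuous":
            y = self.y.astype(float)
            if strength == 0:
                est = LinearRegression()
            elif self.penalty == "l2":
                est = Ridge(alpha=strength)
            elif self.penalty == "l1":
                # sklearn's lasso objective divides the RSS by n
                est = Lasso(alpha=strength / n, max_iter=50_000)
            else:
                est = ElasticNet(alpha=strength / n, l1_ratio=mix, max_iter=50_000)
            est.fit(self.X, y)
            coef = np.ravel(est.coef_)
            intercept = float(est.intercept_)
            return PenalizedLinearResults(self, coef, intercept, classes=None,
                                          sk_model=est, strength=strength, mix=mix)
        # discrete -> logistic; l1_ratio encodes the penalty (0=L2, 1=L1)
        C = np.inf if strength == 0 else 1.0 / strength
        l1_ratio = {"l2": 0.0, "l1": 1.0, "elastic-net": mix}[self.penalty]
        est = LogisticRegression(C=C, l1_ratio=l1_ratio, solver="saga",
                                 max_iter=20_000)
        est.fit(self.X, self.y)
        coef = est.coef_
        return PenalizedLinearResults(self, coef, est.intercept_, classes=est.classes_,
                                      sk_model=est, strength=strength, mix=mix)


class PenalizedLinearResults:
    """Fitted penalized model; coefficients double as feature importances."""

    def __init__(self, model, coef, intercept, classes, sk_model, strength, mix):
        self.model = model
        self.coef = coef
        self.intercept = intercept
        self.classes = classes
        self._sk = sk_model
        self.strength = strength
        self.mix = mix

    @property
    def params(self) -> np.ndarray:
        return self.coef

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.model.X.shape[1]:
            raise ValueError("feature count mismatch with fitted model")
        return self._sk.predict(X_new)

    def feature_importance(self) -> np.ndarray:
        """|coefficient| per feature (summed over classes for multinomial fits)."""
        coef = np.atleast_2d(self.coef)
        return np.sum(np.abs(coef), axis=0)

    def summary(self) -> str:
        kind = "logistic" if self.classes is not None else "linear"
        nz = int(np.sum(np.atleast_2d(self.coef) != 0))
        lines = [
            f"Penalized {kind} regression ({self.model.penalty})",
            "=" * 46,
            f"n samples            {self.model.X.shape[0]:>12d}",
            f"n features           {self.model.X.shape[1]:>12d}",
            f"penalty strength     {self.strength:>12.6g}",
            f"non-zero coef        {nz:>12d}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_state(self) -> dict:
        return {
            "mu": np.asarray(self.intercept).tolist(),
            "u": np.asarray(self.coef).tolist(),
            "classes": None if self.classes is None else np.asarray(self.classes).tolist(),
            "penalty": self.model.penalty,
            "strength": self.strength,
            "mix": self.mix,
        }
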