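"""Ridge-regression BLUP (RR-BLUP) with REML variance components.

Model: y = mu*1 + Z u + e, with marker effects u ~ N(0, sigma2_u I_m) and
residuals e ~ N(0, sigma2_e I_n); Z is the additive dosage matrix,
column-centered by its training means. Marginally y ~ N(mu*1, sigma2_u K +
sigma2_e I) with K = Z_c Z_c'. The variance ratio delta = sigma2_e /
sigma2_u is estimated by restricted maximum likelihood using a single
eigendecomposition of K followed by a 1-D optimization, after which the
effect estimates have the closed form

    u_hat = Z_c' (K + delta I)^{-1} (y - mu_hat),

which coincides with the primal ridge solution (Z_c'Z_c + delta I)^{-1}
Z_c' (y - y_bar) for any fixed delta.

Narrow-sense heritability is reported as the fraction of phenotypic
variance captured by the markers, h2 = s2g / (s2g + sigma2_e) with per-
sample genetic variance s2g = sigma2_u * tr(K)/n.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import helmert
from scipy.optimize import minimize_scalar

__all__ = ["RRBLUP", "RRBLUPResults"]


class RRBLUP:
    """RR-BLUP model for a continuous phenotype.

    Parameters
    ----------
    y : (n,) continuous phenotype.
    Z : (n, m) additive dosage matrix (uncentered; training column means
        are computed and stored here).
    marker_ids : optional marker names carried into the results.
    """

    def __init__(self, y, Z, marker_ids=None):
        self.y = np.asarray(y, dtype=float).ravel()
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[0] != self.y.shape[0]:
            raise ValueError("Z must be (n_samples, n_markers) matching y")
        if self.y.shape[0] < 3:
            raise ValueError("RR-BLUP requires n >= 3 samples")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite phenotype values")
        if np.var(self.y) == 0:
            raise ValueError("constant phenotype: variance components are unidentifiable")
        self.col_means = Z.mean(axis=0)
        self.Zc = Z - self.col_means
        self.marker_ids = list(marker_ids) if marker_ids is not None else None

    def fit(self, lam: float | None = None, bounds: tuple[float, float] = (-12.0, 12.0)) -> "RRBLUPResults":
        """Fit the model.

        With ``lam`` given, the shrinkage is fixed and only the effects are
        solved; otherwise delta is estimated by REML (1-D bounded search
        over log delta within ``bounds``).
        """
        n, m = self.Zc.shape
        y = self.y
        K = self.Zc @ self.Zc.T
        trK_n = np.trace(K) / n

        if lam is not None:
            if lam <= 0:
                raise ValueError("fixed lambda must be > 0")
            delta = float(lam)
            sigma2_u = np.nan
            sigma2_e = np.nan
            reml_ll = np.nan
        else:
            # Restricted likelihood: project out the intercept with a
            # Helmert contrast (rows orthonormal, orthogonal to 1).
            Q = helmert(n)
            Kt = Q @ K @ Q.T
            yt = Q @ y
            lam_eig, V = np.linalg.eigh(Kt)
            lam_eig = np.clip(lam_eig, 0.0, None)
            w2 = (V.T @ yt) ** 2

            def neg_reml(log_delta: float) -> float:
                d = np.exp(log_delta)
                denom = lam_eig + d
                s = np.sum(w2 / denom)
                return (n - 1) * np.log(s) + np.sum(np.log(denom))

            res = minimize_scalar(neg_reml, bounds=bounds, method="bounded",
                                  options={"xatol": 1e-8})
            if not res.success:
                raise RuntimeError(f"REML optimization did not converge: {res.message}")
            delta = float(np.exp(res.x))
            sigma2_u = float(np.sum(w2 / (lam_eig + delta)) / (n - 1))
            sigma2_e = float(delta * sigma2_u)
            reml_ll = float(-0.5 * (res.fun + (n - 1) * (1 + np.log(2 * np.pi / (n - 1)))))

        Vmat = K + delta * np.eye(n)
        Vinv_1 = np.linalg.solve(Vmat, np.ones(n))
        Vinv_y = np.linalg.solve(Vmat, y)
        mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
        resid = y - mu
        u_hat = self.Zc.T @ np.linalg.solve(Vmat, resid)
        if not np.all(np.isfinite(u_hat)):
            raise RuntimeError("non-finite marker effects; system is ill-conditioned")

        h2 = trK_n / (trK_n + delta) if trK_n > 0 else 0.0
        return RRBLUPResults(
            model=self, mu=mu, u=u_hat, lam=delta,
            sigma2_u=sigma2_u, sigma2_e=sigma2_e, h2=float(h2), reml_loglik=reml_ll,
        )


class RRBLUPResults:
    """Fitted RR-BLUP: intercept, shrunken marker effects and variance components."""

    def __init__(self, model, mu, u, lam, sigma2_u, sigma2_e, h2, reml_loglik):
        self.model = model
        self.mu = mu
        self.u = u
        self.lam = lam
        self.sigma2_u = sigma2_u
        self.sigma2_e = sigma2_e
        self.h2 = h2
        self.reml_loglik = reml_loglik

    @property
    def params(self) -> np.ndarray:
        return self.u

    def predict(self, Z_new) -> np.ndarray:
        """Predict phenotypes for new samples; Z_new is centered with the
        TRAINING column means before the matrix product."""
        Z_new = np.asarray(Z_new, dtype=float)
        if Z_new.ndim != 2 or Z_new.shape[1] != self.u.shape[0]:
            raise ValueError(
                f"marker count mismatch: fit has {self.u.shape[0]} markers, "
                f"new data has {Z_new.shape[1] if Z_new.ndim == 2 else 'invalid'}"
            )
        return self.mu + (Z_new - self.model.col_means) @ self.u

    def fittedvalues(self) -> np.ndarray:
        return self.mu + self.model.Zc @ self.u

    def feature_importance(self) -> np.ndarray:
        """Absolute shrunken effect per marker."""
        return np.abs(self.u)

    def summary(self) -> str:
        n, m = self.model.Zc.shape
        lines = [
            "RR-BLUP results",
            "=" * 46,
            f"n samples            {n:>12d}",
            f"n markers            {m:>12d}",
            f"intercept (mu)       {self.mu:>12.6g}",
            f"lambda (s2e/s2u)     {self.lam:>12.6g}",
            f"sigma2_u             {self.sigma2_u:>12.6g}",
            f"sigma2_e             {self.sigma2_e:>12.6g}",
            f"h2 (marker-based)    {self.h2:>12.4f}",
            f"REML log-likelihood  {self.reml_loglik:>12.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_state(self) -> dict:
        return {
            "mu": self.mu,
            "u": self.u.tolist(),
            "lam": self.lam,
            "sigma2_u": None if np.isnan(self.sigma2_u) else self.sigma2_u,
            "sigma2_e": None if np.isnan(self.sigma2_e) else self.sigma2_e,
            "h2": self.h2,
            "col_means": self.model.col_means.tolist(),
        }
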