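"""Bayesian-alphabet marker-effect models via single-site Gibbs sampling.

All three variants share the linear model y = mu + Z_c beta + e with
residuals e ~ N(0, sigma2_e I) and a scaled-inverse-chi-square prior on
sigma2_e. They differ in the prior on marker effects:

* **BayesA** — every marker has an effect, beta_j ~ N(0, sigma2_j) with its
  own scaled-inverse-chi-square(nu_u, S_u) variance (marginally a scaled t).
* **BayesB** — BayesA's per-marker variances plus a point mass at zero:
  each marker carries an inclusion indicator with prior P(excluded) = pi.
* **BayesC** — point mass at zero with mixing pi, but a single effect
  variance sigma2_beta shared by all included markers.

Conjugate updates throughout; indicator sampling integrates the effect out
analytically. The sampler is fully deterministic given (data, variant,
chain settings, seed): random draws are batched per iteration in a fixed
order, so the seed-to-chain mapping never depends on the sampled path.

With pi = 0 and both variances fixed, BayesC's posterior-mean effects
converge to the ridge / RR-BLUP solution at lambda = sigma2_e / sigma2_u —
used as an independent cross-check in the tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BayesAlphabet", "BayesAlphabetResults"]

_VARIANTS = ("A", "B", "C")


class BayesAlphabet:
    """Gibbs-sampled Bayesian marker-effect model for a continuous phenotype.

    Parameters
    ----------
    y, Z : phenotype vector and additive dosage matrix (columns centered
        internally by their training means).
    variant : 'A', 'B' or 'C'.
    pi : prior exclusion probability for B/C (ignored for A); in [0, 1).
    nu_u, s_u : prior degrees of freedom and scale for effect variances;
        ``s_u=None`` selects a method-of-moments default in which the prior
        mode equals 0.5 * var(y) * h2_prior / m (divided by 1 - pi for B/C
        so the implied genetic variance stays comparable).
    nu_e, s_e : residual-variance prior; default scale puts the prior mode
        at 0.5 * var(y).
    fixed_sigma2_u, fixed_sigma2_e : freeze a variance instead of sampling
        it (used for the ridge limiting case).
    """

    def __init__(
        self,
        y,
        Z,
        variant: str = "C",
        *,
        pi: float = 0.95,
        nu_u: float = 5.0,
        s_u: float | None = None,
        nu_e: float = 5.0,
        s_e: float | None = None,
        h2_prior: float = 0.5,
        fixed_sigma2_u: float | None = None,
        fixed_sigma2_e: float | None = None,
        marker_ids=None,
    ):
        if variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
        self.y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite phenotype values")
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[0] != self.y.shape[0]:
            raise ValueError("Z must be (n_samples, n_markers) matching y")
        if variant in ("B", "C") and not 0.0 <= pi < 1.0:
            raise ValueError(f"pi must lie in [0, 1), got {pi}")
        self.variant = variant
        self.pi = float(pi) if variant in ("B", "C") else 0.0
        self.col_means = Z.mean(axis=0)
        self.Zc = np.asfortranarray(Z - self.col_means)
        self.marker_ids = list(marker_ids) if marker_ids is not None else None

        n, m = self.Zc.shape
        vary = float(np.var(self.y))
        if vary == 0:
            raise ValueError("constant phenotype")
        self.nu_u = float(nu_u)
        self.nu_e = float(nu_e)
        if s_u is None:
            mode = 0.5 * vary * h2_prior / max(m, 1)
            if self.variant in ("B", "C"):
                mode /= max(1.0 - self.pi, 1e-3)
            s_u = mode * (self.nu_u + 2.0) / self.nu_u
        self.s_u = float(s_u)
        if s_e is None:
            s_e = 0.5 * vary * (self.nu_e + 2.0) / self.nu_e
        self.s_e = float(s_e)
        self.fixed_sigma2_u = fixed_sigma2_u
        self.fixed_sigma2_e = fixed_sigma2_e

    def fit(
        self,
        n_iter: int = 6000,
        burn_in: int = 1000,
        thin: int = 5,
        seed: int = 0,
    ) -> "BayesAlphabetResults":
        """Run the Gibbs chain and return posterior summaries.

        ``n_iter`` total iterations, the first ``burn_in`` discarded, every
        ``thin``-th kept thereafter.
        """
        if not (n_iter > burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        rng = np.random.default_rng(seed)
        X = self.Zc
        y = self.y
        n, m = X.shape
        cols = [np.ascontiguousarray(X[:, j]) for j in range(m)]
        cvec = np.array([c @ c for c in cols])
        vary = float(np.var(y))

        variant = self.variant
        pi = self.pi
        nu_u, s_u = self.nu_u, self.s_u
        nu_e, s_e = self.nu_e, self.s_e
        fix_u = self.fixed_sigma2_u
        fix_e = self.fixed_sigma2_e

        # state
        mu = float(np.mean(y))
        alpha = np.zeros(m)  # effective effects (0 when excluded)
        delta = np.ones(m, dtype=bool)
        sigma2_j = np.full(m, s_u)  # per-marker (A/B); index 0 used as shared (C)
        sigma2_beta = s_u if fix_u is None else float(fix_u)
        sigma2_e = 0.5 * vary if fix_e is None else float(fix_e)
        e = y - mu  # residual (alpha = 0)

        n_kept = 0
        sum_alpha = np.zeros(m)
        sum_delta = np.zeros(m)
        sum_mu = 0.0
        sum_s2e = 0.0
        sum_s2b = 0.0

        log1mpi = np.log1p(-pi) if pi > 0 else 0.0
        logpi = np.log(pi) if pi > 0 else -np.inf

        for it in range(n_iter):
            # fixed-order batched draws keep the chain seed-deterministic
            znorm = rng.standard_normal(m)
            unis = rng.random(m)
            chi_post = rng.chisquare(nu_u + 1.0, m)
            chi_prior = rng.chisquare(nu_u, m)
            mu_norm = rng.standard_normal()
            chi_e = rng.chisquare(nu_e + n)

            # intercept (flat prior)
            offset = float(np.mean(e)) + mu
            mu_new = offset + np.sqrt(sigma2_e / n) * mu_norm
            e += mu - mu_new
            mu = mu_new

            include_all = variant == "A" or pi == 0.0
            for j in range(m):
                z = cols[j]
                cj = cvec[j]
                if cj == 0.0:
                    alpha[j] = 0.0
                    delta[j] = include_all
                    continue
                a_old = alpha[j]
                rhs = float(z @ e) + cj * a_old
                s2b = sigma2_beta if variant == "C" else sigma2_j[j]
                if include_all:
                    inc = True
                else:
                    # integrated likelihood ratio for delta_j = 1 vs 0
                    t = cj * s2b + sigma2_e
                    log_bf = 0.5 * np.log(sigma2_e / t) + 0.5 * rhs * rhs * s2b / (sigma2_e * t)
                    log_p1 = log1mpi + log_bf
                    # P(delta=1) = 1 / (1 + exp(logpi - log_p1))
                    d = logpi - log_p1
                    p1 = 1.0 / (1.0 + np.exp(d)) if d < 35 else 0.0
                    inc = unis[j] < p1
                if inc:
                    lam_j = sigma2_e / s2b
                    denom = cj + lam_j
                    mean = rhs / denom
                    sd = np.sqrt(sigma2_e / denom)
                    a_new = mean + sd * znorm[j]
                    delta[j] = True
                else:
                    a_new = 0.0
                    delta[j] = False
                if a_new != a_old:
                    e += z * (a_old - a_new)
                    alpha[j] = a_new
                # per-marker variance update (A and B)
                if variant in ("A", "B") and fix_u is None:
                    if delta[j]:
                        sigma2_j[j] = (nu_u * s_u + alpha[j] ** 2) / chi_post[j]
                    else:
                        sigma2_j[j] = nu_u * s_u / chi_prior[j]

            # shared effect variance (C)
            if variant == "C" and fix_u is None:
                m_in = int(np.sum(delta))
                ssq = float(np.sum(alpha[delta] ** 2))
                sigma2_beta = (nu_u * s_u + ssq) / rng.chisquare(nu_u + m_in)

            # residual variance
            if fix_e is None:
                sigma2_e = (nu_e * s_e + float(e @ e)) / chi_e

            if it >= burn_in and (it - burn_in) % thin == 0:
                n_kept += 1
                sum_alpha += alpha
                sum_delta += delta
                sum_mu += mu
                sum_s2e += sigma2_e
                sum_s2b += sigma2_beta if variant == "C" else float(np.mean(sigma2_j))

        effects = sum_alpha / n_kept
        return BayesAlphabetResults(
            model=self,
            mu=sum_mu / n_kept,
            effects=effects,
            inclusion_prob=sum_delta / n_kept,
            sigma2_e=sum_s2e / n_kept,
            sigma2_u=sum_s2b / n_kept,
            chain={"n_iter": n_iter, "burn_in": burn_in, "thin": thin, "seed": seed,
                   "n_kept": n_kept},
        )


class BayesAlphabetResults:
    """Posterior summaries of a Bayesian-alphabet fit."""

    def __init__(self, model, mu, effects, inclusion_prob, sigma2_e, sigma2_u, chain):
        self.model = model
        self.mu = mu
        self.effects = effects
        self.inclusion_prob = inclusion_prob
        self.sigma2_e = sigma2_e
        self.sigma2_u = sigma2_u
        self.chain = chain

    @property
    def params(self) -> np.ndarray:
        return self.effects

    def predict(self, Z_new) -> np.ndarray:
        Z_new = np.asarray(Z_new, dtype=float)
        if Z_new.ndim != 2 or Z_new.shape[1] != self.effects.shape[0]:
            raise ValueError("marker count mismatch with fitted model")
        return self.mu + (Z_new - self.model.col_means) @ self.effects

    def feature_importance(self) -> np.ndarray:
        """Absolute posterior-mean effect per marker."""
        return np.abs(self.effects)

    def summary(self) -> str:
        n, m = self.model.Zc.shape
        lines = [
            f"Bayes{self.model.variant} results (Gibbs)",
            "=" * 46,
            f"n samples            {n:>12d}",
            f"n markers            {m:>12d}",
            f"pi (exclusion prior) {self.model.pi:>12.3f}",
            f"chain                {self.chain['n_iter']} iter / {self.chain['burn_in']} burn-in / thin {self.chain['thin']}",
            f"kept samples         {self.chain['n_kept']:>12d}",
            f"intercept (mu)       {self.mu:>12.6g}",
            f"sigma2_e (post mean) {self.sigma2_e:>12.6g}",
            f"sigma2_u (post mean) {self.sigma2_u:>12.6g}",
            f"mean incl. prob      {float(np.mean(self.inclusion_prob)):>12.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_state(self) -> dict:
        return {
            "mu": self.mu,
            "u": self.effects.tolist(),
            "inclusion_prob": self.inclusion_prob.tolist(),
            "sigma2_e": self.sigma2_e,
            "sigma2_u": self.sigma2_u,
            "chain": self.chain,
            "col_means": self.model.col_means.tolist(),
        }
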