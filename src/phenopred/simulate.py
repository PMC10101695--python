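"""Synthetic genotypes and linear-mixed-model phenotype simulation.

The genotype generator draws independent biallelic markers under
Hardy-Weinberg proportions at a minor-allele frequency sampled per marker
from a configurable range — a fixture generator, not a model of linkage.

The phenotype simulator implements an additive linear mixed model with a
known causal architecture:

    y = mu + Z_c beta (+ Z u_bg) + eps,

where a chosen number of causal markers receive effects drawn from a
configurable distribution, an optional polygenic background adds small
i.i.d. effects on all markers, and the noise is scaled so the realized
heritability var(g)/var(y) hits the target h2. Every ingredient (causal
ids, effects, genetic values, realized h2, config, seed) is recorded so a
simulation is fully self-describing and exactly reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import RawGenotype
from .preprocess import EncodedGenotype, encode_additive

__all__ = [
    "SimulationConfig",
    "SimulatedPhenotype",
    "simulate_genotypes",
    "simulate_phenotype",
    "export_simulation",
]

_NUCS = np.array(list("ACGT"))


def simulate_genotypes(
    n_samples: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> RawGenotype:
    """Independent biallelic markers under Hardy-Weinberg proportions.

    Per marker, the minor-allele frequency is drawn uniformly from
    ``maf_range`` (a subset of (0, 0.5]) and genotype classes are sampled
    with probabilities (q^2, 2pq, p^2). Deterministic per seed.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    calls = np.empty((n_samples, n_markers), dtype="<U2")
    for j in range(n_markers):
        p = rng.uniform(lo, hi)  # minor-allele frequency
        a, b = rng.choice(4, size=2, replace=False)
        minor, major = str(_NUCS[a]), str(_NUCS[b])
        dosage = rng.binomial(2, p, size=n_samples)  # copies of the minor allele
        hom_major = major + major
        het = minor + major if minor <= major else major + minor
        hom_minor = minor + minor
        lut = np.array([hom_major, het, hom_minor], dtype="<U2")
        calls[:, j] = lut[dosage]
    return RawGenotype(sample_ids, marker_ids, calls)


@dataclass
class SimulationConfig:
    """Knobs of the phenotype simulator.

    h2 is the target heritability in [0, 1); effect_distribution in
    {'gaussian', 'laplace', 'equal'}; noise_distribution in {'gaussian',
    'gamma-skewed'} (the gamma option, shape 2, is mean-centered and
    variance-scaled to keep the location and the h2 construction intact);
    n_classes discretizes y by quantiles into labeled classes when >= 2.
    """

    n_causal: int = 20
    h2: float = 0.5
    effect_distribution: str = "gaussian"
    include_background: bool = False
    noise_distribution: str = "gaussian"
    seed: int = 0
    n_classes: int = 0  # 0 = continuous
    mu: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError(f"h2 must lie in [0, 1), got {self.h2}")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.effect_distribution not in ("gaussian", "laplace", "equal"):
            raise ValueError(f"unknown effect distribution {self.effect_distribution!r}")
        if self.noise_distribution not in ("gaussian", "gamma-skewed"):
            raise ValueError(f"unknown noise distribution {self.noise_distribution!r}")


@dataclass
class SimulatedPhenotype:
    """A simulated trait with its full ground truth."""

    y: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    causal_ids: list[str]
    beta: np.ndarray  # per-marker true effects (zeros off-causal)
    g: np.ndarray  # genetic value per sample
    realized_h2: float
    config: SimulationConfig = field(default_factory=SimulationConfig)
    classes: np.ndarray | None = None  # discretized labels when configured

    @property
    def trait_values(self) -> np.ndarray:
        return self.classes if self.classes is not None else self.y


def _background_fraction() -> float:
    """Background polygenic variance as a fraction of the causal genetic variance."""
    return 0.10


def simulate_phenotype(
    geno: RawGenotype | EncodedGenotype,
    cfg: SimulationConfig,
) -> SimulatedPhenotype:
    """Simulate a phenotype on the given genotypes under the additive LMM.

    Causal markers are drawn uniformly (without replacement) among the
    polymorphic markers; noise is rescaled against the empirical var(g) so
    that var(g) / (var(g) + var(eps)) equals h2.
    """
    enc = geno if isinstance(geno, EncodedGenotype) else encode_additive(geno)
    Z = enc.matrix - enc.matrix.mean(axis=0)
    n, m = Z.shape
    if cfg.n_causal > m:
        raise ValueError(f"n_causal={cfg.n_causal} exceeds marker count {m}")
    rng = np.random.default_rng(cfg.seed)

    polymorphic = np.flatnonzero(Z.var(axis=0) > 0)
    if cfg.n_causal > 0 and len(polymorphic) < cfg.n_causal:
        raise ValueError("not enough polymorphic markers for the requested n_causal")

    beta = np.zeros(m)
    causal = np.sort(rng.choice(polymorphic, size=cfg.n_causal, replace=False)) if cfg.n_causal else np.array([], dtype=int)
    if cfg.n_causal:
        if cfg.effect_distribution == "gaussian":
            raw = rng.standard_normal(cfg.n_causal)
        elif cfg.effect_distribution == "laplace":
            raw = rng.laplace(size=cfg.n_causal)
        else:  # equal
            raw = np.ones(cfg.n_causal)
        beta[causal] = raw

    g = Z @ beta
    if cfg.include_background:
        var_g = float(np.var(g))
        target_bg = _background_fraction() * var_g if var_g > 0 else 1.0
        u_bg = rng.standard_normal(m)
        g_bg = Z @ u_bg
        vb = float(np.var(g_bg))
        if vb > 0:
            g_bg *= np.sqrt(target_bg / vb)
        g = g + g_bg

    var_g = float(np.var(g))
    if cfg.h2 > 0 and var_g == 0:
        raise ValueError(
            "h2 > 0 requires genetic variance: set n_causal > 0 or include_background"
        )

    if cfg.h2 == 0:
        # pure noise: the genetic signal contributes nothing
        beta = np.zeros(m)
        g = np.zeros(n)
        eps = _draw_noise(rng, n, 1.0, cfg.noise_distribution)
    else:
        target_var_eps = var_g * (1.0 - cfg.h2) / cfg.h2
        eps = _draw_noise(rng, n, target_var_eps, cfg.noise_distribution)

    y = cfg.mu + g + eps
    vy = float(np.var(y))
    realized = float(np.var(g) / vy) if vy > 0 else 0.0

    classes = None
    if cfg.n_classes >= 2:
        qs = np.quantile(y, np.linspace(0, 1, cfg.n_classes + 1)[1:-1])
        classes = np.searchsorted(qs, y, side="right").astype(int)

    return SimulatedPhenotype(
        y=y,
        sample_ids=list(enc.sample_ids),
        marker_ids=list(enc.marker_ids),
        causal_ids=[enc.marker_ids[j] for j in causal],
        beta=beta,
        g=g,
        realized_h2=realized,
        config=cfg,
        classes=classes,
    )


def _draw_noise(rng: np.random.Generator, n: int, target_var: float, dist: str) -> np.ndarray:
    if dist == "gaussian":
        eps = rng.standard_normal(n)
    else:  # gamma-skewed, shape 2, mean-centered
        eps = rng.gamma(shape=2.0, scale=1.0, size=n) - 2.0
    eps = eps - eps.mean()
    v = float(np.var(eps))
    if v > 0:
        eps *= np.sqrt(target_var / v)
    return eps


def export_simulation(sim: SimulatedPhenotype, out_dir: str | os.PathLike, trait_name: str = "sim_trait") -> tuple[str, str]:
    """Write the phenotype and ground-truth CSVs (config embedded as '#' comments).

    Returns (phenotype_path, ground_truth_path). The phenotype file is
    ingestible by :func:`phenopred.genotype_io.read_phenotype_csv`.
    """
    os.makedirs(out_dir, exist_ok=True)
    cfg_items = asdict(sim.config)
    header = "".join(f"# {k}={v}\n" for k, v in sorted(cfg_items.items()))
    header += f"# realized_h2={sim.realized_h2!r}\n"

    pheno_path = os.path.join(out_dir, "phenotype.csv")
    values = sim.trait_values
    with open(pheno_path, "w") as fh:
        fh.write(header)
        pd.DataFrame({"sample_id": sim.sample_ids, trait_name: values}).to_csv(fh, index=False)

    truth_path = os.path.join(out_dir, "ground_truth.csv")
    causal_set = set(sim.causal_ids)
    with open(truth_path, "w") as fh:
        fh.write(header)
        pd.DataFrame({
            "marker_id": sim.marker_ids,
            "beta": sim.beta,
            "causal": [int(mid in causal_set) for mid in sim.marker_ids],
        }).to_csv(fh, index=False)
    return pheno_path, truth_path
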