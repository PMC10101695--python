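import numpy as np
import pytest

import phenopred as pp


@pytest.fixture
def tiny_raw() -> pp.RawGenotype:
    """5 samples x 3 markers, hand-written, all invariants satisfied."""
    calls = np.array([
        ["AA", "AG", "CC"],
        ["AG", "GG", "CC"],
        ["GG", "GG", "CT"],
        ["GG", "AG", "CC"],
        ["AG", "AA", "CC"],
    ])
    return pp.RawGenotype([f"s{i}" for i in range(1, 6)], ["m1", "m2", "m3"], calls)


@pytest.fixture
def random_raw():
    """Factory for HWE random genotype fixtures."""

    def make(n=30, m=20, seed=0, maf_range=(0.05, 0.5)):
        return pp.simulate_genotypes(n, m, maf_range, seed=seed)

    return make


@pytest.fixture
def sim_dataset():
    """Small matched dataset with known causal structure (continuous trait)."""
    raw = pp.simulate_genotypes(60, 30, seed=5)
    enc = pp.encode_additive(raw)
    sim = pp.simulate_phenotype(enc, pp.SimulationConfig(n_causal=5, h2=0.6, seed=6))
    ds = pp.MatchedDataset(genotype=enc, y=sim.y, trait="sim_trait", trait_type="continuous")
    return ds, sim
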