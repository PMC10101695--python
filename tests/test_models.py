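"""RR-BLUP, Bayesian-alphabet samplers, penalized baselines and the registry."""

import numpy as np
import pytest

import phenopred as pp
from phenopred.models import (
    BayesAlphabet,
    HyperparamSpace,
    ModelContract,
    PenalizedLinear,
    RRBLUP,
    RealDim,
    aggregate_importance,
    register_model,
)
from phenopred.models.base import _REGISTRY


def ridge_dense(Zc, yc, lam):
    """Closed-form primal ridge oracle on centered data."""
    m = Zc.shape[1]
    return np.linalg.solve(Zc.T @ Zc + lam * np.eye(m), Zc.T @ yc)


class TestRRBLUP:
    def test_fixed_lambda_toy_equals_normal_equations(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        y = np.array([1.0, 2.0, -1.0, 0.5])
        res = RRBLUP(y, Z).fit(lam=1.0)
        Zc = Z - Z.mean(0)
        np.testing.assert_allclose(res.u, ridge_dense(Zc, y - y.mean(), 1.0), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_solution_matches_primal_ridge(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.integers(0, 3, size=(30, 8)).astype(float)
        y = rng.standard_normal(30)
        lam = float(rng.uniform(0.1, 10))
        res = RRBLUP(y, Z).fit(lam=lam)
        Zc = Z - Z.mean(0)
        np.testing.assert_allclose(res.u, ridge_dense(Zc, y - y.mean(), lam),
                                   rtol=1e-8, atol=1e-12)

    def test_extreme_shrinkage_collapses_to_mean(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(20, 5)).astype(float)
        y = rng.standard_normal(20) + 3.0
        res = RRBLUP(y, Z).fit(lam=1e12)
        assert np.abs(res.u).max() < 1e-6
        np.testing.assert_allclose(res.predict(Z), np.full(20, y.mean()), atol=1e-4)

    def test_prediction_is_centered_matrix_product(self, sim_dataset):
        ds, _ = sim_dataset
        res = RRBLUP(ds.y, ds.X).fit()
        Z_new = ds.X[:7]
        expected = res.mu + (Z_new - ds.X.mean(0)) @ res.u
        np.testing.assert_allclose(res.predict(Z_new), expected)
        # a row equal to the training means predicts the intercept
        np.testing.assert_allclose(res.predict(ds.X.mean(0)[None, :]), [res.mu])

    def test_marker_mismatch_rejected(self, sim_dataset):
        ds, _ = sim_dataset
        res = RRBLUP(ds.y, ds.X).fit()
        with pytest.raises(ValueError, match="marker count mismatch"):
            res.predict(ds.X[:, :5])

    def test_constant_phenotype_rejected(self):
        Z = np.zeros((5, 3))
        with pytest.raises(ValueError, match="constant phenotype"):
            RRBLUP(np.ones(5), Z)

    def test_reml_heritability_recovery_light(self):
        """REML h2 estimates track the simulated truth (small Monte Carlo)."""
        ests = []
        for s in range(5):
            raw = pp.simulate_genotypes(200, 80, seed=50 + s)
            enc = pp.encode_additive(raw)
            sim = pp.simulate_phenotype(enc, pp.SimulationConfig(n_causal=10, h2=0.5, seed=s))
            ests.append(RRBLUP(sim.y, enc.matrix).fit().h2)
        assert abs(np.mean(ests) - 0.5) < 0.15


class TestBayesAlphabet:
    def test_same_seed_gives_identical_posterior(self, sim_dataset):
        ds, _ = sim_dataset
        kw = dict(n_iter=400, burn_in=100, thin=2, seed=11)
        a = BayesAlphabet(ds.y, ds.X, variant="B").fit(**kw)
        b = BayesAlphabet(ds.y, ds.X, variant="B").fit(**kw)
        np.testing.assert_array_equal(a.effects, b.effects)
        np.testing.assert_array_equal(a.inclusion_prob, b.inclusion_prob)

    def test_ridge_limit_of_bayesc(self):
        rng = np.random.default_rng(2)
        n, m = 50, 10
        Z = rng.standard_normal((n, m))
        y = Z @ rng.standard_normal(m) * 0.4 + rng.standard_normal(n)
        s2u, s2e = 0.2, 1.0
        res = BayesAlphabet(y, Z, variant="C", pi=0.0,
                            fixed_sigma2_u=s2u, fixed_sigma2_e=s2e).fit(
            n_iter=6000, burn_in=1000, thin=1, seed=4)
        Zc = Z - Z.mean(0)
        oracle = ridge_dense(Zc, y - y.mean(), s2e / s2u)
        assert np.abs(res.effects - oracle).max() < 0.08

    def test_null_data_keeps_bayesb_inclusion_low(self):
        raw = pp.simulate_genotypes(80, 30, seed=9)
        enc = pp.encode_additive(raw)
        y = np.random.default_rng(10).standard_normal(80)  # no genetic signal
        res = BayesAlphabet(y, enc.matrix, variant="B", pi=0.95).fit(
            n_iter=1200, burn_in=300, thin=2, seed=1)
        assert float(np.mean(res.inclusion_prob)) <= 0.15

    @pytest.mark.parametrize("bad_pi", [-0.1, 1.0, 1.5])
    def test_invalid_pi_rejected(self, bad_pi):
        with pytest.raises(ValueError, match="pi"):
            BayesAlphabet(np.arange(5.0), np.zeros((5, 2)), variant="C", pi=bad_pi)

    def test_non_finite_phenotype_rejected(self):
        y = np.array([1.0, np.nan, 2.0])
        with pytest.raises(ValueError, match="non-finite"):
            BayesAlphabet(y, np.zeros((3, 2)))


class TestPenalizedLinear:
    def test_zero_strength_matches_ols(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(40)
        res = PenalizedLinear(y, X, penalty="l1").fit(strength=0)
        Xd = np.column_stack([np.ones(40), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(res.coef, beta[1:], rtol=1e-6)

    def test_l2_equals_rrblup_at_fixed_lambda(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(30, 8)).astype(float)
        y = rng.standard_normal(30)
        lam = 2.5
        sk = PenalizedLinear(y, X, penalty="l2").fit(strength=lam)
        rr = RRBLUP(y, X).fit(lam=lam)
        np.testing.assert_allclose(sk.coef, rr.u, rtol=1e-6, atol=1e-10)

    def test_huge_strength_shrinks_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        res = PenalizedLinear(y, X, penalty="elastic-net").fit(strength=1e9)
        assert np.abs(res.coef).max() < 1e-6

    def test_logistic_for_discrete_traits(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] + 0.2 * rng.standard_normal(60) > 0).astype(int)
        res = PenalizedLinear(y, X, penalty="l2", trait_type="discrete").fit(strength=1.0)
        acc = float(np.mean(res.predict(X) == y))
        assert acc > 0.8
        assert res.feature_importance().argmax() == 0

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            PenalizedLinear(np.arange(5.0), np.zeros((5, 2))).fit(strength=-1)


class TestRegistry:
    def test_duplicate_name_rejected(self):
        with pytest.raises(ValueError, match="already registered"):
            register_model(ModelContract(
                name="rrblup", trait_types=("continuous",),
                default_encoding="additive_012", allowed_encodings=("additive_012",),
                kind="param_free", factory=lambda p, t: None))

    def test_searchable_without_space_rejected(self):
        with pytest.raises(ValueError, match="HyperparamSpace"):
            ModelContract(
                name="x", trait_types=("continuous",),
                default_encoding="additive_012", allowed_encodings=("additive_012",),
                kind="searchable", factory=lambda p, t: None, space=None)

    def test_param_free_mean_predictor_runs_end_to_end(self, sim_dataset):
        ds, _ = sim_dataset

        class MeanPredictor:
            def fit(self, X, y):
                self.mean = float(np.mean(y))
                return self

            def predict(self, X):
                return np.full(len(X), self.mean)

        name = "mean-predictor-test"
        register_model(ModelContract(
            name=name, trait_types=("continuous",),
            default_encoding="additive_012", allowed_encodings=("additive_012",),
            kind="param_free", factory=lambda p, t: MeanPredictor(),
            supports_importance=False))
        try:
            split = pp.make_split(ds.n_samples, "train-val-test", seed=0,
                                  test_frac=0.2, val_frac=0.25)
            run = pp.run_optimization(ds, split, name, n_trials=1, seed=0)
            assert run.counts["n_trials"] == 0  # no search for param-free models
            assert run.test_metrics["mse"] is not None
        finally:
            _REGISTRY.pop(name)


class TestFeatureImportance:
    def test_rrblup_importance_is_absolute_effect(self, sim_dataset):
        ds, _ = sim_dataset
        res = RRBLUP(ds.y, ds.X).fit()
        np.testing.assert_array_equal(res.feature_importance(), np.abs(res.u))

    def test_onehot_block_aggregates_by_absolute_sum(self):
        scores = np.array([0.1, 0.2, -0.3])
        out = aggregate_importance(scores, np.array([0, 0, 0]), 1)
        np.testing.assert_allclose(out, [0.6])

    def test_causal_markers_rank_high_in_importance(self):
        """Large-effect causal markers land in the top decile (median over seeds)."""
        hits = []
        for s in range(8):
            raw = pp.simulate_genotypes(150, 100, seed=200 + s)
            enc = pp.encode_additive(raw)
            sim = pp.simulate_phenotype(enc, pp.SimulationConfig(
                n_causal=5, h2=0.8, effect_distribution="equal", seed=s))
            res = RRBLUP(sim.y, enc.matrix).fit()
            ranks = np.argsort(np.argsort(-res.feature_importance()))  # 0 = most important
            causal_idx = [enc.marker_ids.index(mid) for mid in sim.causal_ids]
            hits.append(np.sum(ranks[causal_idx] < 10))
        assert np.median(hits) >= 4  # at least 4 of 5 in top decile


def test_permutation_null_rrblup_mean_r_near_zero(sim_dataset):
    """Fitting against permuted phenotypes yields no held-out correlation."""
    ds, _ = sim_dataset
    tr, te = np.arange(45), np.arange(45, 60)
    rs = []
    for p in range(20):
        y = ds.y[np.random.default_rng(p).permutation(ds.n_samples)]
        res = RRBLUP(y[tr], ds.X[tr]).fit()
        pred = res.predict(ds.X[te])
        rs.append(0.0 if np.std(pred) == 0 else np.corrcoef(y[te], pred)[0, 1])
    assert abs(np.mean(rs)) < 0.15
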