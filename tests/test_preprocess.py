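"""Encodings, MAF filtering, sample matching and reproducible splits."""

import numpy as np
import pytest

import phenopred as pp
from phenopred.genotype_io import PhenotypeTable
from phenopred.preprocess import (
    compute_maf,
    load_split,
    persist_split,
    regenerate_split,
)
import pandas as pd
import h5py


def brute_force_maf(raw: pp.RawGenotype) -> np.ndarray:
    """Independent per-call allele tally oracle."""
    out = []
    for j in range(raw.n_markers):
        counts: dict[str, int] = {}
        for call in raw.calls[:, j]:
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        if len(counts) < 2:
            out.append(0.0)
        else:
            out.append(min(counts.values()) / (2 * raw.n_samples))
    return np.array(out)


class TestMAF:
    def test_hand_counted_example(self):
        # G allele count 0+1+2+2+1 = 6 of 10 -> minor (A) frequency 0.4
        calls = np.array([["AA"], ["AG"], ["GG"], ["GG"], ["AG"]])
        raw = pp.RawGenotype([f"s{i}" for i in range(5)], ["m1"], calls)
        assert compute_maf(raw)[0] == pytest.approx(0.4)

    def test_constant_marker_is_zero(self):
        calls = np.array([["AA"], ["AA"], ["AA"]])
        raw = pp.RawGenotype(["a", "b", "c"], ["m1"], calls)
        assert compute_maf(raw)[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_tally(self, random_raw, seed):
        raw = random_raw(n=20, m=50, seed=seed)
        np.testing.assert_allclose(compute_maf(raw), brute_force_maf(raw))


class TestMAFFilter:
    def test_strict_threshold_keeps_only_above(self, random_raw):
        raw = random_raw(n=40, m=30, seed=1)
        maf = compute_maf(raw)
        filtered, mask = pp.maf_filter(raw, 0.1)
        assert np.array_equal(mask, maf > 0.1)
        assert filtered.n_markers == int(mask.sum())

    def test_boundary_thresholds(self, random_raw):
        raw = random_raw(n=40, m=30, seed=2)
        maf = compute_maf(raw)
        _, mask0 = pp.maf_filter(raw, 0.0)
        assert np.array_equal(mask0, maf > 0)  # constants removed, polymorphic kept
        _, mask5 = pp.maf_filter(raw, 0.5)
        assert mask5.sum() == 0  # MAF can never exceed 0.5

    def test_monotone_in_threshold(self, random_raw):
        raw = random_raw(n=40, m=50, seed=3)
        _, loose = pp.maf_filter(raw, 0.05)
        _, tight = pp.maf_filter(raw, 0.2)
        assert np.all(loose[tight])  # kept at 0.2 -> kept at 0.05

    def test_invalid_threshold_rejected(self, random_raw):
        with pytest.raises(ValueError, match="threshold"):
            pp.maf_filter(random_raw(), 0.7)


class TestAdditiveEncoding:
    def test_counts_minor_allele_copies(self):
        # A freq 0.75, G freq 0.25 -> G is minor: AA->0, AG->1, GG->2
        calls = np.array([["AA"], ["AA"], ["AG"], ["GG"]])
        raw = pp.RawGenotype(list("abcd"), ["m1"], calls)
        enc = pp.encode_additive(raw)
        assert enc.minor_allele == ["G"]
        assert list(enc.matrix[:, 0]) == [0, 0, 1, 2]

    def test_fifty_fifty_tie_lexicographic(self):
        calls = np.array([["CC"], ["TT"]])
        raw = pp.RawGenotype(["a", "b"], ["m1"], calls)
        enc = pp.encode_additive(raw)
        assert enc.minor_allele == ["C"]
        assert list(enc.matrix[:, 0]) == [2, 0]

    def test_constant_marker_all_zero(self):
        calls = np.array([["AA"], ["AA"], ["AA"]])
        raw = pp.RawGenotype(["a", "b", "c"], ["m1"], calls)
        assert np.all(pp.encode_additive(raw).matrix == 0)

    def test_dosage_decodes_back_to_genotype_classes(self, random_raw):
        raw = random_raw(n=30, m=15, seed=4)
        enc = pp.encode_additive(raw)
        for j in range(raw.n_markers):
            minor, major = enc.minor_allele[j], enc.major_allele[j]
            het = "".join(sorted(minor + major))
            decode = {0: major + major, 1: het, 2: minor + minor}
            rebuilt = [decode[int(d)] for d in enc.matrix[:, j]]
            assert rebuilt == list(raw.calls[:, j])


class TestOnehotEncoding:
    def test_het_block_is_definitional(self):
        calls = np.array([["AA"], ["AG"], ["GG"], ["GG"]])
        raw = pp.RawGenotype(list("abcd"), ["m1"], calls)
        enc = pp.encode_onehot(raw)
        # class order (hom-major, het, hom-minor); sample b is AG
        assert list(enc.matrix[1]) == [0, 1, 0]

    def test_marker_without_heterozygotes_gets_two_columns(self):
        calls = np.array([["AA"], ["GG"], ["AA"]])
        raw = pp.RawGenotype(["a", "b", "c"], ["m1"], calls)
        enc = pp.encode_onehot(raw)
        assert enc.matrix.shape[1] == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_block_row_sums_are_one(self, random_raw, seed):
        raw = random_raw(n=25, m=12, seed=seed)
        enc = pp.encode_onehot(raw)
        for j in range(raw.n_markers):
            block = enc.matrix[:, enc.feature_to_marker == j]
            np.testing.assert_array_equal(block.sum(axis=1), np.ones(raw.n_samples))


class TestMatchSamples:
    def _pheno(self, values: dict) -> PhenotypeTable:
        s = pd.Series(values, dtype=float)
        return PhenotypeTable(data=s.to_frame("t"), trait_types={"t": "continuous"})

    def _geno(self, ids):
        calls = np.array([["AA"], ["AG"], ["GG"]][: len(ids)])
        raw = pp.RawGenotype(ids, ["m1"], calls)
        return pp.encode_additive(raw)

    def test_intersection_with_missing_value_dropped(self):
        geno = self._geno(["a", "b", "c"])
        pheno = self._pheno({"b": 1.0, "c": np.nan, "d": 2.0})
        ds = pp.match_samples(geno, pheno, "t")
        assert ds.genotype.sample_ids == ["b"]
        assert ds.n_dropped == 2

    def test_identical_ids_keep_all(self):
        geno = self._geno(["a", "b", "c"])
        pheno = self._pheno({"a": 1.0, "b": 2.0, "c": 3.0})
        ds = pp.match_samples(geno, pheno, "t")
        assert ds.n_samples == 3
        np.testing.assert_array_equal(ds.y, [1.0, 2.0, 3.0])

    def test_disjoint_ids_error(self):
        geno = self._geno(["a", "b"])
        pheno = self._pheno({"x": 1.0})
        with pytest.raises(ValueError, match="no overlap"):
            pp.match_samples(geno, pheno, "t")


def _all_index_sets(split: pp.SplitIndices) -> list[np.ndarray]:
    if split.split_type == "train-val-test":
        return [split.train, split.val, split.test]
    if split.split_type == "cv-test":
        return [split.test] + [f["val"] for f in split.folds]
    return [o["test"] for o in split.outer]


class TestMakeSplit:
    def test_cv_test_sizes_by_counting(self):
        split = pp.make_split(10, "cv-test", seed=0, test_frac=0.2, k_folds=4)
        assert len(split.test) == 2
        assert sorted(len(f["val"]) for f in split.folds) == [2, 2, 2, 2]
        covered = np.sort(np.concatenate(_all_index_sets(split)))
        np.testing.assert_array_equal(covered, np.arange(10))

    def test_same_inputs_same_indices(self):
        a = pp.make_split(37, "train-val-test", seed=9, test_frac=0.2, val_frac=0.25)
        b = pp.make_split(37, "train-val-test", seed=9, test_frac=0.2, val_frac=0.25)
        for x, y in zip(_all_index_sets(a), _all_index_sets(b)):
            np.testing.assert_array_equal(x, y)

    def test_nested_cv_partition_enumeration(self):
        split = pp.make_split(12, "nested-cv", seed=1, outer_folds=3, inner_folds=2)
        outer_tests = np.sort(np.concatenate([o["test"] for o in split.outer]))
        np.testing.assert_array_equal(outer_tests, np.arange(12))  # each sample once
        for o in split.outer:
            assert len(o["train"]) == 8
            inner_vals = np.sort(np.concatenate([f["val"] for f in o["inner"]]))
            np.testing.assert_array_equal(inner_vals, o["train"])
            assert sorted(len(f["val"]) for f in o["inner"]) == [4, 4]

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        kind = ["train-val-test", "cv-test", "nested-cv"][seed % 3]
        kwargs = dict(seed=seed)
        if kind == "train-val-test":
            kwargs.update(test_frac=0.2, val_frac=0.25)
        elif kind == "cv-test":
            kwargs.update(test_frac=0.2, k_folds=int(rng.integers(2, 6)))
        else:
            kwargs.update(outer_folds=int(rng.integers(2, 5)), inner_folds=2)
        split = pp.make_split(n, kind, **kwargs)
        sets = _all_index_sets(split)
        union = np.concatenate(sets)
        assert len(union) == n and len(np.unique(union)) == n  # disjoint cover
        # fold-level disjointness & leakage-freedom
        for ctx in split.outer_contexts():
            test = set(ctx["test_idx"].tolist())
            for fold in ctx["folds"]:
                assert not test & set(fold["train"].tolist())
                assert not test & set(fold["val"].tolist())
                assert not set(fold["train"].tolist()) & set(fold["val"].tolist())

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="empty partition"):
            pp.make_split(3, "cv-test", seed=0, test_frac=0.2, k_folds=4)

    def test_stratified_split_balances_classes(self):
        labels = np.array([0] * 20 + [1] * 20)
        split = pp.make_split(40, "cv-test", seed=3, test_frac=0.2, k_folds=4, labels=labels)
        test_labels = labels[split.test]
        assert abs((test_labels == 0).sum() - (test_labels == 1).sum()) <= 1


class TestSplitPersistence:
    def test_round_trip(self, tmp_path, random_raw):
        store = tmp_path / "s.h5"
        pp.to_unified_store(random_raw(n=20, m=5, seed=0), store)
        split = pp.make_split(20, "cv-test", seed=4, test_frac=0.2, k_folds=4)
        key = persist_split(store, split)
        persist_split(store, split)  # identical re-persist is a no-op
        loaded = load_split(store, split)
        np.testing.assert_array_equal(loaded.test, split.test)
        for fa, fb in zip(loaded.folds, split.folds):
            np.testing.assert_array_equal(fa["val"], fb["val"])
        assert "seed4" in key

    def test_two_seeds_coexist(self, tmp_path, random_raw):
        store = tmp_path / "s.h5"
        pp.to_unified_store(random_raw(n=20, m=5, seed=0), store)
        for seed in (1, 2):
            persist_split(store, pp.make_split(20, "cv-test", seed=seed, test_frac=0.2, k_folds=4))
        with h5py.File(store) as h5:
            assert "index/datasplit/cv-test/k_folds4-test_frac0.2/seed1" in h5
            assert "index/datasplit/cv-test/k_folds4-test_frac0.2/seed2" in h5

    def test_tampered_store_detected(self, tmp_path, random_raw):
        store = tmp_path / "s.h5"
        pp.to_unified_store(random_raw(n=20, m=5, seed=0), store)
        split = pp.make_split(20, "train-val-test", seed=4, test_frac=0.2, val_frac=0.25)
        key = persist_split(store, split)
        with h5py.File(store, "a") as h5:
            idx = h5[key]["test"][()]
            del h5[key]["test"]
            h5[key].create_dataset("test", data=idx[::-1].copy() * 0)  # corrupt
        with pytest.raises(ValueError, match="corrupt"):
            load_split(store, split)

    def test_regeneration_from_description_alone(self):
        split = pp.make_split(33, "nested-cv", seed=8, outer_folds=3, inner_folds=2)
        regen = regenerate_split(split)
        for oa, ob in zip(split.outer, regen.outer):
            np.testing.assert_array_equal(oa["test"], ob["test"])
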