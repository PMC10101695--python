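"""Genotype encoding, MAF filtering, sample matching and reproducible splits.

Everything here is deterministic by construction: a data split is fully
defined by (split type, parameters, seed, n) and is regenerated bit-
identically on any machine, so only those four ingredients (plus the
resulting indices, as a cross-check) need to be persisted.

The shuffle underlying every split is a single permutation drawn from
``numpy.random.default_rng(seed)`` (the PCG64 generator) followed by
contiguous slicing; this seed-to-stream mapping is part of the on-disk
contract for persisted splits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .genotype_io import PhenotypeTable, RawGenotype

__all__ = [
    "EncodedGenotype",
    "MatchedDataset",
    "SplitIndices",
    "compute_maf",
    "maf_filter",
    "encode_additive",
    "encode_onehot",
    "match_samples",
    "make_split",
    "persist_split",
    "load_split",
    "persist_maf_filter",
]


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def compute_maf(raw: RawGenotype) -> np.ndarray:
    """Per-marker minor-allele frequency.

    MAF = min(f, 1 - f) where f is one allele's count over the 2n allele
    slots at that marker; a constant marker has MAF 0. Values lie in
    [0, 0.5].
    """
    n, m = raw.calls.shape
    maf = np.zeros(m)
    for j in range(m):
        alleles = raw.marker_alleles(j)
        if len(alleles) < 2:
            continue
        a = alleles[0]
        col = raw.calls[:, j]
        count_a = sum(call.count(a) for call in col)
        f = count_a / (2 * n)
        maf[j] = min(f, 1.0 - f)
    return maf


def maf_filter(
    data: RawGenotype | "EncodedGenotype",
    threshold: float,
    *,
    maf: np.ndarray | None = None,
) -> tuple[RawGenotype | "EncodedGenotype", np.ndarray]:
    """Drop markers with MAF <= threshold (strict keep rule: MAF > threshold).

    Returns the filtered data plus the boolean keep-mask over the original
    marker order. The mask can be persisted into the unified store with
    :func:`persist_maf_filter`.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must lie in [0, 0.5], got {threshold}")
    if maf is None:
        if isinstance(data, EncodedGenotype):
            maf = data.maf
            if maf is None:
                raise ValueError("EncodedGenotype carries no MAF; pass maf= explicitly")
        else:
            maf = compute_maf(data)
    mask = np.asarray(maf) > threshold
    if isinstance(data, EncodedGenotype):
        return data.subset_markers(mask), mask
    keep = np.flatnonzero(mask)
    filtered = RawGenotype(
        data.sample_ids,
        [data.marker_ids[j] for j in keep],
        data.calls[:, keep],
        chrom_pos=[data.chrom_pos[j] for j in keep] if data.chrom_pos is not None else None,
    )
    return filtered, mask


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------

@dataclass
class EncodedGenotype:
    """Numeric genotype matrix plus the metadata needed to decode it.

    ``encoding`` is one of 'additive_012' (columns count minor-allele
    copies) or 'onehot' (each marker expands into one column per observed
    genotype class). ``feature_to_marker`` maps every matrix column back to
    the index of its source marker.
    """

    matrix: np.ndarray
    encoding: str
    sample_ids: list[str]
    marker_ids: list[str]
    feature_to_marker: np.ndarray  # (n_features,) marker index per column
    minor_allele: list[str]  # per marker
    major_allele: list[str]  # per marker
    maf: np.ndarray | None = None
    onehot_classes: list[list[str]] | None = None  # per marker, for 'onehot'

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, mask: np.ndarray) -> "EncodedGenotype":
        mask = np.asarray(mask, dtype=bool)
        keep_markers = np.flatnonzero(mask)
        col_keep = np.isin(self.feature_to_marker, keep_markers)
        remap = -np.ones(len(mask), dtype=int)
        remap[keep_markers] = np.arange(len(keep_markers))
        return EncodedGenotype(
            matrix=self.matrix[:, col_keep],
            encoding=self.encoding,
            sample_ids=self.sample_ids,
            marker_ids=[self.marker_ids[j] for j in keep_markers],
            feature_to_marker=remap[self.feature_to_marker[col_keep]],
            minor_allele=[self.minor_allele[j] for j in keep_markers],
            major_allele=[self.major_allele[j] for j in keep_markers],
            maf=self.maf[keep_markers] if self.maf is not None else None,
            onehot_classes=[self.onehot_classes[j] for j in keep_markers]
            if self.onehot_classes is not None
            else None,
        )

    def subset_samples(self, rows: np.ndarray) -> "EncodedGenotype":
        rows = np.asarray(rows)
        return EncodedGenotype(
            matrix=self.matrix[rows],
            encoding=self.encoding,
            sample_ids=[self.sample_ids[i] for i in rows],
            marker_ids=self.marker_ids,
            feature_to_marker=self.feature_to_marker,
            minor_allele=self.minor_allele,
            major_allele=self.major_allele,
            maf=self.maf,
            onehot_classes=self.onehot_classes,
        )


def _marker_polarity(raw: RawGenotype, j: int) -> tuple[str, str]:
    """(minor, major) allele at marker j; 50/50 ties give the lexicographically
    smaller allele minor status; a constant marker is its own major allele."""
    alleles = raw.marker_alleles(j)
    if len(alleles) == 1:
        return alleles[0], alleles[0]
    a, b = alleles
    col = raw.calls[:, j]
    count_a = sum(call.count(a) for call in col)
    count_b = 2 * len(col) - count_a
    if count_a < count_b:
        return a, b
    if count_b < count_a:
        return b, a
    return a, b  # tie: lexicographically smaller is minor


def encode_additive(
    raw: RawGenotype,
    *,
    minor_alleles: list[str] | None = None,
    maf: np.ndarray | None = None,
) -> EncodedGenotype:
    """Additive 0/1/2 dosage encoding counting copies of the minor allele.

    The minor allele per marker is the less frequent one (lexicographic
    tie-break at 50/50); pass ``minor_alleles`` to force a stored polarity,
    e.g. when re-encoding new samples for a previously trained model.
    """
    n, m = raw.calls.shape
    if maf is None:
        maf = compute_maf(raw)
    minors: list[str] = []
    majors: list[str] = []
    X = np.zeros((n, m))
    for j in range(m):
        if minor_alleles is not None:
            minor = minor_alleles[j]
            alleles = raw.marker_alleles(j)
            major_cands = [a for a in alleles if a != minor]
            major = major_cands[0] if major_cands else minor
        else:
            minor, major = _marker_polarity(raw, j)
        minors.append(minor)
        majors.append(major)
        if minor != major:  # constant markers carry zero dosage
            X[:, j] = [call.count(minor) for call in raw.calls[:, j]]
    return EncodedGenotype(
        matrix=X,
        encoding="additive_012",
        sample_ids=list(raw.sample_ids),
        marker_ids=list(raw.marker_ids),
        feature_to_marker=np.arange(m),
        minor_allele=minors,
        major_allele=majors,
        maf=maf,
    )


def encode_onehot(raw: RawGenotype) -> EncodedGenotype:
    """One-hot encoding over the genotype classes observed at each marker.

    Class order within a marker block is (hom-major, het, hom-minor),
    restricted to the classes actually observed, so a marker without
    heterozygotes yields a 2-column block. Each marker block has exactly
    one 1 per sample.
    """
    n, m = raw.calls.shape
    maf = compute_maf(raw)
    blocks: list[np.ndarray] = []
    f2m: list[int] = []
    minors: list[str] = []
    majors: list[str] = []
    classes_per_marker: list[list[str]] = []
    for j in range(m):
        minor, major = _marker_polarity(raw, j)
        minors.append(minor)
        majors.append(major)
        hom_major = major + major
        het = minor + major if minor <= major else major + minor
        hom_minor = minor + minor
        ordered = [hom_major, het, hom_minor]
        observed_set = set(raw.calls[:, j])
        classes = [c for c in dict.fromkeys(ordered) if c in observed_set]
        classes_per_marker.append(classes)
        block = np.zeros((n, len(classes)))
        lookup = {c: k for k, c in enumerate(classes)}
        for i, call in enumerate(raw.calls[:, j]):
            block[i, lookup[call]] = 1.0
        blocks.append(block)
        f2m.extend([j] * len(classes))
    return EncodedGenotype(
        matrix=np.hstack(blocks) if blocks else np.zeros((n, 0)),
        encoding="onehot",
        sample_ids=list(raw.sample_ids),
        marker_ids=list(raw.marker_ids),
        feature_to_marker=np.array(f2m, dtype=int),
        minor_allele=minors,
        major_allele=majors,
        maf=maf,
        onehot_classes=classes_per_marker,
    )


# ---------------------------------------------------------------------------
# Sample matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedDataset:
    """Genotypes restricted to samples with a non-missing phenotype, aligned row-wise."""

    genotype: EncodedGenotype
    y: np.ndarray
    trait: str
    trait_type: str  # 'continuous' | 'discrete'
    n_dropped: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def X(self) -> np.ndarray:
        return self.genotype.matrix


def match_samples(geno: EncodedGenotype, pheno: PhenotypeTable, trait: str) -> MatchedDataset:
    """Intersect genotype and phenotype samples on id, preserving genotype row order."""
    values = pheno.trait_values(trait)
    trait_type = pheno.trait_types.get(trait, "continuous")
    pheno_ids = {str(s) for s, v in values.items() if pd.notna(v)}
    keep_rows = [i for i, s in enumerate(geno.sample_ids) if s in pheno_ids]
    if not keep_rows:
        raise ValueError(
            f"no overlap between genotype samples and phenotype samples with "
            f"non-missing {trait!r} values"
        )
    n_dropped = geno.n_samples - len(keep_rows)
    sub = geno.subset_samples(np.array(keep_rows))
    yvals = values.loc[[geno.sample_ids[i] for i in keep_rows]].to_numpy()
    if trait_type == "continuous":
        yvals = yvals.astype(float)
    return MatchedDataset(genotype=sub, y=yvals, trait=trait, trait_type=trait_type, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Data splits
# ---------------------------------------------------------------------------

SPLIT_TYPES = ("train-val-test", "cv-test", "nested-cv")


@dataclass
class SplitIndices:
    """Seed-reproducible index sets for one of the three split types.

    Index sets are 0-based row indices into the matched dataset, stored
    sorted. For 'train-val-test': train/val/test. For 'cv-test': a test set
    plus k (train, val) folds partitioning the remainder. For 'nested-cv':
    outer folds each holding a test set, its training complement and inner
    (train, val) folds partitioning that complement.
    """

    split_type: str
    params: dict
    seed: int
    n: int
    train: np.ndarray | None = None
    val: np.ndarray | None = None
    test: np.ndarray | None = None
    folds: list[dict] = field(default_factory=list)  # cv-test: {train, val}
    outer: list[dict] = field(default_factory=list)  # nested-cv

    def key(self) -> str:
        """Canonical storage key under /index/datasplit."""
        parts = [f"{k}{self.params[k]:g}" if isinstance(self.params[k], float) else f"{k}{self.params[k]}"
                 for k in sorted(self.params)]
        return f"{self.split_type}/{'-'.join(parts)}/seed{self.seed}"

    def outer_contexts(self) -> list[dict]:
        """Per-outer-fold view: list of {train_idx, test_idx, folds} dicts.

        Non-nested splits yield a single context whose folds are the
        validation folds (one fold for train-val-test).
        """
        if self.split_type == "train-val-test":
            trainval = np.sort(np.concatenate([self.train, self.val]))
            return [{
                "train_idx": trainval,
                "test_idx": self.test,
                "folds": [{"train": self.train, "val": self.val}],
            }]
        if self.split_type == "cv-test":
            trainval = np.sort(np.concatenate([f["val"] for f in self.folds]))
            return [{"train_idx": trainval, "test_idx": self.test, "folds": self.folds}]
        return [
            {"train_idx": o["train"], "test_idx": o["test"], "folds": o["inner"]}
            for o in self.outer
        ]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _stratified_permutation(n: int, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permutation whose contiguous slices are approximately class-balanced.

    Shuffles indices within each class, then interleaves classes round-robin
    (class order deterministic by sorted label)."""
    labels = np.asarray(labels)
    order: list[list[int]] = []
    for lab in sorted(np.unique(labels), key=str):
        idx = np.flatnonzero(labels == lab)
        order.append(list(rng.permutation(idx)))
    out: list[int] = []
    while any(order):
        for lst in order:
            if lst:
                out.append(int(lst.pop()))
    return np.array(out, dtype=int)


def make_split(
    n: int,
    split_type: str,
    *,
    seed: int,
    test_frac: float | None = None,
    val_frac: float | None = None,
    k_folds: int | None = None,
    outer_folds: int | None = None,
    inner_folds: int | None = None,
    labels: np.ndarray | None = None,
) -> SplitIndices:
    """Create deterministic, machine-portable split indices.

    Sizes use round-half-away-from-zero on the test size first, then the
    validation size from the remainder. ``labels`` enables class-stratified
    assignment for discrete traits. Any empty partition is an error.
    """
    if split_type not in SPLIT_TYPES:
        raise ValueError(f"unknown split type {split_type!r}; expected one of {SPLIT_TYPES}")
    rng = np.random.default_rng(seed)
    if labels is not None:
        perm = _stratified_permutation(n, labels, rng)
    else:
        perm = rng.permutation(n)

    def _check(*sets):
        for s in sets:
            if len(s) == 0:
                raise ValueError(
                    f"empty partition for n={n}, split={split_type}; "
                    "adjust fractions or fold counts"
                )

    if split_type == "train-val-test":
        if test_frac is None or val_frac is None:
            raise ValueError("train-val-test requires test_frac and val_frac")
        if not (0 < test_frac < 1 and 0 < val_frac < 1):
            raise ValueError("fractions must lie in (0, 1)")
        n_test = _round_half_away(n * test_frac)
        rest = perm[n_test:]
        n_val = _round_half_away(len(rest) * val_frac)
        test = np.sort(perm[:n_test])
        val = np.sort(rest[:n_val])
        train = np.sort(rest[n_val:])
        _check(train, val, test)
        return SplitIndices(
            split_type, {"test_frac": test_frac, "val_frac": val_frac}, seed, n,
            train=train, val=val, test=test,
        )

    if split_type == "cv-test":
        if test_frac is None or k_folds is None:
            raise ValueError("cv-test requires test_frac and k_folds")
        if not 0 < test_frac < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        n_test = _round_half_away(n * test_frac)
        test = np.sort(perm[:n_test])
        rest = perm[n_test:]
        chunks = np.array_split(rest, k_folds)
        folds = []
        for i in range(k_folds):
            val = np.sort(chunks[i])
            train = np.sort(np.concatenate([chunks[j] for j in range(k_folds) if j != i]))
            _check(train, val)
            folds.append({"train": train, "val": val})
        _check(test)
        return SplitIndices(
            split_type, {"test_frac": test_frac, "k_folds": k_folds}, seed, n,
            test=test, folds=folds,
        )

    # nested-cv
    if outer_folds is None or inner_folds is None:
        raise ValueError("nested-cv requires outer_folds and inner_folds")
    if outer_folds < 2 or inner_folds < 2:
        raise ValueError("fold counts must be >= 2")
    outer_chunks = np.array_split(perm, outer_folds)
    outer = []
    for o in range(outer_folds):
        test = np.sort(outer_chunks[o])
        train_part = np.concatenate([outer_chunks[j] for j in range(outer_folds) if j != o])
        inner_chunks = np.array_split(train_part, inner_folds)
        inner = []
        for i in range(inner_folds):
            val = np.sort(inner_chunks[i])
            tr = np.sort(np.concatenate([inner_chunks[j] for j in range(inner_folds) if j != i]))
            _check(tr, val)
            inner.append({"train": tr, "val": val})
        _check(test, train_part)
        outer.append({"test": test, "train": np.sort(train_part), "inner": inner})
    return SplitIndices(
        split_type, {"outer_folds": outer_folds, "inner_folds": inner_folds}, seed, n,
        outer=outer,
    )


def regenerate_split(split: SplitIndices, labels: np.ndarray | None = None) -> SplitIndices:
    """Rebuild a split from its (type, params, seed, n) description alone."""
    return make_split(split.n, split.split_type, seed=split.seed, labels=labels, **split.params)


def _split_equal(a: SplitIndices, b: SplitIndices) -> bool:
    def eq(x, y):
        return (x is None and y is None) or (x is not None and y is not None and np.array_equal(x, y))

    if (a.split_type, a.seed, a.n) != (b.split_type, b.seed, b.n):
        return False
    if not (eq(a.train, b.train) and eq(a.val, b.val) and eq(a.test, b.test)):
        return False
    if len(a.folds) != len(b.folds) or len(a.outer) != len(b.outer):
        return False
    for fa, fb in zip(a.folds, b.folds):
        if not (eq(fa["train"], fb["train"]) and eq(fa["val"], fb["val"])):
            return False
    for oa, ob in zip(a.outer, b.outer):
        if not (eq(oa["test"], ob["test"]) and eq(oa["train"], ob["train"])):
            return False
        for fa, fb in zip(oa["inner"], ob["inner"]):
            if not (eq(fa["train"], fb["train"]) and eq(fa["val"], fb["val"])):
                return False
    return True


# ---------------------------------------------------------------------------
# Persistence into the unified store
# ---------------------------------------------------------------------------

def persist_maf_filter(store_path: str | os.PathLike, threshold: float, mask: np.ndarray) -> str:
    """Write a MAF keep-mask under /index/maf_filter/<threshold>."""
    key = f"index/maf_filter/{threshold:g}"
    with h5py.File(store_path, "a") as h5:
        if key in h5:
            stored = h5[key][()].astype(bool)
            if np.array_equal(stored, np.asarray(mask, dtype=bool)):
                return key
            raise ValueError(f"store already holds a different mask at {key}")
        h5.create_dataset(key, data=np.asarray(mask, dtype=bool))
    return key


def persist_split(store_path: str | os.PathLike, split: SplitIndices) -> str:
    """Write split indices under /index/datasplit/<type>/<params>/<seed>.

    Re-persisting an identical split is a verified no-op; a key collision
    with different indices raises (corruption guard).
    """
    key = f"index/datasplit/{split.key()}"
    with h5py.File(store_path, "a") as h5:
        if key in h5:
            existing = _read_split_group(h5[key], split)
            if _split_equal(existing, split):
                return key
            raise ValueError(
                f"store already holds different indices at {key} (corruption guard)"
            )
        grp = h5.create_group(key)
        grp.attrs["split_type"] = split.split_type
        grp.attrs["seed"] = split.seed
        grp.attrs["n"] = split.n
        grp.attrs["index_base"] = 0
        for pk, pv in split.params.items():
            grp.attrs[f"param_{pk}"] = pv
        if split.split_type == "train-val-test":
            grp.create_dataset("train", data=split.train)
            grp.create_dataset("val", data=split.val)
            grp.create_dataset("test", data=split.test)
        elif split.split_type == "cv-test":
            grp.create_dataset("test", data=split.test)
            for i, f in enumerate(split.folds):
                fg = grp.create_group(f"fold_{i}")
                fg.create_dataset("train", data=f["train"])
                fg.create_dataset("val", data=f["val"])
        else:
            for o, od in enumerate(split.outer):
                og = grp.create_group(f"outer_{o}")
                og.create_dataset("test", data=od["test"])
                og.create_dataset("train", data=od["train"])
                for i, f in enumerate(od["inner"]):
                    fg = og.create_group(f"inner_{i}")
                    fg.create_dataset("train", data=f["train"])
                    fg.create_dataset("val", data=f["val"])
    return key


def _read_split_group(grp: h5py.Group, template: SplitIndices) -> SplitIndices:
    st = grp.attrs["split_type"]
    out = SplitIndices(st, dict(template.params), int(grp.attrs["seed"]), int(grp.attrs["n"]))
    if st == "train-val-test":
        out.train = grp["train"][()]
        out.val = grp["val"][()]
        out.test = grp["test"][()]
    elif st == "cv-test":
        out.test = grp["test"][()]
        i = 0
        while f"fold_{i}" in grp:
            fg = grp[f"fold_{i}"]
            out.folds.append({"train": fg["train"][()], "val": fg["val"][()]})
            i += 1
    else:
        o = 0
        while f"outer_{o}" in grp:
            og = grp[f"outer_{o}"]
            od = {"test": og["test"][()], "train": og["train"][()], "inner": []}
            i = 0
            while f"inner_{i}" in og:
                fg = og[f"inner_{i}"]
                od["inner"].append({"train": fg["train"][()], "val": fg["val"][()]})
                i += 1
            out.outer.append(od)
            o += 1
    return out


def load_split(store_path: str | os.PathLike, split: SplitIndices) -> SplitIndices:
    """Load a persisted split and verify it against a fresh regeneration.

    A mismatch between stored and regenerated indices means the store was
    tampered with or produced by an incompatible version — an error either
    way.
    """
    key = f"index/datasplit/{split.key()}"
    with h5py.File(store_path, "r") as h5:
        if key not in h5:
            raise KeyError(f"no split stored at {key}")
        stored = _read_split_group(h5[key], split)
    regenerated = regenerate_split(split)
    if not _split_equal(stored, regenerated):
        raise ValueError(
            f"stored indices at {key} do not match regeneration from "
            "(type, params, seed, n); store may be corrupted"
        )
    return stored
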