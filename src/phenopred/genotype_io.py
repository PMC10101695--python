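"""Reading, validating and persisting genotype and phenotype data.

Genotypes are diploid nucleotide calls at biallelic markers. All readers
produce a :class:`RawGenotype`, which downstream code treats as the single
source of truth; a unified HDF5 store makes every later step independent of
the original file format and guards against silent re-processing of changed
data.

No missing calls are accepted anywhere: the pipeline requires a fully
imputed genotype matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

__all__ = [
    "RawGenotype",
    "PhenotypeTable",
    "read_genotype_csv",
    "read_genotype_plink_text",
    "read_phenotype_csv",
    "write_genotype_csv",
    "write_genotype_plink_text",
    "to_unified_store",
    "load_unified_store",
]


def _canonical_call(cell: str, *, homozygous_shorthand: bool = True) -> str:
    """Canonicalize a genotype cell to a sorted two-letter call ('AG' not 'GA')."""
    cell = cell.strip()
    if homozygous_shorthand and len(cell) == 1:
        cell = cell + cell
    if len(cell) != 2 or cell[0] not in VALID_ALLELES or cell[1] not in VALID_ALLELES:
        raise ValueError(f"invalid genotype call {cell!r}")
    return cell if cell[0] <= cell[1] else cell[1] + cell[0]


@dataclass
class RawGenotype:
    """Nucleotide-level genotype matrix with sample and marker identifiers.

    ``calls`` is an (n_samples, n_markers) array of two-letter strings, each
    an unordered diploid call stored with alleles sorted lexicographically
    ('AG', never 'GA'). Markers must be biallelic or constant and calls may
    never be missing.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    chrom_pos: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype="<U2")
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id {dup!r}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dup = _first_duplicate(self.marker_ids)
            raise ValueError(f"duplicate marker id {dup!r}")
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if self.chrom_pos is not None and len(self.chrom_pos) != self.n_markers:
            raise ValueError("chrom_pos length does not match marker count")
        for j, marker in enumerate(self.marker_ids):
            col = self.calls[:, j]
            alleles = set("".join(col))
            if not alleles <= VALID_ALLELES:
                bad = sorted(alleles - VALID_ALLELES)
                raise ValueError(f"marker {marker!r} has invalid allele(s) {bad}")
            if len(alleles) > 2:
                raise ValueError(
                    f"marker {marker!r} has {len(alleles)} alleles "
                    f"({sorted(alleles)}); only biallelic markers are supported"
                )
            for call in col:
                if call[0] > call[1]:
                    raise ValueError(f"non-canonical call {call!r} at marker {marker!r}")

    def marker_alleles(self, j: int) -> list[str]:
        """Distinct alleles observed at marker ``j`` (sorted; 1 or 2 entries)."""
        return sorted(set("".join(self.calls[:, j])))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawGenotype):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class PhenotypeTable:
    """Per-sample trait values; traits are typed continuous or discrete.

    A trait is *discrete* when all of its non-missing values are integers or
    strings with at most ``max_discrete_classes`` distinct levels; otherwise
    it is continuous. Missing values are permitted here and dropped when the
    table is matched against a genotype matrix.
    """

    data: pd.DataFrame  # index = sample id (str), one column per trait
    trait_types: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise KeyError(
                f"trait {trait!r} not found; available traits: {list(self.data.columns)}"
            )
        return self.data[trait]


def _classify_trait(values: pd.Series, max_discrete_classes: int) -> str:
    nonmissing = values.dropna()
    distinct = nonmissing.unique()
    if len(distinct) == 0:
        return "continuous"
    integral = True
    for v in distinct:
        if isinstance(v, str):
            continue
        try:
            if float(v) != int(float(v)):
                integral = False
                break
        except (TypeError, ValueError):
            integral = False
            break
    if integral and len(distinct) <= max_discrete_classes:
        return "discrete"
    return "continuous"


def read_genotype_csv(
    path: str | os.PathLike,
    *,
    homozygous_shorthand: bool = True,
) -> RawGenotype:
    """Read a genotype CSV: header = marker ids, first column = sample ids.

    Cells are nucleotide pairs ('AA', 'AG'); a single symbol is expanded to
    a homozygous call when ``homozygous_shorthand`` is on (common for inbred
    plant panels). Heterozygous calls are canonicalized (GA -> AG). Missing
    cells are an error — the matrix must be fully imputed.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    marker_ids = [str(m) for m in df.columns]
    calls = np.empty((len(sample_ids), len(marker_ids)), dtype="<U2")
    for i, s in enumerate(sample_ids):
        for j, m in enumerate(marker_ids):
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "NA", "nan"):
                raise ValueError(f"missing genotype at ({s}, {m})")
            try:
                calls[i, j] = _canonical_call(str(cell), homozygous_shorthand=homozygous_shorthand)
            except ValueError as exc:
                raise ValueError(f"at ({s}, {m}): {exc}") from exc
    return RawGenotype(sample_ids, marker_ids, calls)


def read_genotype_plink_text(ped_path: str | os.PathLike, map_path: str | os.PathLike) -> RawGenotype:
    """Read PLINK 1.x text files (PED + MAP).

    PED rows: family id, individual id, four ignored pedigree/sex/phenotype
    columns, then two allele columns per marker. MAP rows: chromosome,
    marker id, genetic distance (ignored), base-pair position. The PLINK
    missing-allele code '0' is rejected — no missing data is permitted.
    """
    marker_ids: list[str] = []
    chrom_pos: list[tuple[str, int]] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"malformed MAP line: {line.strip()!r}")
            chrom, marker, _dist, pos = parts[:4]
            marker_ids.append(marker)
            chrom_pos.append((chrom, int(pos)))
    n_markers = len(marker_ids)

    sample_ids: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"malformed PED line starting {parts[:2]}")
            ind_id = parts[1]
            alleles = parts[6:]
            if len(alleles) != 2 * n_markers:
                raise ValueError(
                    f"PED/MAP marker count mismatch for sample {ind_id!r}: "
                    f"MAP lists {n_markers} markers but PED row carries "
                    f"{len(alleles)} allele columns ({len(alleles) / 2:g} markers)"
                )
            calls_row = []
            for j in range(n_markers):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    raise ValueError(
                        f"missing genotype not allowed (PLINK code '0') for "
                        f"sample {ind_id!r} at marker {marker_ids[j]!r}"
                    )
                if a not in VALID_ALLELES or b not in VALID_ALLELES:
                    raise ValueError(
                        f"invalid allele {a!r}/{b!r} for sample {ind_id!r} "
                        f"at marker {marker_ids[j]!r}"
                    )
                calls_row.append(a + b if a <= b else b + a)
            sample_ids.append(ind_id)
            rows.append(calls_row)
    calls = np.array(rows, dtype="<U2").reshape(len(sample_ids), n_markers)
    return RawGenotype(sample_ids, marker_ids, calls, chrom_pos=chrom_pos)


def read_phenotype_csv(
    path: str | os.PathLike,
    trait_names: list[str] | None = None,
    *,
    sample_id_column: str | None = None,
    max_discrete_classes: int = 10,
) -> PhenotypeTable:
    """Read a phenotype CSV (one sample-id column plus >= 1 trait columns).

    Lines starting with '#' are treated as metadata comments. Each requested
    trait is tagged continuous or discrete by the class-count rule.
    """
    df = pd.read_csv(path, comment="#")
    id_col = sample_id_column if sample_id_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise KeyError(f"sample id column {id_col!r} not found")
    df = df.set_index(id_col)
    df.index = df.index.map(str)
    if trait_names is not None:
        missing = [t for t in trait_names if t not in df.columns]
        if missing:
            raise KeyError(
                f"trait(s) {missing} not found; available columns: {list(df.columns)}"
            )
        df = df[list(trait_names)]
    trait_types = {t: _classify_trait(df[t], max_discrete_classes) for t in df.columns}
    return PhenotypeTable(data=df, trait_types=trait_types)


def write_genotype_csv(raw: RawGenotype, path: str | os.PathLike) -> None:
    """Write a RawGenotype in the CSV dialect accepted by :func:`read_genotype_csv`."""
    df = pd.DataFrame(raw.calls, index=raw.sample_ids, columns=raw.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def write_genotype_plink_text(raw: RawGenotype, ped_path: str | os.PathLike, map_path: str | os.PathLike) -> None:
    """Write PED/MAP text files round-trippable by :func:`read_genotype_plink_text`."""
    with open(map_path, "w") as fh:
        for j, marker in enumerate(raw.marker_ids):
            chrom, pos = raw.chrom_pos[j] if raw.chrom_pos is not None else ("0", j + 1)
            fh.write(f"{chrom}\t{marker}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(raw.sample_ids):
            alleles = " ".join(f"{c[0]} {c[1]}" for c in raw.calls[i])
            fh.write(f"FAM{i + 1} {sample} 0 0 0 -9 {alleles}\n")


# ---------------------------------------------------------------------------
# Unified HDF5 store
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def to_unified_store(raw: RawGenotype, path: str | os.PathLike) -> str:
    """Persist a RawGenotype (plus per-marker MAF) into the unified HDF5 store.

    Layout: /genotype/matrix (two-letter calls), /genotype/sample_ids,
    /genotype/marker_ids, optional /genotype/chrom and /genotype/pos, /maf,
    and an /index group that split/filter persistence appends to later.

    Re-running against an existing store is a verified no-op when the
    genotype content is identical and an error otherwise — index files keep
    referring to exactly the data they were computed from.
    """
    from .preprocess import compute_maf  # local import avoids a module cycle

    path = os.fspath(path)
    maf = compute_maf(raw)
    if os.path.exists(path):
        existing = load_unified_store(path)
        if existing == raw:
            return path
        raise ValueError(
            f"store {path!r} already holds different genotype content; "
            "refusing to overwrite (reproducibility guard)"
        )
    with h5py.File(path, "w") as h5:
        g = h5.create_group("genotype")
        g.create_dataset("matrix", data=raw.calls.astype("S2"), compression="gzip")
        g.create_dataset("sample_ids", data=np.array(raw.sample_ids, dtype=_STR))
        g.create_dataset("marker_ids", data=np.array(raw.marker_ids, dtype=_STR))
        if raw.chrom_pos is not None:
            g.create_dataset("chrom", data=np.array([c for c, _ in raw.chrom_pos], dtype=_STR))
            g.create_dataset("pos", data=np.array([p for _, p in raw.chrom_pos], dtype=np.int64))
        h5.create_dataset("maf", data=maf, compression="gzip")
        idx = h5.create_group("index")
        idx.attrs["index_base"] = 0
    return path


def load_unified_store(path: str | os.PathLike) -> RawGenotype:
    """Load the RawGenotype back out of a unified HDF5 store (exact round trip)."""
    with h5py.File(path, "r") as h5:
        g = h5["genotype"]
        calls = g["matrix"][()].astype("<U2")
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in g["sample_ids"][()]]
        marker_ids = [m.decode() if isinstance(m, bytes) else str(m) for m in g["marker_ids"][()]]
        chrom_pos = None
        if "chrom" in g:
            chroms = [c.decode() if isinstance(c, bytes) else str(c) for c in g["chrom"][()]]
            poss = [int(p) for p in g["pos"][()]]
            chrom_pos = list(zip(chroms, poss))
    return RawGenotype(sample_ids, marker_ids, calls, chrom_pos=chrom_pos)


def load_store_maf(path: str | os.PathLike) -> np.ndarray:
    """Per-marker minor-allele frequencies as stored in the unified store."""
    with h5py.File(path, "r") as h5:
        return h5["maf"][()]
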