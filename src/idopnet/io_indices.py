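"""Expression data I/O and the index series that replace time.

A grafted plant is treated as a two-compartment ecosystem (scion above the
graft union, rootstock below).  The *compartment index* of a sample is the
total expression of all genes in one compartment; the *ecosystem index* sums
the two compartment indices of the same plant; the *niche index* of a gene
sums its scion and rootstock expression in one sample.  Sorting samples by an
index yields the quasi-dynamic axis along which all downstream trajectories
and ODEs are defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from idopnet.errors import (
    DataValidationError,
    DuplicateGeneError,
    MetadataMismatchError,
    NegativeValueError,
)


class Combination(str, enum.Enum):
    """Scion/rootstock species combination (scion species first)."""

    AA = "AA"
    AB = "AB"
    BA = "BA"
    BB = "BB"


class Segment(str, enum.Enum):
    SCION = "scion"
    ROOTSTOCK = "rootstock"


class IndexKind(str, enum.Enum):
    COMPARTMENT = "compartment"
    ECOSYSTEM = "ecosystem"
    NICHE = "niche"


@dataclass
class SampleMeta:
    """Per-sample record: which graft, which segment, when, which replicate."""

    sample_id: str
    combination: Combination
    segment: Segment
    time: float
    replicate: int


@dataclass
class ExpressionDataset:
    """Nonnegative expression matrix (genes in rows, samples in columns).

    Values are in expression units (e.g. FPKM).  Validated on construction:
    no negative entries, unique gene ids, one metadata record per column.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_meta: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene ids for {m} matrix rows"
            )
        if len(set(self.gene_ids)) != m:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise DuplicateGeneError(f"duplicate gene id: {dup!r}")
        if len(self.sample_meta) != n:
            raise MetadataMismatchError(
                f"{len(self.sample_meta)} metadata records for {n} samples"
            )
        if np.any(self.values < 0):
            j, i = np.argwhere(self.values < 0)[0]
            raise NegativeValueError(
                f"negative expression at gene {self.gene_ids[j]!r}, "
                f"sample {self.sample_meta[i].sample_id!r}: {self.values[j, i]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression matrix has non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.sample_meta]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionDataset(self.values[idx], list(gene_ids), self.sample_meta)


@dataclass
class IndexSeries:
    """An index value per sample plus the ascending sample ordering it induces.

    ``order`` is the permutation of sample positions sorting ``values``
    nondecreasing; ties keep original sample position (stable sort) so the
    quasi-dynamic axis is deterministic.
    """

    kind: IndexKind
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataValidationError("index values must be a vector")
        if np.any(self.values < 0):
            raise DataValidationError("index values must be nonnegative")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.size)]

    @property
    def order(self) -> np.ndarray:
        """Ascending permutation of sample positions (stable on ties)."""
        return np.argsort(self.values, kind="stable")

    @property
    def sorted_values(self) -> np.ndarray:
        return self.values[self.order]

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# I/O

_META_COLUMNS = ("sample_id", "combination", "segment", "time", "replicate")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Read a genes x samples matrix and its sample metadata table.

    The matrix file has a header row of sample ids and gene ids in the first
    column; TSV by default, CSV when the suffix is ``.csv``.  The metadata
    table needs columns combination, segment, time, replicate and one row per
    matrix column, keyed by sample id.
    """
    mat = _read_table(path)
    try:
        values = mat.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValidationError(f"non-numeric matrix cell in {path}: {exc}") from exc
    meta = _read_table(meta_path).reset_index()
    meta.columns = [str(c).strip() for c in meta.columns]
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataMismatchError(f"metadata lacks columns {missing}")
    records = {
        str(r.sample_id): SampleMeta(
            sample_id=str(r.sample_id),
            combination=Combination(str(r.combination)),
            segment=Segment(str(r.segment)),
            time=float(r.time),
            replicate=int(r.replicate),
        )
        for r in meta.itertuples(index=False)
    }
    sample_ids = [str(c) for c in mat.columns]
    unmatched = [s for s in sample_ids if s not in records]
    if unmatched:
        raise MetadataMismatchError(f"samples missing from metadata: {unmatched}")
    sample_meta = [records[s] for s in sample_ids]
    return ExpressionDataset(values, [str(g) for g in mat.index], sample_meta)


def write_expression(ds: ExpressionDataset, path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    """Write a dataset back to delimited text (lossless round-trip)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids).to_csv(
        path, sep=sep, index_label="gene_id"
    )
    if meta_path is not None:
        meta_path = Path(meta_path)
        msep = "," if meta_path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "combination": s.combination.value,
                    "segment": s.segment.value,
                    "time": s.time,
                    "replicate": s.replicate,
                }
                for s in ds.sample_meta
            ]
        ).to_csv(meta_path, sep=msep, index=False)


def write_index(series: IndexSeries, path: str | Path) -> None:
    pd.DataFrame({"sample_id": series.sample_ids, "value": series.values}).to_csv(
        Path(path), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Indices


def compartment_index(ds: ExpressionDataset) -> IndexSeries:
    """Total expression per sample: E_i = sum_j y_ji.

    The compartment index summarizes the carrying capacity of one graft
    segment and replaces time as the ordering axis.
    """
    if ds.n_genes < 1:
        raise DataValidationError("empty expression matrix")
    return IndexSeries(
        IndexKind.COMPARTMENT, ds.values.sum(axis=0), list(ds.sample_ids)
    )


def ecosystem_index(
    scion: IndexSeries,
    rootstock: IndexSeries,
    pairing: Mapping[str, str] | None = None,
) -> IndexSeries:
    """Per grafted plant, scion compartment index + rootstock compartment index.

    ``pairing`` maps each scion sample id to its rootstock sample id from the
    same plant; identity-by-position when omitted.
    """
    if pairing is None:
        if len(scion) != len(rootstock):
            raise DataValidationError(
                "unpaired samples: scion and rootstock series differ in length"
            )
        values = scion.values + rootstock.values
        return IndexSeries(IndexKind.ECOSYSTEM, values, list(scion.sample_ids))
    root_pos = {s: i for i, s in enumerate(rootstock.sample_ids)}
    values = np.empty(len(scion))
    for i, sid in enumerate(scion.sample_ids):
        if sid not in pairing or pairing[sid] not in root_pos:
            raise DataValidationError(f"unpaired scion sample {sid!r}")
        values[i] = scion.values[i] + rootstock.values[root_pos[pairing[sid]]]
    if len(set(pairing.values())) != len(pairing):
        raise DataValidationError("pairing is not a bijection")
    return IndexSeries(IndexKind.ECOSYSTEM, values, list(scion.sample_ids))


def niche_index(
    gene: str, scion_row: np.ndarray, rootstock_row: np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> IndexSeries:
    """Per-gene niche index N_i: scion + rootstock expression of one gene.

    Drives the coupled two-compartment crosstalk ODEs for that gene.
    """
    scion_row = np.asarray(scion_row, dtype=float)
    rootstock_row = np.asarray(rootstock_row, dtype=float)
    if scion_row.shape != rootstock_row.shape or scion_row.ndim != 1:
        raise DataValidationError(
            f"length mismatch for gene {gene!r}: "
            f"{scion_row.shape} vs {rootstock_row.shape}"
        )
    ids = list(sample_ids) if sample_ids is not None else []
    return IndexSeries(IndexKind.NICHE, scion_row + rootstock_row, ids)


def pool_replicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Average replicate columns sharing (combination, segment, time).

    Optional pre-processing; the pipeline default uses the matrix as given.
    """
    keys: dict[tuple, list[int]] = {}
    for i, s in enumerate(ds.sample_meta):
        keys.setdefault((s.combination, s.segment, s.time), []).append(i)
    cols, meta = [], []
    for (comb, seg, t), idx in keys.items():
        cols.append(ds.values[:, idx].mean(axis=1))
        first = ds.sample_meta[idx[0]]
        meta.append(SampleMeta(first.sample_id, comb, seg, t, 0))
    return ExpressionDataset(np.column_stack(cols), list(ds.gene_ids), meta)
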