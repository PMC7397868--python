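"""Data model and TSV I/O for protein-level MS intensity experiments.

An experiment is a protein x sample matrix of log2 MS intensities plus
per-sample metadata (fraction, genotype, replicate, batch).  Missing cells
(label-free non-detections) are represented as NaN and are first-class:
they are distinct from zero and survive round trips as "NA".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FRACTIONS = ("RIC", "WCE", "noCL")

#: serialized population flags (full circle / empty circle / cross convention)
POPULATION_BOTH = "both"
POPULATION_RIC_ONLY = "ric_only"
POPULATION_WCE_ONLY = "wce_only"


class TableError(ValueError):
    """Raised for malformed intensity tables, metadata, or merges."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one MS sample (one column of an intensity matrix)."""

    sample_id: str
    fraction: str
    genotype: str
    replicate: int
    batch: str

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise TableError(
                f"sample {self.sample_id!r}: fraction must be one of {FRACTIONS}, "
                f"got {self.fraction!r}"
            )
        if int(self.replicate) < 1:
            raise TableError(f"sample {self.sample_id!r}: replicate must be >= 1")


class IntensityTable:
    """Protein x sample matrix of log2 intensities with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample id, NaN for
        missing (non-detected) cells.  All non-NaN values must be finite.
    samples
        One :class:`SampleMeta` per column, in column order.
    imputed
        Optional boolean mask of the same shape; True marks cells that were
        missing before background imputation.  Defaults to all-False.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleMeta],
        imputed: pd.DataFrame | None = None,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate protein ids: {dups}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise TableError("duplicate sample_ids in metadata")
        if list(values.columns) != ids:
            raise TableError(
                "intensity columns do not match sample metadata order: "
                f"{list(values.columns)} vs {ids}"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(values.to_numpy()).any():
                raise TableError("non-finite (inf) intensity values")
        if imputed is None:
            imputed = pd.DataFrame(False, index=values.index, columns=values.columns)
        else:
            imputed = imputed.astype(bool)
            if imputed.shape != values.shape:
                raise TableError("imputed mask shape does not match values")
            imputed = imputed.set_axis(values.index, axis=0).set_axis(
                values.columns, axis=1
            )
        self.values = values
        self.samples = list(samples)
        self.imputed = imputed

    # -- basic accessors ---------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def batches(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.batch not in out:
                out.append(s.batch)
        return out

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.values.copy(), list(self.samples), self.imputed.copy())

    def observed(self) -> pd.DataFrame:
        """Boolean mask of cells observed *before* any imputation."""
        return self.values.notna() & ~self.imputed

    def sample_ids_where(
        self,
        fraction: str | None = None,
        genotype: str | None = None,
        batch: str | None = None,
    ) -> list[str]:
        out = []
        for s in self.samples:
            if fraction is not None and s.fraction != fraction:
                continue
            if genotype is not None and s.genotype != genotype:
                continue
            if batch is not None and s.batch != batch:
                continue
            out.append(s.sample_id)
        return out

    def subset(self, sample_ids: Iterable[str]) -> "IntensityTable":
        ids = list(sample_ids)
        metas = [self.meta(i) for i in ids]
        return IntensityTable(self.values[ids].copy(), metas, self.imputed[ids].copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"IntensityTable({len(self.protein_ids)} proteins x "
            f"{len(self.samples)} samples, batches={self.batches})"
        )


@dataclass
class AnnotationTable:
    """Per-protein Pfam / GO annotation with classical-RBD flags.

    ``classical_ids`` / ``nonclassical_ids`` are the configured domain-ID
    vocabularies (editable files, not hard-coded); the per-protein boolean
    flags are derived from them.
    """

    pfam: dict[str, frozenset[str]]
    go: dict[str, frozenset[str]]
    classical_ids: frozenset[str] = field(default_factory=frozenset)
    nonclassical_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.pfam) != set(self.go):
            missing = set(self.pfam) ^ set(self.go)
            raise TableError(f"pfam/go protein universes differ: {sorted(missing)[:5]}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.pfam)

    def has_classical_rbd(self, protein_id: str) -> bool:
        return bool(self.pfam.get(protein_id, frozenset()) & self.classical_ids)

    def has_nonclassical_rbd(self, protein_id: str) -> bool:
        return bool(self.pfam.get(protein_id, frozenset()) & self.nonclassical_ids)

    def nonclassical_domains(self, protein_id: str) -> frozenset[str]:
        return self.pfam.get(protein_id, frozenset()) & self.nonclassical_ids

    def has_go_term(self, protein_id: str, term: str) -> bool:
        return term in self.go.get(protein_id, frozenset())


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV (sample_id, fraction, genotype, replicate, batch)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fraction", "genotype", "replicate", "batch"}
    if not required.issubset(df.columns):
        raise TableError(f"metadata missing columns: {sorted(required - set(df.columns))}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            fraction=row.fraction,
            genotype=row.genotype,
            replicate=int(row.replicate),
            batch=row.batch,
        )
        for row in df.itertuples()
    ]


def read_intensity_table(
    path: str | Path,
    meta_path: str | Path,
    scale: str = "log2",
) -> IntensityTable:
    """Read a wide intensity TSV plus its sample-metadata TSV.

    The first column of the TSV is ``protein_id``; remaining columns are
    sample ids and must match the metadata one-to-one.  With
    ``scale="linear"`` values are log2-transformed and non-positive values
    are censored to missing; empty cells and "NA" are missing on either
    scale.
    """
    if scale not in ("log2", "linear"):
        raise TableError(f"scale must be 'log2' or 'linear', got {scale!r}")
    samples = read_sample_meta(meta_path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "protein_id":
        raise TableError("first column of intensity TSV must be 'protein_id'")
    raw = raw.set_index("protein_id")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate protein ids in {path}: {dups}")

    meta_ids = [s.sample_id for s in samples]
    extra = [c for c in raw.columns if c not in meta_ids]
    if extra:
        raise TableError(f"sample columns without metadata rows: {extra}")
    absent = [i for i in meta_ids if i not in raw.columns]
    if absent:
        raise TableError(f"metadata rows without sample columns: {absent}")
    raw = raw[meta_ids]

    na_tokens = {"", "NA", "NaN", "nan"}
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col]
        keep = ~cells.isin(na_tokens)
        numeric = pd.to_numeric(cells[keep], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            raise TableError(
                f"non-numeric cell at protein {bad[0]!r}, sample {col!r}: "
                f"{cells.loc[bad[0]]!r}"
            )
        values.loc[keep, col] = numeric.astype(float)

    if scale == "linear":
        arr = values.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            arr = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    return IntensityTable(values, samples)


def merge_batches(tables: Sequence[IntensityTable]) -> IntensityTable:
    """Column-wise concatenation of per-batch tables over the protein union.

    Proteins absent from a batch get missing cells in that batch's columns.
    Batch identifiers and sample ids must be distinct across inputs.
    """
    if not tables:
        raise TableError("no tables to merge")
    seen_batches: set[str] = set()
    seen_samples: set[str] = set()
    for t in tables:
        b = set(t.batches)
        if b & seen_batches:
            raise TableError(f"clashing batch ids across tables: {sorted(b & seen_batches)}")
        seen_batches |= b
        s = set(t.sample_ids)
        if s & seen_samples:
            raise TableError(f"clashing sample_ids across tables: {sorted(s & seen_samples)}")
        seen_samples |= s

    proteins: list[str] = []
    for t in tables:
        for p in t.protein_ids:
            if p not in proteins:
                proteins.append(p)

    values = pd.concat([t.values.reindex(proteins) for t in tables], axis=1)
    imputed = pd.concat(
        [t.imputed.reindex(proteins, fill_value=False) for t in tables], axis=1
    )
    samples = [s for t in tables for s in t.samples]
    return IntensityTable(values, samples, imputed)


def write_results(rows: pd.DataFrame | Sequence, path: str | Path) -> None:
    """Write a homogeneous result table as TSV (floats at >=6 significant digits)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r for r in rows])
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_id_list(path: str | Path) -> frozenset[str]:
    """Read a one-id-per-line domain list ('#' starts a comment)."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return frozenset(ids)


def read_annotation_table(
    path: str | Path,
    classical_ids: Iterable[str] = (),
    nonclassical_ids: Iterable[str] = (),
) -> AnnotationTable:
    """Read an annotation TSV (protein_id, pfam_ids, go_terms; ';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "pfam_ids", "go_terms"}
    if not required.issubset(df.columns):
        raise TableError(f"annotation missing columns: {sorted(required - set(df.columns))}")
    if df["protein_id"].duplicated().any():
        raise TableError("duplicate protein ids in annotation table")

    def split(cell: str) -> frozenset[str]:
        return frozenset(x for x in cell.split(";") if x)

    pfam = {r.protein_id: split(r.pfam_ids) for r in df.itertuples()}
    go = {r.protein_id: split(r.go_terms) for r in df.itertuples()}
    return AnnotationTable(
        pfam=pfam,
        go=go,
        classical_ids=frozenset(classical_ids),
        nonclassical_ids=frozenset(nonclassical_ids),
    )


def write_annotation_table(ann: AnnotationTable, path: str | Path) -> None:
    rows = [
        {
            "protein_id": p,
            "pfam_ids": ";".join(sorted(ann.pfam[p])),
            "go_terms": ";".join(sorted(ann.go[p])),
        }
        for p in ann.protein_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_intensity_table(table: IntensityTable, path: str | Path, meta_path: str | Path) -> None:
    """Write an intensity table and its metadata as the two-TSV external format."""
    out = table.values.copy()
    out.insert(0, "protein_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")
    meta = pd.DataFrame([vars(s) for s in table.samples])
    meta.to_csv(meta_path, sep="\t", index=False)
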