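"""Reading, probe filtering, and normalization of expression cohorts.

A cohort arrives as a tab-separated table with one row per patient and one
column per microarray probe (or gene). Probes are collapsed to genes via an
annotation table; probes without an annotated gene carry no usable biology
for the knowledge graph and are dropped. Values can then be min-max scaled
per gene (across patients) or per patient (across genes) onto [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "NormalizationMode",
    "ExpressionLoadError",
    "read_expression_table",
    "read_probe_annotation",
    "read_labels",
    "collapse_probes",
    "normalize",
]


class ExpressionLoadError(ValueError):
    """Raised when an expression table violates the load contract."""


class NormalizationMode(str, enum.Enum):
    """How to min-max scale a cohort before graph construction."""

    NONE = "none"
    PER_GENE = "per_gene"
    PER_PATIENT = "per_patient"


@dataclass(frozen=True)
class ExpressionDataset:
    """One cohort: a patients x genes matrix with optional binary labels.

    ``values[i, j]`` is the expression of ``gene_ids[j]`` in
    ``patient_ids[i]`` (non-negative, arbitrary units before normalization).
    ``labels`` maps patient_id to ``"case"`` or ``"control"`` when known.
    """

    dataset_id: str
    patient_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    labels: Optional[Mapping[str, str]] = field(default=None)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if vals.shape != (len(self.patient_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match "
                f"({len(self.patient_ids)} patients, {len(self.gene_ids)} genes)"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene/probe IDs")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("non-finite expression values")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.gene_ids)
        )

    def label_vector(self) -> np.ndarray:
        """Binary label array aligned with ``patient_ids`` (case=1, control=0)."""
        if self.labels is None:
            raise ValueError(f"dataset {self.dataset_id!r} has no labels")
        missing = [p for p in self.patient_ids if p not in self.labels]
        if missing:
            raise ValueError(f"patients without labels: {missing[:5]}")
        return np.array(
            [1 if self.labels[p] == "case" else 0 for p in self.patient_ids], dtype=int
        )


def read_expression_table(path, dataset_id: str) -> ExpressionDataset:
    """Load a patients x probes TSV (first column patient ID, header probe IDs).

    Row and column order are preserved from the file. Missing, non-numeric
    cells or duplicated patient IDs are load errors naming the offender.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ExpressionLoadError(f"{path}: empty file") from exc
    index = [str(i) for i in df.index]
    dupes = pd.Index(index)[pd.Index(index).duplicated()]
    if len(dupes):
        raise ExpressionLoadError(f"duplicate patient ID {dupes[0]!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        bad = _first_bad_cell(df)
        raise ExpressionLoadError(
            f"non-numeric cell at patient {bad[0]!r}, column {bad[1]!r}"
        ) from exc
    if values.isna().any().any():
        row, col = _first_na_cell(values)
        raise ExpressionLoadError(f"missing value at patient {row!r}, column {col!r}")
    return ExpressionDataset(
        dataset_id=dataset_id,
        patient_ids=tuple(index),
        gene_ids=tuple(str(c) for c in df.columns),
        values=values.to_numpy(dtype=float),
    )


def _first_bad_cell(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(col)
    return "?", "?"


def _first_na_cell(df: pd.DataFrame) -> tuple[str, str]:
    mask = df.isna()
    for col in df.columns:
        if mask[col].any():
            return str(df.index[mask[col].argmax()]), str(col)
    return "?", "?"


def read_probe_annotation(path) -> dict[str, str]:
    """Read a (probe_id, gene_id) TSV into a probe -> gene mapping.

    Probes without a gene simply do not appear; blank gene cells are skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionLoadError(f"{path}: need (probe_id, gene_id) columns")
    probe_col, gene_col = df.columns[:2]
    mapping: dict[str, str] = {}
    for probe, gene in zip(df[probe_col], df[gene_col]):
        if pd.isna(gene) or str(gene).strip() == "":
            continue
        probe = str(probe)
        if probe in mapping and mapping[probe] != str(gene):
            raise ExpressionLoadError(f"probe {probe!r} maps to multiple genes")
        mapping[probe] = str(gene)
    return mapping


def read_labels(path) -> dict[str, str]:
    """Read a (patient_id, label) TSV; labels must be 'case' or 'control'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    patient_col, label_col = df.columns[:2]
    labels: dict[str, str] = {}
    for pid, lab in zip(df[patient_col], df[label_col]):
        lab = str(lab).strip().lower()
        if lab not in {"case", "control"}:
            raise ExpressionLoadError(f"label {lab!r} for {pid!r} not in {{case, control}}")
        labels[str(pid)] = lab
    return labels


def collapse_probes(
    ds: ExpressionDataset,
    annot: Mapping[str, str],
    agg: str = "mean",
) -> ExpressionDataset:
    """Drop unannotated probes and summarize multi-probe genes.

    Probes absent from ``annot`` are filtered out; probes mapping to the same
    gene are aggregated (arithmetic mean by default, ``agg="median"``
    available). Column order follows first appearance of each gene.
    """
    if agg not in {"mean", "median"}:
        raise ValueError(f"unknown aggregation {agg!r}")
    kept = [(j, annot[p]) for j, p in enumerate(ds.gene_ids) if p in annot]
    if not kept:
        raise ExpressionLoadError(f"dataset {ds.dataset_id!r}: no annotated probes")
    gene_cols: dict[str, list[int]] = {}
    for j, gene in kept:
        gene_cols.setdefault(gene, []).append(j)
    genes = list(gene_cols)
    func = np.mean if agg == "mean" else np.median
    out = np.empty((ds.n_patients, len(genes)), dtype=float)
    for k, gene in enumerate(genes):
        out[:, k] = func(ds.values[:, gene_cols[gene]], axis=1)
    return replace(ds, gene_ids=tuple(genes), values=out)


def normalize(ds: ExpressionDataset, mode: NormalizationMode | str) -> ExpressionDataset:
    """Min-max scale per gene (column) or per patient (row) onto [0, 1].

    A constant column/row has zero range; it maps to all zeros so values stay
    in [0, 1] without NaNs.
    """
    mode = NormalizationMode(mode)
    if mode is NormalizationMode.NONE:
        return ds
    axis = 0 if mode is NormalizationMode.PER_GENE else 1
    vals = ds.values
    if vals.size == 0:
        return ds
    lo = vals.min(axis=axis, keepdims=True)
    rng = vals.max(axis=axis, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(rng > 0, (vals - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return replace(ds, values=scaled)
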