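"""The eight patient-representation strategies.

Per embedding method, patients are represented either *directly* — the
patient entity's own vector from a graph that contains patients (three
binning variants, one per normalization mode, plus two patient-gene link
variants) — or *compositely*, as the expression-weighted average of gene
embedding vectors, with weights taken from the raw, patient-normalized or
gene-normalized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from patientkg.expression_io import ExpressionDataset, NormalizationMode, normalize
from patientkg.kg_builder import (
    KnowledgeGraph,
    build_binning_graph,
    build_link_graph,
    gene_iri,
    merge_and_map,
    patient_iri,
)
from patientkg.kg_embeddings import EmbeddingTable, train_embeddings

__all__ = [
    "PatientMatrix",
    "STRATEGIES",
    "direct_representation",
    "composite_representation",
    "enumerate_strategies",
]

logger = logging.getLogger(__name__)

STRATEGIES = (
    "composite_not-norm",
    "composite_pat-norm",
    "composite_gene-norm",
    "direct_kgbin_not-norm",
    "direct_kgbin_pat-norm",
    "direct_kgbin_gene-norm",
    "direct_linkpat-gene_patavg",
    "direct_linkpat-gene_geneavg",
)

_COMPOSITE_NORM = {
    "composite_not-norm": NormalizationMode.NONE,
    "composite_pat-norm": NormalizationMode.PER_PATIENT,
    "composite_gene-norm": NormalizationMode.PER_GENE,
}
_BIN_NORM = {
    "direct_kgbin_not-norm": NormalizationMode.NONE,
    "direct_kgbin_pat-norm": NormalizationMode.PER_PATIENT,
    "direct_kgbin_gene-norm": NormalizationMode.PER_GENE,
}
_LINK_MODE = {
    "direct_linkpat-gene_patavg": "patient_avg",
    "direct_linkpat-gene_geneavg": "gene_avg",
}


@dataclass(frozen=True)
class PatientMatrix:
    """Patients x dim representation from one strategy and one method."""

    patient_ids: tuple[str, ...]
    vectors: np.ndarray
    strategy: str
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        vecs = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vecs)
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy tag {self.strategy!r}")
        if vecs.shape[0] != len(self.patient_ids):
            raise ValueError("one row per patient required")
        if vecs.size and not np.all(np.isfinite(vecs)):
            raise ValueError("non-finite representation entries")

    def rows_for(self, patient_ids: Sequence[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        return self.vectors[[pos[p] for p in patient_ids]]


def direct_representation(
    table: EmbeddingTable,
    patients: Sequence[str],
    strategy: str = "direct_linkpat-gene_patavg",
) -> PatientMatrix:
    """Pure lookup: row i is the entity vector of patient i, untransformed."""
    rows = []
    for p in patients:
        iri = p if p.startswith(":patient/") else patient_iri(p)
        if iri not in table.entity_vectors:
            raise KeyError(f"patient {p!r} has no embedding")
        rows.append(table.entity_vectors[iri])
    return PatientMatrix(
        patient_ids=tuple(patients), vectors=np.stack(rows),
        strategy=strategy, method=table.method,
    )


def composite_representation(
    table: EmbeddingTable,
    ds: ExpressionDataset,
    strategy: str = "composite_not-norm",
) -> PatientMatrix:
    """Expression-weighted average of gene embeddings per patient.

    ``row_p = sum_g w_pg e_g / sum_g w_pg`` with non-negative weights from
    the (possibly normalized) expression matrix. Genes lacking embeddings are
    dropped from both sums (warned); a patient whose usable weights are all
    zero gets the zero vector (warned).
    """
    usable: list[tuple[int, np.ndarray]] = []
    missing = []
    for j, g in enumerate(ds.gene_ids):
        iri = gene_iri(g)
        if iri in table.entity_vectors:
            usable.append((j, table.entity_vectors[iri]))
        else:
            missing.append(g)
    if missing:
        logger.warning("%d genes lack embeddings and are dropped: %s...",
                       len(missing), missing[:3])
    if not usable:
        raise ValueError(f"dataset {ds.dataset_id!r}: no gene has an embedding")
    cols = [j for j, _ in usable]
    G = np.stack([v for _, v in usable])          # (g, dim)
    W = ds.values[:, cols]                        # (p, g), non-negative
    if np.any(W < 0):
        raise ValueError("negative expression weights")
    sums = W.sum(axis=1, keepdims=True)
    zero_rows = sums[:, 0] == 0
    if zero_rows.any():
        logger.warning("%d patients have all-zero weights; zero vectors emitted",
                       int(zero_rows.sum()))
    out = (W @ G) / np.where(sums > 0, sums, 1.0)
    out[zero_rows] = 0.0
    return PatientMatrix(
        patient_ids=ds.patient_ids, vectors=out,
        strategy=strategy, method=table.method,
    )


def enumerate_strategies(
    method: str,
    datasets: Sequence[ExpressionDataset],
    domain_graph: Optional[KnowledgeGraph] = None,
    mapping: Optional[Mapping[str, str]] = None,
    dim: int = 100,
    seed: int = 0,
    bin_fraction: float = 0.1,
    composite_link_mode: str = "gene_avg",
    strategies: Optional[Sequence[str]] = None,
    train: Optional[Callable[[KnowledgeGraph], EmbeddingTable]] = None,
) -> dict[str, list[PatientMatrix]]:
    """Build patient matrices for the requested strategies of one method.

    Direct strategies train on the merged graph of the matching KG variant
    (binning on the strategy's normalization mode, or the link graph with the
    strategy's averaging mode). Composite strategies share one embedding
    table — genes embedded from the merged link-strategy graph
    (``composite_link_mode`` averaging) — and differ only in the weight
    normalization. Returns one PatientMatrix per cohort per strategy.

    ``train`` overrides the training call (same graph in, table out), which
    is how reduced-scale profiles are injected.
    """
    wanted = list(strategies) if strategies is not None else list(STRATEGIES)
    unknown = set(wanted) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    if train is None:
        train = lambda kg: train_embeddings(kg, method, dim=dim, seed=seed)

    out: dict[str, list[PatientMatrix]] = {}

    def merged(expr_graphs):
        return merge_and_map(expr_graphs, domain_graph, mapping)

    composite_wanted = [s for s in wanted if s in _COMPOSITE_NORM]
    if composite_wanted:
        expr_graphs = [build_link_graph(ds, composite_link_mode) for ds in datasets]
        table = train(merged(expr_graphs))
        for strat in composite_wanted:
            mode = _COMPOSITE_NORM[strat]
            out[strat] = [
                composite_representation(table, normalize(ds, mode), strat)
                for ds in datasets
            ]

    for strat in wanted:
        if strat in _BIN_NORM:
            mode = _BIN_NORM[strat]
            expr_graphs = [
                build_binning_graph(normalize(ds, mode), bin_fraction)
                for ds in datasets
            ]
        elif strat in _LINK_MODE:
            expr_graphs = [build_link_graph(ds, _LINK_MODE[strat]) for ds in datasets]
        else:
            continue
        try:
            table = train(merged(expr_graphs))
            out[strat] = [
                direct_representation(
                    table, [patient_iri(p) for p in ds.patient_ids], strat
                )
                for ds in datasets
            ]
            # restore bare patient IDs for downstream label joins
            out[strat] = [
                PatientMatrix(ds.patient_ids, m.vectors, strat, method)
                for ds, m in zip(datasets, out[strat])
            ]
        except Exception as exc:
            raise RuntimeError(f"strategy {strat!r} failed: {exc}") from exc
    return out
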