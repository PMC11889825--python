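"""End-to-end orchestration: cohorts + domain knowledge -> evaluation grid.

The study design: one primary labelled cohort is evaluated by stratified
cross-validation; any further cohorts act as auxiliary training data pooled
into every fold. For each requested embedding method and representation
strategy the pipeline builds the matching knowledge-graph variant, trains
embeddings, derives patient matrices, and scores classification and
clustering quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from patientkg.expression_io import ExpressionDataset
from patientkg.evaluation import (
    EvaluationReport,
    clustering_scores,
    evaluate_classification,
    stratified_kfold,
)
from patientkg.kg_builder import KnowledgeGraph
from patientkg.kg_embeddings import (
    METHODS,
    WalkConfig,
    method_defaults,
    train_scoring_model,
    train_walk_embeddings,
    generate_walks,
)
from patientkg.patient_repr import STRATEGIES, enumerate_strategies

__all__ = ["StudyConfig", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Scale profile of one study run.

    The full-scale profile matches the conventional settings (dim 100,
    500 epochs, 100 walks per entity); the default here is a reduced profile
    sized for desk-scale synthetic workspaces.
    """

    dim: int = 32
    epochs: int = 60
    n_batches: int = 20
    max_walks: int = 20
    sg_epochs: int = 3
    walk_depth: int = 4
    k_folds: int = 5
    bin_fraction: float = 0.1
    seed: int = 0


def _make_trainer(method: str, cfg: StudyConfig):
    if method == "rdf2vec":
        wc = WalkConfig(
            depth=cfg.walk_depth,
            max_walks_per_entity=cfg.max_walks,
            sg_epochs=cfg.sg_epochs,
            seed=cfg.seed,
        )

        def train(kg: KnowledgeGraph):
            corpus = generate_walks(kg, wc)
            return train_walk_embeddings(corpus, dim=cfg.dim, config=wc,
                                         entities=kg.entities)

        return train
    hp = method_defaults(
        method, dim=cfg.dim, epochs=cfg.epochs, n_batches=cfg.n_batches,
        seed=cfg.seed,
    )
    return lambda kg: train_scoring_model(kg, method, hp)


def run_study(
    datasets: Sequence[ExpressionDataset],
    domain_graph: Optional[KnowledgeGraph] = None,
    mapping: Optional[Mapping[str, str]] = None,
    methods: Sequence[str] = ("rdf2vec",),
    strategies: Optional[Sequence[str]] = None,
    config: Optional[StudyConfig] = None,
) -> dict[tuple[str, str], EvaluationReport]:
    """Run the method x strategy grid; ``datasets[0]`` is the primary cohort.

    Returns one report per (method, strategy) with per-fold classification
    metrics on the primary cohort and clustering scores over all labelled
    patients pooled across cohorts.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    cfg = config if config is not None else StudyConfig()
    primary = datasets[0]
    if primary.labels is None:
        raise ValueError("primary cohort must be labelled")
    folds = stratified_kfold(
        {p: primary.labels[p] for p in primary.patient_ids},
        k=cfg.k_folds, seed=cfg.seed,
    )
    reports: dict[tuple[str, str], EvaluationReport] = {}
    for method in methods:
        trainer = _make_trainer(method, cfg)
        matrices = enumerate_strategies(
            method, datasets, domain_graph=domain_graph, mapping=mapping,
            dim=cfg.dim, seed=cfg.seed, bin_fraction=cfg.bin_fraction,
            strategies=strategies, train=trainer,
        )
        for strat, per_cohort in matrices.items():
            prim = per_cohort[0]
            aux_vecs, aux_labs = [], []
            for ds, mat in zip(datasets[1:], per_cohort[1:]):
                if ds.labels is None:
                    continue
                aux_vecs.append(mat.vectors)
                aux_labs.extend(ds.labels[p] for p in mat.patient_ids)
            report = evaluate_classification(
                prim.vectors, prim.patient_ids, primary.labels, folds,
                aux_vectors=np.vstack(aux_vecs) if aux_vecs else None,
                aux_labels=aux_labs if aux_labs else None,
                strategy=strat, method=method, seed=cfg.seed,
            )
            pooled = [m.vectors for m in per_cohort]
            pooled_labels = [
                ds.labels[p]
                for ds, m in zip(datasets, per_cohort) if ds.labels is not None
                for p in m.patient_ids
            ]
            if len(set(pooled_labels)) >= 2:
                ch, db, sil = clustering_scores(
                    np.vstack(pooled), pooled_labels
                )
                report.clustering = {"calinski_harabasz": ch,
                                     "davies_bouldin": db,
                                     "silhouette": sil}
            prim_labels = [primary.labels[p] for p in prim.patient_ids]
            if len(set(prim_labels)) >= 2:
                ch_p, db_p, sil_p = clustering_scores(prim.vectors, prim_labels)
                report.clustering.update({
                    "calinski_harabasz_primary": ch_p,
                    "davies_bouldin_primary": db_p,
                    "silhouette_primary": sil_p,
                })
            reports[(method, strat)] = report
    return reports
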