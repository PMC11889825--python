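"""Seeded synthetic fixtures: multi-cohort expression data plus domain knowledge.

Real studies of this kind combine several public expression cohorts whose
gene panels only partially overlap, a class hierarchy of protein functions,
function annotations, and scored protein-protein interactions. This module
generates all of those artifacts with a planted, recoverable disease signal:
case patients have a configurable subset of genes shifted upward by a fixed
effect size over a Gaussian noise floor. Everything derives deterministically
from one master seed.

The generator emulates the structure of such studies — cohort sizes, Venn-style
gene overlaps, binary case/control labels, a rooted acyclic ontology with
three root classes, uniform interaction scores — not microarray noise physics
or platform effects.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from patientkg.expression_io import ExpressionDataset

__all__ = [
    "CohortSpec",
    "DomainSpec",
    "generate_cohorts",
    "generate_domain_knowledge",
    "default_workspace_specs",
    "write_workspace",
]

BASELINE_EXPRESSION = 5.0  # arbitrary units; keeps truncation at zero rare


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the mean upward shift of ``signal_genes`` in case
    patients, in the same arbitrary units as the baseline; ``noise_sd`` is
    the Gaussian noise standard deviation shared by all genes.
    """

    dataset_id: str
    n_case: int
    n_control: int
    genes: tuple[str, ...]
    signal_genes: tuple[str, ...] = ()
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline: float = BASELINE_EXPRESSION

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "signal_genes", tuple(self.signal_genes))
        if not set(self.signal_genes) <= set(self.genes):
            raise ValueError("signal_genes must be a subset of genes")
        if self.n_case + self.n_control < 2:
            raise ValueError("need at least two patients")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class DomainSpec:
    """Parameters of the synthetic domain knowledge.

    Three roots by default, one per function domain (process, function,
    component), mirroring a hierarchy whose roots share no common ancestor.
    """

    n_classes: int = 30
    n_roots: int = 3
    annotation_density: float = 0.3
    n_proteins: int = 0  # 0 = one protein per gene, filled by the caller
    ppi_edge_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n_roots > self.n_classes:
            raise ValueError("n_roots cannot exceed n_classes")
        if not (0 < self.annotation_density <= 1):
            raise ValueError("annotation_density must be in (0, 1]")
        if not (0 <= self.ppi_edge_prob <= 1):
            raise ValueError("ppi_edge_prob must be in [0, 1]")


def _rng(master_seed: int, *stream: str | int) -> np.random.Generator:
    """Deterministic per-component RNG derived from one master seed."""
    keys = [zlib.crc32(str(s).encode()) % (2**31) for s in stream]
    ss = np.random.SeedSequence([master_seed % (2**31)] + keys)
    return np.random.default_rng(ss)


def make_gene_panels(
    sizes: Sequence[int], shared: int, prefix: str = "G"
) -> list[tuple[str, ...]]:
    """Gene ID panels where every pair of cohorts shares the first ``shared``
    genes; the remainder of each panel is cohort-private."""
    if any(shared > s for s in sizes):
        raise ValueError("shared gene count exceeds a panel size")
    core = [f"{prefix}{i:04d}" for i in range(shared)]
    panels = []
    offset = shared
    for s in sizes:
        private = [f"{prefix}{offset + i:04d}" for i in range(s - shared)]
        offset += s - shared
        panels.append(tuple(core + private))
    return panels


def generate_cohorts(
    specs: Sequence[CohortSpec], master_seed: int = 0
) -> list[ExpressionDataset]:
    """Draw labelled expression matrices with the planted case/control signal.

    Values are Normal(baseline, noise_sd), with signal genes in case patients
    shifted to Normal(baseline + effect_size, noise_sd); all values are
    truncated at zero. A fixed seed yields bit-identical matrices.
    """
    out = []
    for spec in specs:
        rng = _rng(master_seed, "cohort", spec.dataset_id)
        n = spec.n_case + spec.n_control
        g = len(spec.genes)
        values = rng.normal(spec.baseline, spec.noise_sd, size=(n, g))
        sig_cols = [j for j, gene in enumerate(spec.genes) if gene in set(spec.signal_genes)]
        if sig_cols and spec.effect_size != 0:
            values[: spec.n_case, sig_cols] += spec.effect_size
        np.maximum(values, 0.0, out=values)
        patient_ids = tuple(
            f"{spec.dataset_id}-P{i:03d}" for i in range(n)
        )
        labels = {
            pid: ("case" if i < spec.n_case else "control")
            for i, pid in enumerate(patient_ids)
        }
        out.append(
            ExpressionDataset(
                dataset_id=spec.dataset_id,
                patient_ids=patient_ids,
                gene_ids=spec.genes,
                values=values,
                labels=labels,
            )
        )
    return out


def generate_domain_knowledge(
    spec: DomainSpec,
    genes: Sequence[str],
    master_seed: int = 0,
) -> tuple[
    list[tuple[str, str]],
    list[tuple[str, str]],
    list[tuple[str, str, float]],
    dict[str, str],
]:
    """Generate (ontology, annotations, scored PPI edges, gene->protein map).

    The ontology is a rooted DAG built by construction: classes are ordered,
    the first ``n_roots`` are roots, and every later class picks one or two
    parents among strictly earlier classes, so cycles are impossible. Each
    protein is annotated to a random subset of classes
    (``annotation_density`` of them in expectation, at least one), PPI edges
    appear independently with ``ppi_edge_prob`` and carry uniform [0, 1]
    combined scores, and the gene/protein mapping is a bijection.
    """
    rng = _rng(master_seed, "domain")
    classes = [f"C{i:03d}" for i in range(spec.n_classes)]
    ontology: list[tuple[str, str]] = []
    for i in range(spec.n_roots, spec.n_classes):
        n_parents = int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in np.atleast_1d(parents):
            ontology.append((classes[i], classes[int(p)]))

    genes = list(genes)
    n_proteins = spec.n_proteins or len(genes)
    proteins = [f"PROT{i:04d}" for i in range(n_proteins)]
    mapping = {gene: proteins[i] for i, gene in enumerate(genes) if i < n_proteins}

    annotations: list[tuple[str, str]] = []
    # annotate only to classes present in the ontology edge list, so every
    # annotation cross-references a class the domain graph will know about
    present = sorted({c for pair in ontology for c in pair}) or classes[: spec.n_roots]
    n_annot = max(1, int(round(spec.annotation_density * spec.n_classes)))
    for prot in proteins:
        chosen = rng.choice(len(present), size=min(n_annot, len(present)),
                            replace=False)
        for c in np.atleast_1d(chosen):
            annotations.append((prot, present[int(c)]))

    ppi: list[tuple[str, str, float]] = []
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            if rng.random() < spec.ppi_edge_prob:
                ppi.append((proteins[i], proteins[j], float(rng.random())))

    return ontology, annotations, ppi, mapping


@dataclass(frozen=True)
class WorkspaceSpecs:
    cohorts: tuple[CohortSpec, ...]
    domain: DomainSpec
    all_genes: tuple[str, ...] = field(default=())


def default_workspace_specs(
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    n_signal: int = 10,
    cohort_sizes: tuple[tuple[int, int], ...] = ((20, 22), (3, 12), (8, 8)),
    panel_sizes: tuple[int, ...] = (60, 50, 40),
    shared: int = 30,
) -> WorkspaceSpecs:
    """Study-shaped default: one primary cohort plus two small auxiliary
    cohorts with partially overlapping gene panels; the signal genes live in
    the shared core so every cohort carries the signal."""
    panels = make_gene_panels(panel_sizes, shared)
    signal = panels[0][:n_signal]
    cohorts = tuple(
        CohortSpec(
            dataset_id=f"cohort{k + 1}",
            n_case=nc,
            n_control=nt,
            genes=panels[k],
            signal_genes=tuple(g for g in signal if g in panels[k]),
            effect_size=effect_size,
            noise_sd=noise_sd,
        )
        for k, (nc, nt) in enumerate(cohort_sizes)
    )
    all_genes = tuple(dict.fromkeys(g for p in panels for g in p))
    return WorkspaceSpecs(cohorts=cohorts, domain=DomainSpec(), all_genes=all_genes)


def write_workspace(specs: WorkspaceSpecs, outdir, master_seed: int = 0) -> dict:
    """Materialize a full workspace of TSV files consumable by the loaders.

    Returns a manifest of the paths written.
    """
    os.makedirs(outdir, exist_ok=True)
    datasets = generate_cohorts(specs.cohorts, master_seed)
    ontology, annotations, ppi, mapping = generate_domain_knowledge(
        specs.domain, specs.all_genes, master_seed
    )
    manifest: dict = {"cohorts": []}
    for ds in datasets:
        expr_path = os.path.join(outdir, f"{ds.dataset_id}_expression.tsv")
        with open(expr_path, "w", encoding="utf-8") as fh:
            fh.write("patient_id\t" + "\t".join(ds.gene_ids) + "\n")
            for i, pid in enumerate(ds.patient_ids):
                row = "\t".join(f"{v:.6g}" for v in ds.values[i])
                fh.write(f"{pid}\t{row}\n")
        label_path = os.path.join(outdir, f"{ds.dataset_id}_labels.tsv")
        with open(label_path, "w", encoding="utf-8") as fh:
            fh.write("patient_id\tlabel\n")
            for pid in ds.patient_ids:
                fh.write(f"{pid}\t{ds.labels[pid]}\n")
        manifest["cohorts"].append(
            {"dataset_id": ds.dataset_id, "expression": expr_path, "labels": label_path}
        )
    paths = {
        "ontology": ("child_class\tparent_class\n",
                     [f"{c}\t{p}\n" for c, p in ontology]),
        "annotations": ("protein\tclass\n",
                        [f"{a}\t{c}\n" for a, c in annotations]),
        "ppi": ("proteinA\tproteinB\tcombined_score\n",
                [f"{a}\t{b}\t{s:.6f}\n" for a, b, s in ppi]),
        "mapping": ("gene\tprotein\n",
                    [f"{g}\t{p}\n" for g, p in mapping.items()]),
    }
    for name, (header, lines) in paths.items():
        path = os.path.join(outdir, f"{name}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            fh.writelines(lines)
        manifest[name] = path
    return manifest
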