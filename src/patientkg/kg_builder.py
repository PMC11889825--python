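"""Knowledge-graph construction from expression cohorts and domain knowledge.

Expression values never enter the graph as numeric literals (most embedding
methods cannot consume them). Two strategies turn a cohort matrix into
structure:

* **binning** — each gene's value range (within one dataset) is discretized
  into interval entities; each (patient, gene) measurement is reified through
  a skolemized blank node linked to the gene and to its bin.
* **patient-gene links** — an edge ``hasHighExpressionOf`` is created only
  when the value strictly exceeds an average (the patient's own mean across
  genes, or the gene's mean across patients).

Domain knowledge contributes a class hierarchy (subclass-of triples),
protein function annotations, and protein-protein interactions kept only
above a confidence threshold (strictly above 0.7 by default, mirroring
high-confidence STRING filtering). A gene-to-protein mapping bridges the two
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from patientkg.expression_io import ExpressionDataset

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "BinSpec",
    "RDF_TYPE",
    "HAS_EXPRESSION",
    "IS_EXPRESSION_OF_GENE",
    "HAS_VALUE",
    "HAS_HIGH_EXPRESSION_OF",
    "SUBCLASS_OF",
    "HAS_FUNCTION",
    "INTERACTS_WITH",
    "MAPPED_TO_PROTEIN",
    "compute_bins",
    "build_binning_graph",
    "build_link_graph",
    "build_domain_graph",
    "merge_and_map",
    "write_ntriples",
    "read_ntriples",
]

# Relation IRIs (compact, namespaced under an internal prefix).
RDF_TYPE = "rdf:type"
HAS_EXPRESSION = ":hasExpression"
IS_EXPRESSION_OF_GENE = ":isExpressionOfGene"
HAS_VALUE = ":hasValue"
HAS_HIGH_EXPRESSION_OF = ":hasHighExpressionOf"
SUBCLASS_OF = ":subClassOf"
HAS_FUNCTION = ":hasFunction"
INTERACTS_WITH = ":interactsWith"
MAPPED_TO_PROTEIN = ":mappedToProtein"

PATIENT_CLASS = ":Patient"
GENE_CLASS = ":Gene"


@dataclass(frozen=True)
class Triple:
    """A (subject, predicate, object) fact; the object is always an entity."""

    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if not (self.subject and self.predicate and self.object):
            raise ValueError(f"empty component in triple {self!r}")


# entity kind tags
KINDS = ("patient", "gene", "protein", "class", "bin", "blank", "type")


@dataclass
class KnowledgeGraph:
    """A set of entity triples with entity-kind and relation registries."""

    triples: set[Triple] = field(default_factory=set)
    entities: dict[str, str] = field(default_factory=dict)  # IRI -> kind tag
    relations: set[str] = field(default_factory=set)

    def add(self, subject: str, predicate: str, obj: str,
            s_kind: str = "type", o_kind: str = "type") -> None:
        self.triples.add(Triple(subject, predicate, obj))
        self.entities.setdefault(subject, s_kind)
        self.entities.setdefault(obj, o_kind)
        self.relations.add(predicate)

    def update(self, other: "KnowledgeGraph") -> None:
        self.triples |= other.triples
        for iri, kind in other.entities.items():
            self.entities.setdefault(iri, kind)
        self.relations |= other.relations

    def entities_of_kind(self, kind: str) -> list[str]:
        return sorted(e for e, k in self.entities.items() if k == kind)

    def out_edges(self, subject: str) -> list[Triple]:
        return [t for t in self.triples if t.subject == subject]

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def sorted_triples(self) -> list[Triple]:
        return sorted(self.triples, key=lambda t: (t.subject, t.predicate, t.object))


@dataclass(frozen=True)
class BinSpec:
    """Equal-width discretization of one gene's values within one dataset."""

    dataset_id: str
    gene_id: str
    edges: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_index(self, value: float) -> int:
        """Index of the half-open bin [e_i, e_{i+1}) containing value; the
        last bin is closed on the right."""
        if self.n_bins == 1:
            return 0
        idx = int(np.searchsorted(self.edges, value, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)


def compute_bins(
    values: Sequence[float],
    unique_fraction: float = 0.1,
    dataset_id: str = "",
    gene_id: str = "",
) -> BinSpec:
    """Derive a bin specification from observed values of one gene.

    The number of bins is a fraction of the number of distinct values
    (``max(1, round(unique_fraction * n_distinct))``) so genes with richer
    value sets get finer discretization; edges are equal-width over
    [min, max]. Constant input collapses to a single bin.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot bin an empty value set")
    if not (0 < unique_fraction <= 1):
        raise ValueError(f"unique_fraction {unique_fraction} not in (0, 1]")
    n_distinct = len(np.unique(vals))
    n_bins = max(1, int(round(unique_fraction * n_distinct)))
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        n_bins = 1
    edges = tuple(np.linspace(lo, hi, n_bins + 1).tolist())
    return BinSpec(dataset_id=dataset_id, gene_id=gene_id, edges=edges)


def patient_iri(patient_id: str) -> str:
    return f":patient/{patient_id}"


def gene_iri(gene_id: str) -> str:
    return f":gene/{gene_id}"


def protein_iri(protein_id: str) -> str:
    return protein_id if protein_id.startswith(":protein/") else f":protein/{protein_id}"


def class_iri(class_id: str) -> str:
    return class_id if class_id.startswith(":class/") else f":class/{class_id}"


def build_binning_graph(
    ds: ExpressionDataset, unique_fraction: float = 0.1
) -> KnowledgeGraph:
    """Reify every (patient, gene) measurement through a blank node.

    Per cell the graph gains three triples —
    ``(patient, hasExpression, blank)``, ``(blank, isExpressionOfGene, gene)``
    and ``(blank, hasValue, bin)`` — plus one type triple per patient and per
    gene. Blank nodes are skolemized to deterministic IRIs
    ``_:expr/{dataset}/{patient}/{gene}`` so entity identity is stable across
    runs; bin entities are shared across patients within one (dataset, gene)
    scope only.
    """
    kg = KnowledgeGraph()
    bins = {
        g: compute_bins(ds.values[:, j], unique_fraction, ds.dataset_id, g)
        for j, g in enumerate(ds.gene_ids)
    }
    for p in ds.patient_ids:
        kg.add(patient_iri(p), RDF_TYPE, PATIENT_CLASS, "patient", "type")
    for g in ds.gene_ids:
        kg.add(gene_iri(g), RDF_TYPE, GENE_CLASS, "gene", "type")
    for i, p in enumerate(ds.patient_ids):
        for j, g in enumerate(ds.gene_ids):
            blank = f"_:expr/{ds.dataset_id}/{p}/{g}"
            b = bins[g].bin_index(ds.values[i, j])
            bin_ent = f":bin/{ds.dataset_id}/{g}/{b}"
            kg.add(patient_iri(p), HAS_EXPRESSION, blank, "patient", "blank")
            kg.add(blank, IS_EXPRESSION_OF_GENE, gene_iri(g), "blank", "gene")
            kg.add(blank, HAS_VALUE, bin_ent, "blank", "bin")
    return kg


def build_link_graph(ds: ExpressionDataset, mode: str = "patient_avg") -> KnowledgeGraph:
    """Link a patient to a gene iff expression strictly exceeds an average.

    ``mode="patient_avg"`` compares each value against that patient's mean
    across all its genes; ``mode="gene_avg"`` against the gene's mean across
    all patients. Equality never creates a link.
    """
    if mode not in {"patient_avg", "gene_avg"}:
        raise ValueError(f"unknown link mode {mode!r}")
    kg = KnowledgeGraph()
    for p in ds.patient_ids:
        kg.add(patient_iri(p), RDF_TYPE, PATIENT_CLASS, "patient", "type")
    for g in ds.gene_ids:
        kg.add(gene_iri(g), RDF_TYPE, GENE_CLASS, "gene", "type")
    if ds.values.size == 0:
        return kg
    if mode == "patient_avg":
        thresh = ds.values.mean(axis=1, keepdims=True)
    else:
        thresh = ds.values.mean(axis=0, keepdims=True)
    above = ds.values > thresh
    for i, p in enumerate(ds.patient_ids):
        for j, g in enumerate(ds.gene_ids):
            if above[i, j]:
                kg.add(patient_iri(p), HAS_HIGH_EXPRESSION_OF, gene_iri(g),
                       "patient", "gene")
    return kg


def build_domain_graph(
    ontology: Iterable[tuple[str, str]],
    annotations: Iterable[tuple[str, str]],
    ppi: Iterable[tuple[str, str, float]] = (),
    score_threshold: float = 0.7,
) -> KnowledgeGraph:
    """Assemble the domain-knowledge component of the graph.

    ``ontology`` is (child_class, parent_class) subclass-of pairs,
    ``annotations`` is (protein, class) function assignments, and ``ppi`` is
    (proteinA, proteinB, combined_score) with scores in [0, 1]. Only
    interactions with score strictly above ``score_threshold`` are kept, once
    per unordered pair in canonical ID order. Annotations referencing a class
    absent from the ontology are errors.
    """
    kg = KnowledgeGraph()
    classes: set[str] = set()
    for child, parent in ontology:
        c, p = class_iri(child), class_iri(parent)
        kg.add(c, SUBCLASS_OF, p, "class", "class")
        classes |= {c, p}
    for protein, cls in annotations:
        c = class_iri(cls)
        if classes and c not in classes:
            raise ValueError(f"annotation references unknown class {cls!r}")
        kg.add(protein_iri(protein), HAS_FUNCTION, c, "protein", "class")
    seen_pairs: set[tuple[str, str]] = set()
    for a, b, score in ppi:
        if not (score > score_threshold):
            continue
        pa, pb = sorted((protein_iri(a), protein_iri(b)))
        if (pa, pb) in seen_pairs:
            continue
        seen_pairs.add((pa, pb))
        kg.add(pa, INTERACTS_WITH, pb, "protein", "protein")
    return kg


def merge_and_map(
    expression_graphs: Sequence[KnowledgeGraph],
    domain_graph: KnowledgeGraph | None = None,
    mapping: Mapping[str, str] | None = None,
) -> KnowledgeGraph:
    """Union expression and domain graphs and bridge genes to proteins.

    Genes shared by cohorts collapse to a single entity (identity by IRI).
    For every mapped gene that occurs in some expression graph a
    ``(gene, mappedToProtein, protein)`` triple is added; unmapped genes stay
    in the graph but remain disconnected from the domain component.
    """
    merged = KnowledgeGraph()
    for g in expression_graphs:
        merged.update(g)
    if domain_graph is not None:
        merged.update(domain_graph)
    if mapping:
        expr_genes = {
            e for g in expression_graphs for e, k in g.entities.items() if k == "gene"
        }
        for gene, protein in mapping.items():
            gi = gene_iri(gene)
            if gi in expr_genes:
                merged.add(gi, MAPPED_TO_PROTEIN, protein_iri(protein),
                           "gene", "protein")
    return merged


def write_ntriples(kg: KnowledgeGraph, path) -> None:
    """Serialize one triple per line as ``<s> <p> <o> .`` in sorted order."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.sorted_triples():
            fh.write(f"<{t.subject}> <{t.predicate}> <{t.object}> .\n")


def read_ntriples(path) -> KnowledgeGraph:
    """Read the serialization written by :func:`write_ntriples`.

    Entity kinds are recovered from the IRI namespaces used by the builders.
    """
    kg = KnowledgeGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.rstrip(" .").split("> <")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed triple {line!r}")
            s, p, o = parts[0].lstrip("<"), parts[1], parts[2].rstrip(">")
            kg.add(s, p, o, _kind_from_iri(s), _kind_from_iri(o))
    return kg


def _kind_from_iri(iri: str) -> str:
    for prefix, kind in (
        (":patient/", "patient"),
        (":gene/", "gene"),
        (":protein/", "protein"),
        (":class/", "class"),
        (":bin/", "bin"),
        ("_:", "blank"),
    ):
        if iri.startswith(prefix):
            return kind
    return "type"
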