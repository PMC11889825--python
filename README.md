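# patientkg

Learning uniform patient representations from *incompatible* gene-expression
cohorts by integrating them — together with domain knowledge about protein
function and interactions — into a single biomedical knowledge graph.

## The problem

Public expression cohorts (e.g. case/control microarray studies of type 1
diabetes) are individually small, and different cohorts measure different,
only partially overlapping gene panels. Naively concatenating them produces
a matrix riddled with missing features. `patientkg` instead represents every
cohort in one knowledge graph (KG): patients, genes, proteins and ontology
classes become entities; expression measurements become graph structure; and
KG embedding methods then place *all* patients from *all* cohorts in one
vector space, where a single classifier can be trained.

## The method

**Graph construction.** Expression values never enter the KG as numeric
literals. Two strategies encode them:

- *binning* — per gene (within one dataset) the observed value range is
  discretized into equal-width interval entities; each measurement is
  reified through a skolemized blank node:
  `(patient, hasExpression, _:x)`, `(_:x, isExpressionOfGene, gene)`,
  `(_:x, hasValue, bin)`. The bin count is a fraction of the number of
  distinct values.
- *patient–gene links* — an edge `(patient, hasHighExpressionOf, gene)` is
  created only when the value strictly exceeds an average: either the
  patient's mean across its genes, or the gene's mean across patients.

Domain knowledge adds a class hierarchy of protein functions (subclass-of
triples with three roots sharing no common ancestor), protein→class
annotations, and protein–protein interactions retained only when their
combined confidence score is strictly above 0.7. A gene→protein mapping
bridges the expression and domain components.

**Embedding.** Six methods, all authored here with analytic gradients:

| method | score s(h, r, t) | loss |
|---|---|---|
| TransE | −‖h + r − t‖₂ | margin ranking |
| TransR | −‖M_r h + r − M_r t‖₂ | margin ranking |
| DistMult | Σᵢ hᵢ rᵢ tᵢ | softplus + L2 |
| ComplEx | Re(Σᵢ hᵢ rᵢ conj(tᵢ)) | softplus + L2 |
| HolE | r · (h ⋆ t), circular correlation | softplus |
| walk-based (RDF2vec-style) | — | skip-gram with negative sampling over random graph walks |

**Patient representation.** Eight strategies per method: five *direct*
(the patient entity's own vector, from binning KGs under three normalization
modes or link KGs under two averaging modes) and three *composite* (the
expression-weighted average of gene vectors, with raw, patient-normalized or
gene-normalized weights).

**Evaluation.** Stratified 5-fold cross-validation of a one-hidden-layer MLP
on the primary cohort (auxiliary cohorts pooled into every training fold),
reporting precision, recall, F1 and support-weighted F1; clustering quality
(Calinski-Harabasz, Davies-Bouldin, silhouette) over the representation
vectors; optional t-SNE projection for plots.

## Worked example

```python
from patientkg import build_domain_graph
from patientkg.pipeline import StudyConfig, run_study
from patientkg.synthetic_data import (
    default_workspace_specs, generate_cohorts, generate_domain_knowledge)

specs = default_workspace_specs(effect_size=3.0, noise_sd=1.0, n_signal=10)
datasets = generate_cohorts(specs.cohorts, master_seed=1)
onto, annot, ppi, mapping = generate_domain_knowledge(
    specs.domain, specs.all_genes, master_seed=1)
domain = build_domain_graph(onto, annot, ppi)

reports = run_study(
    datasets, domain, mapping,
    methods=["distmult"],
    strategies=["composite_gene-norm", "direct_linkpat-gene_geneavg"],
    config=StudyConfig(seed=1),
)
for (method, strategy), rep in sorted(reports.items()):
    print(method, strategy,
          "WAF %.3f +/- %.3f" % (rep.mean["weighted_f1"], rep.sd["weighted_f1"]),
          "silhouette %.3f" % rep.clustering["silhouette_primary"])
```

prints:

```
distmult composite_gene-norm WAF 1.000 +/- 0.000 silhouette 0.309
distmult direct_linkpat-gene_geneavg WAF 0.975 +/- 0.051 silhouette 0.063
```

Three synthetic cohorts (42 + 15 + 16 patients, 60/50/40-gene panels sharing
a 30-gene core) carry a planted 3-sigma case/control shift on 10 genes. The
weighted F1 of 1.000 says the gene-normalized composite representation
recovers the planted signal perfectly under 5-fold cross-validation; the
primary-cohort silhouette of 0.309 exceeds the raw-expression baseline
(0.234 on the same patients), i.e. the embedding space separates the classes
better than the original matrix.

The same pipeline is scriptable from the shell:

```bash
patientkg fixtures --outdir ws --seed 1          # synthetic workspace
patientkg build-kg --expression ws/cohort1_expression.tsv \
    --strategy link-geneavg --ontology ws/ontology.tsv \
    --annotations ws/annotations.tsv --ppi ws/ppi.tsv \
    --mapping ws/mapping.tsv --out ws/kg.nt
patientkg embed --kg ws/kg.nt --method distmult --dim 32 --out ws/emb.tsv
patientkg run-all --config config.yaml --out summary.csv
```

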