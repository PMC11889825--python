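# Methods

## Model overview

`patientkg` treats multi-cohort expression integration as a knowledge-graph
representation-learning problem. The KG is a set of (subject, predicate,
object) triples over typed entities — patients, genes, proteins, ontology
classes, bins, and skolemized blank nodes — with no numeric literals:
expression values are carried either by interval (bin) entities or by the
existence of above-average links. Entity embeddings trained on this graph
give every patient, regardless of cohort and gene panel, a vector in one
shared space.

## Expression processing

Cohorts are patients × probes tables. Probes without a gene annotation are
dropped (they cannot connect to the domain knowledge); probes sharing a gene
are summarized by their arithmetic mean (median available via `agg=`), a
standard microarray summarization chosen because it is deterministic and
order-independent. Min-max scaling is applied per gene (column) or per
patient (row); a zero-range column/row maps to all zeros, which keeps
outputs in [0, 1] without NaNs and preserves "the minimum maps to 0".
Missing cells are load errors rather than imputed values: silent imputation
would alter bin boundaries and link thresholds invisibly.

## Graph construction choices

- **Bin count.** The number of bins per (dataset, gene) is
  `max(1, round(f · n_distinct))` with `f` = 0.1 by default; genes with
  richer value sets get finer discretization while graph size stays bounded.
  Edges are equal-width over the observed [min, max]; the last bin is closed
  on the right. Equal width was preferred over quantile edges as the
  simplest rule consistent with "more unique values → more bins"; both the
  fraction and the edge rule are configuration, not science.
- **Blank-node identity.** Blank nodes are skolemized to
  `_:expr/{dataset}/{patient}/{gene}` so that entity identity — and hence
  every embedding — is stable across runs and serialization round trips.
- **Strict thresholds.** A patient-gene link requires the value to *strictly*
  exceed the average; a PPI edge requires combined score *strictly* above
  0.7. Equality never creates an edge.
- **PPI canonicalization.** Interaction inputs typically list both
  directions; each unordered pair is stored once in lexicographic order so
  that no edge is double-weighted.
- **Bin scoping.** Bin entities are shared across patients within one
  (dataset, gene) scope but never across genes or datasets, because the
  discretization is defined per gene within a dataset.

## Embedding models

The five triple scorers and their losses are implemented directly in numpy
with hand-derived analytic gradients (verified against central finite
differences in the test suite):

- TransE / TransR minimize the margin ranking loss
  `mean(max(0, γ + d(pos) − d(neg)))` with `d = ‖·‖₂`, one corrupted entity
  per positive, and entity vectors renormalized to unit L2 norm at the start
  of each epoch (the standard translational-model constraint; without it the
  loss can be driven down by inflating norms).
- DistMult / ComplEx / HolE minimize the softplus loss
  `mean(log(1 + exp(−y·s)))` over positives (y = +1) and corruptions
  (y = −1), with an optional L2 penalty `λ·(mean h² + mean r² + mean t²)/3`
  on the parameters touched by the positive batch.
- The `λ` listed for TransR is applied through the same L2 mechanism as for
  the semantic-matching models; margin and penalty coexist in its loss.
- HolE's circular correlation is computed by FFT
  (`(h ⋆ t) = F⁻¹(conj(F h) · F t)`); the O(d²) definition is retained in
  the tests as the independent route.

Negative sampling replaces head or tail uniformly, or — when the Bernoulli
flag is set — with probability `tph/(tph+hpt)` of corrupting the head, where
`tph`/`hpt` are the relation's average tails-per-head and heads-per-tail.
Corruptions that reconstruct a true triple are resampled up to 100 times,
then accepted; the cap prevents livelock on dense toy graphs. Relations are
never corrupted at the default relation negative rate of 0.

Default hyperparameters per method (embedding size 100, 500 epochs, 100
minibatches, entity negative rate 1): learning rate 0.5 (ComplEx, DistMult,
Adagrad), 0.1 (HolE, Adagrad), 0.001 (TransE, TransR, SGD); λ = 0.05
(ComplEx, DistMult) and 4 (TransR); margin 1 (TransE, TransR); Bernoulli
corruption for ComplEx and DistMult only.

The walk-based method generates, per entity, up to 100 random walks of at
most 4 entity hops over *outgoing* triples, emitting alternating
entity/relation tokens; when exhaustive enumeration yields no more walks
than the cap, the unique complete walks are used instead of sampling. The
corpus feeds a skip-gram model with negative sampling written in numpy
(window 5, 5 negatives from the unigram^0.75 distribution, linearly decaying
learning rate from 0.025), single-threaded and therefore bit-reproducible
under a fixed seed. Entities that never appear in the corpus (possible only
for entities unreachable by any walk start, which does not occur with
per-entity starts) would receive a seeded random vector and a log warning.

## Patient representations

Direct strategies read the patient entity's vector straight from the table —
a pure lookup. Composite strategies compute
`row_p = Σ_g w_pg e_g / Σ_g w_pg` with non-negative expression weights;
rows therefore lie in the convex hull of the gene vectors and are invariant
to rescaling a patient's weights. A patient with all-zero usable weights
receives the zero vector (with a warning) so cohort matrices stay
rectangular. Gene embeddings for the composite strategies come from the
merged link-strategy graph with gene-average thresholds by default; this is
configurable because the composite approach is independent of the KG
construction strategy, and no canonical choice exists.

## Evaluation

Stratified k-fold (k = 5) splits are computed once per study and reused for
every method and strategy, so comparisons share folds. Per fold, a
feed-forward classifier — one hidden layer of 100 rectified units, adaptive
moment estimation, at most 500 iterations, fixed seed — is fit on the
primary-cohort training split pooled with *all* auxiliary-cohort patients;
auxiliary patients never enter a test split. Reported metrics are accuracy,
precision, recall and F1 of the case class, and the support-weighted mean of
per-class F1 scores. Clustering quality (Calinski-Harabasz, Davies-Bouldin,
silhouette; Euclidean throughout) is computed over the original embedding
vectors, both pooled across cohorts and on the primary cohort alone — the
primary-only variant is the like-for-like comparison against the raw
expression matrix, since pooled raw expression does not exist for
incompatible panels.

## Synthetic data

The generator emulates the *structure* of multi-cohort case/control
expression studies: a primary cohort of 20 + 22 patients plus two auxiliary
cohorts (3 + 12 and 8 + 8), gene panels of 60/50/40 sharing a 30-gene core,
binary labels, a 30-class ontology DAG with three roots (one per function
domain), annotations at density 0.3, and interaction edges appearing with
probability 0.05 carrying uniform [0, 1] combined scores. Expression values
are Normal(5, σ) truncated at zero, with the 10 signal genes shifted by the
effect size (default 3σ, σ = 1) in case patients. Acyclicity of the ontology
is guaranteed by construction: classes are ordered and each non-root picks
one or two parents among strictly earlier classes. All randomness derives
from one master seed through per-component seed sequences, so fixtures are
bit-identical across runs and platforms.

What the generator does *not* emulate: microarray noise physics, platform
and batch effects, correlated gene modules, label noise, class-imbalance
pathologies, or realistic ontology topologies. Passing tests therefore
demonstrate that the machinery recovers a known signal under clean
conditions and stays at chance under the null — not that any particular
performance level transfers to real cohorts.

## Scale profiles and numerical choices

Studies on the synthetic workspaces run at a reduced profile (embedding
size 32, 60 epochs, 20 minibatches, 20 walks per entity, 3 skip-gram
epochs), which the recovery experiments show is sufficient for clean planted
signals; the full-scale defaults above remain available per call. Distances
at exactly zero are guarded (gradient of ‖·‖ taken as 0); softplus and
sigmoid use numerically stable forms; Adagrad uses ε = 1e-8. Degenerate
inputs fail loudly: empty graphs, single-entity corruption, single-cluster
scoring, sub-k classes in stratification, and missing patient embeddings
all raise with the offending name.

## Known limitations

- Minibatch SGD over dense gradient arrays is economical only up to graphs
  of a few thousand entities; large real KGs would need sparse updates.
- The skip-gram trainer is a faithful but plain implementation (no
  subsampling of frequent tokens, fixed context window); it is the
  reproducibility-first choice, not the fastest one.
- Absolute performance on real cohort collections depends on data outside
  this package's scope; the pipeline's claims are the property-based ones
  exercised by the test suite.
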