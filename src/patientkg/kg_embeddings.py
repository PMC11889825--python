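"""Knowledge-graph embedding methods.

Six methods are provided. Five are triple-scoring models trained by negative
sampling with analytic gradients:

* **TransE** — relations as translations, score ``-||h + r - t||_2``;
* **TransR** — translations in a relation-specific projected space,
  ``-||M_r h + r - M_r t||_2``;
* **DistMult** — trilinear product ``sum_i h_i r_i t_i``;
* **ComplEx** — complex-valued trilinear product ``Re(sum_i h_i r_i conj(t_i))``
  (each complex vector stored as 2*dim reals: real parts then imaginary);
* **HolE** — circular correlation, ``r . (h * t)`` with
  ``(h * t)_k = sum_i h_i t_{(i+k) mod d}``.

Translational models use margin-based ranking loss with per-epoch unit-norm
entity renormalization; semantic-matching models use softplus (logistic)
loss with an optional L2 penalty. Optimizers are plain SGD or Adagrad.

The sixth method is walk-based: uniform random walks over outgoing triples
produce token sequences (alternating entities and relations) that feed a
skip-gram model with negative sampling, trained here directly in numpy.

All training is seed-reproducible at a fixed thread count.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from patientkg.kg_builder import KnowledgeGraph, Triple

__all__ = [
    "Hyperparameters",
    "WalkConfig",
    "EmbeddingTable",
    "METHODS",
    "method_defaults",
    "score_triple",
    "batch_loss_grad",
    "negative_sample",
    "train_scoring_model",
    "generate_walks",
    "train_walk_embeddings",
    "train_embeddings",
]

logger = logging.getLogger(__name__)

SCORING_METHODS = ("transe", "transr", "distmult", "hole", "complex")
METHODS = ("rdf2vec",) + SCORING_METHODS
TRANSLATIONAL = {"transe", "transr"}

# Per-method defaults: (learning_rate, lambda_reg, margin, bern, optimizer)
_METHOD_DEFAULTS = {
    "complex": (0.5, 0.05, None, True, "adagrad"),
    "distmult": (0.5, 0.05, None, True, "adagrad"),
    "hole": (0.1, None, None, False, "adagrad"),
    "transe": (0.001, None, 1.0, False, "sgd"),
    "transr": (0.001, 4.0, 1.0, False, "sgd"),
}


@dataclass(frozen=True)
class Hyperparameters:
    """Training knobs for the triple-scoring models.

    Defaults follow the conventional full-scale configuration (embedding
    size 100, 500 epochs, 100 minibatches, one corrupted entity per positive,
    no relation corruption); :func:`method_defaults` fills the per-method
    learning rate, regularization weight, margin, Bernoulli-corruption flag
    and optimizer.
    """

    dim: int = 100
    epochs: int = 500
    n_batches: int = 100
    learning_rate: float = 0.01
    lambda_reg: Optional[float] = None
    margin: Optional[float] = None
    entity_neg_rate: int = 1
    relation_neg_rate: int = 0
    bern: bool = False
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.epochs < 0 or self.n_batches <= 0:
            raise ValueError("dim/epochs/n_batches out of range")
        if self.entity_neg_rate < 0 or self.relation_neg_rate < 0:
            raise ValueError("negative rates must be >= 0")
        if self.optimizer not in {"sgd", "adagrad"}:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def method_defaults(method: str, **overrides) -> Hyperparameters:
    """Hyperparameters with the per-method defaults filled in."""
    if method not in SCORING_METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    lr, lam, margin, bern, opt = _METHOD_DEFAULTS[method]
    base = dict(learning_rate=lr, lambda_reg=lam, margin=margin, bern=bern,
                optimizer=opt)
    base.update(overrides)
    return Hyperparameters(**base)


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk and skip-gram settings for the walk-based method."""

    depth: int = 4
    max_walks_per_entity: int = 100
    window: int = 5
    sg_epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.max_walks_per_entity < 1:
            raise ValueError("depth and max_walks_per_entity must be >= 1")


@dataclass
class EmbeddingTable:
    """Learned vectors for entities and (for scoring models) relations."""

    method: str
    dim: int
    entity_vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    relation_projections: dict[str, np.ndarray] = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)
    seed: int = 0

    def vector(self, entity: str) -> np.ndarray:
        try:
            return self.entity_vectors[entity]
        except KeyError:
            raise KeyError(f"no embedding for entity {entity!r}") from None

    def score(self, h: str, r: str, t: str) -> float:
        proj = self.relation_projections.get(r)
        return score_triple(
            self.method, self.entity_vectors[h], self.relation_vectors[r],
            self.entity_vectors[t], proj=proj,
        )

    def matrix(self, entities: Sequence[str]) -> np.ndarray:
        return np.stack([self.vector(e) for e in entities])


# ---------------------------------------------------------------------------
# scoring functions
# ---------------------------------------------------------------------------

def _ccorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular correlation along the last axis via FFT."""
    d = a.shape[-1]
    return np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=d)


def _cconv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular convolution along the last axis via FFT."""
    d = a.shape[-1]
    return np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=d)


def score_triple(
    method: str,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    proj: Optional[np.ndarray] = None,
) -> float:
    """Plausibility score of one triple; higher is more plausible.

    For ComplEx, ``h``/``r``/``t`` carry 2*dim reals (real halves first).
    For TransR, ``proj`` is the relation's d x d projection matrix.
    """
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if method == "transe":
        if not (h.shape == r.shape == t.shape):
            raise ValueError("dimension mismatch")
        return float(-np.linalg.norm(h + r - t))
    if method == "transr":
        if proj is None:
            raise ValueError("TransR requires a projection matrix")
        if proj.shape != (r.shape[0], h.shape[0]):
            raise ValueError("dimension mismatch")
        return float(-np.linalg.norm(proj @ h + r - proj @ t))
    if method == "distmult":
        if not (h.shape == r.shape == t.shape):
            raise ValueError("dimension mismatch")
        return float(np.sum(h * r * t))
    if method == "complex":
        if not (h.shape == r.shape == t.shape) or h.shape[0] % 2:
            raise ValueError("dimension mismatch")
        d = h.shape[0] // 2
        hr, hi = h[:d], h[d:]
        rr, ri = r[:d], r[d:]
        tr, ti = t[:d], t[d:]
        return float(np.sum(hr * rr * tr + hi * rr * ti + hr * ri * ti - hi * ri * tr))
    if method == "hole":
        if not (h.shape == r.shape == t.shape):
            raise ValueError("dimension mismatch")
        return float(r @ _ccorr(h, t))
    raise ValueError(f"unknown scoring method {method!r}")


# ---------------------------------------------------------------------------
# batched loss + analytic gradients
# ---------------------------------------------------------------------------

def _batch_scores(method: str, params: Mapping[str, np.ndarray],
                  idx: np.ndarray) -> np.ndarray:
    E, R = params["E"], params["R"]
    h, r, t = E[idx[:, 0]], R[idx[:, 1]], E[idx[:, 2]]
    if method == "transe":
        return -np.linalg.norm(h + r - t, axis=1)
    if method == "transr":
        M = params["M"][idx[:, 1]]
        hp = np.einsum("bij,bj->bi", M, h)
        tp = np.einsum("bij,bj->bi", M, t)
        return -np.linalg.norm(hp + r - tp, axis=1)
    if method == "distmult":
        return np.sum(h * r * t, axis=1)
    if method == "complex":
        d = h.shape[1] // 2
        hr, hi = h[:, :d], h[:, d:]
        rr, ri = r[:, :d], r[:, d:]
        tr, ti = t[:, :d], t[:, d:]
        return np.sum(hr * rr * tr + hi * rr * ti + hr * ri * ti - hi * ri * tr,
                      axis=1)
    if method == "hole":
        return np.sum(r * _ccorr(h, t), axis=1)
    raise ValueError(f"unknown scoring method {method!r}")


def _score_grads(method: str, params: Mapping[str, np.ndarray], idx: np.ndarray):
    """Per-example gradients of the raw score wrt h, r, t (and M for TransR).

    Returns (gh, gr, gt, gM_or_None); for translational models these are the
    gradients of the *distance* ``d = ||.||`` (score = -d), which the caller
    signs appropriately.
    """
    E, R = params["E"], params["R"]
    h, r, t = E[idx[:, 0]], R[idx[:, 1]], E[idx[:, 2]]
    if method == "transe":
        diff = h + r - t
        dist = np.linalg.norm(diff, axis=1, keepdims=True)
        u = diff / np.maximum(dist, 1e-12)
        return u, u, -u, None
    if method == "transr":
        M = params["M"][idx[:, 1]]
        hp = np.einsum("bij,bj->bi", M, h)
        tp = np.einsum("bij,bj->bi", M, t)
        diff = hp + r - tp
        dist = np.linalg.norm(diff, axis=1, keepdims=True)
        u = diff / np.maximum(dist, 1e-12)
        gh = np.einsum("bij,bi->bj", M, u)
        gM = np.einsum("bi,bj->bij", u, h - t)
        return gh, u, -gh, gM
    if method == "distmult":
        return r * t, h * t, h * r, None
    if method == "complex":
        d = h.shape[1] // 2
        hr, hi = h[:, :d], h[:, d:]
        rr, ri = r[:, :d], r[:, d:]
        tr, ti = t[:, :d], t[:, d:]
        gh = np.concatenate([rr * tr + ri * ti, rr * ti - ri * tr], axis=1)
        gr = np.concatenate([hr * tr + hi * ti, hr * ti - hi * tr], axis=1)
        gt = np.concatenate([hr * rr - hi * ri, hi * rr + hr * ri], axis=1)
        return gh, gr, gt, None
    if method == "hole":
        gh = _ccorr(r, t)
        gr = _ccorr(h, t)
        gt = _cconv(r, h)
        return gh, gr, gt, None
    raise ValueError(f"unknown scoring method {method!r}")


def batch_loss_grad(
    method: str,
    params: Mapping[str, np.ndarray],
    pos: np.ndarray,
    neg: np.ndarray,
    hyper: Hyperparameters,
) -> tuple[float, dict[str, np.ndarray]]:
    """Minibatch loss and dense analytic gradients.

    ``pos`` and ``neg`` are integer (B, 3) arrays of (head, relation, tail)
    indices; for margin-ranking models they are aligned positive/negative
    pairs. Gradients come back as arrays shaped like the parameters.
    """
    pos = np.atleast_2d(pos)
    neg = np.atleast_2d(neg)
    E, R = params["E"], params["R"]
    gE = np.zeros_like(E)
    gR = np.zeros_like(R)
    grads = {"E": gE, "R": gR}
    if method == "transr":
        grads["M"] = np.zeros_like(params["M"])

    if method in TRANSLATIONAL:
        if hyper.margin is None:
            raise ValueError("margin required for translational models")
        if len(pos) != len(neg):
            raise ValueError("margin loss needs aligned pos/neg pairs")
        B = len(pos)
        d_pos = -_batch_scores(method, params, pos)
        d_neg = -_batch_scores(method, params, neg)
        viol = hyper.margin + d_pos - d_neg
        active = viol > 0
        loss = float(np.sum(np.maximum(viol, 0.0)) / B)
        w = active.astype(float) / B
        for sign, idx in ((1.0, pos), (-1.0, neg)):
            gh, gr, gt, gM = _score_grads(method, params, idx)
            coef = (sign * w)[:, None]
            np.add.at(gE, idx[:, 0], coef * gh)
            np.add.at(gR, idx[:, 1], coef * gr)
            np.add.at(gE, idx[:, 2], coef * gt)
            if gM is not None:
                np.add.at(grads["M"], idx[:, 1], coef[:, :, None] * gM)
    else:
        examples = np.concatenate([pos, neg], axis=0)
        y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
        N = len(examples)
        s = _batch_scores(method, params, examples)
        # softplus(-y*s), numerically stable
        loss = float(np.mean(np.logaddexp(0.0, -y * s)))
        # d/ds softplus(-y s) = -y * sigmoid(-y s)
        z = -y * s
        sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                       np.exp(z) / (1.0 + np.exp(z)))
        coef = (-y * sig / N)[:, None]
        gh, gr, gt, _ = _score_grads(method, params, examples)
        np.add.at(gE, examples[:, 0], coef * gh)
        np.add.at(gR, examples[:, 1], coef * gr)
        np.add.at(gE, examples[:, 2], coef * gt)

    if hyper.lambda_reg:
        # L2 penalty on the parameters touched by the positive batch:
        # lambda * mean over batch of (mean h^2 + mean r^2 + mean t^2) / 3.
        B = len(pos)
        dE = E.shape[1]
        dR = R.shape[1]
        h, r, t = E[pos[:, 0]], R[pos[:, 1]], E[pos[:, 2]]
        loss += hyper.lambda_reg * float(
            (np.mean(h**2) + np.mean(r**2) + np.mean(t**2)) / 3.0
        )
        ch = 2.0 * hyper.lambda_reg / (3.0 * B * dE)
        cr = 2.0 * hyper.lambda_reg / (3.0 * B * dR)
        np.add.at(gE, pos[:, 0], ch * h)
        np.add.at(gR, pos[:, 1], cr * r)
        np.add.at(gE, pos[:, 2], ch * t)
    return loss, grads


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

class _TripleIndex:
    """Integer-indexed view of a graph for training."""

    def __init__(self, kg: KnowledgeGraph):
        self.entities = sorted(kg.entities)
        self.relations = sorted(kg.relations)
        self.ent_id = {e: i for i, e in enumerate(self.entities)}
        self.rel_id = {r: i for i, r in enumerate(self.relations)}
        trips = kg.sorted_triples()
        self.triples = np.array(
            [(self.ent_id[t.subject], self.rel_id[t.predicate], self.ent_id[t.object])
             for t in trips],
            dtype=np.int64,
        ).reshape(-1, 3)
        self.triple_set = {tuple(t) for t in self.triples.tolist()}
        # Bernoulli corruption statistics: average tails-per-head (tph) and
        # heads-per-tail (hpt) for each relation.
        self.p_head = np.full(len(self.relations), 0.5)
        for ri in range(len(self.relations)):
            mask = self.triples[:, 1] == ri
            sub = self.triples[mask]
            if not len(sub):
                continue
            tph = len(sub) / max(len(np.unique(sub[:, 0])), 1)
            hpt = len(sub) / max(len(np.unique(sub[:, 2])), 1)
            self.p_head[ri] = tph / (tph + hpt)


def negative_sample(
    triple: tuple[int, int, int],
    index: _TripleIndex,
    bern: bool,
    rng: np.random.Generator,
    max_retries: int = 100,
    corrupt_relation: bool = False,
) -> tuple[int, int, int]:
    """Corrupt one triple by replacing its head or tail (or relation).

    Head-vs-tail choice is uniform, or Bernoulli-weighted by per-relation
    tail/head cardinality ratios when ``bern``. Resampling avoids corruptions
    that are themselves true triples, up to ``max_retries`` attempts (dense
    toy graphs may exhaust this; the last draw is then accepted).
    """
    h, r, t = triple
    n_ent = len(index.entities)
    if n_ent < 2:
        raise ValueError("cannot corrupt a graph with fewer than two entities")
    if corrupt_relation:
        if len(index.relations) < 2:
            raise ValueError("cannot corrupt the relation: only one relation")
        for _ in range(max_retries):
            r2 = int(rng.integers(len(index.relations)))
            if r2 != r and (h, r2, t) not in index.triple_set:
                return (h, r2, t)
        return (h, r2, t)
    p_head = index.p_head[r] if bern else 0.5
    replace_head = rng.random() < p_head
    cand = triple
    for _ in range(max_retries):
        e = int(rng.integers(n_ent))
        cand = (e, r, t) if replace_head else (h, r, e)
        if cand != triple and cand not in index.triple_set:
            return cand
    return cand


# ---------------------------------------------------------------------------
# training loop for the scoring models
# ---------------------------------------------------------------------------

def _init_params(method: str, n_ent: int, n_rel: int, dim: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    width = dim * (2 if method == "complex" else 1)
    bound = 6.0 / np.sqrt(dim)
    params = {
        "E": rng.uniform(-bound, bound, size=(n_ent, width)),
        "R": rng.uniform(-bound, bound, size=(n_rel, width)),
    }
    if method == "transr":
        params["M"] = np.tile(np.eye(dim), (n_rel, 1, 1))
    return params


def train_scoring_model(
    kg: KnowledgeGraph,
    method: str,
    hyper: Optional[Hyperparameters] = None,
) -> EmbeddingTable:
    """Train one triple-scoring model on the graph by negative sampling.

    Each epoch shuffles the triples into ``n_batches`` minibatches; every
    positive gets ``entity_neg_rate`` entity corruptions (and
    ``relation_neg_rate`` relation corruptions). Translational models
    renormalize entity vectors to unit L2 norm at the start of each epoch.
    Raises if the loss goes non-finite, naming the epoch.
    """
    if method not in SCORING_METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    if not len(kg):
        raise ValueError("cannot train on an empty graph")
    hyper = hyper if hyper is not None else method_defaults(method)
    index = _TripleIndex(kg)
    rng = np.random.default_rng(hyper.seed)
    params = _init_params(method, len(index.entities), len(index.relations),
                          hyper.dim, rng)
    state = {k: np.zeros_like(v) for k, v in params.items()}  # adagrad accum
    n_triples = len(index.triples)
    n_batches = min(hyper.n_batches, n_triples)
    history: list[float] = []

    for epoch in range(hyper.epochs):
        if method in TRANSLATIONAL:
            norms = np.linalg.norm(params["E"], axis=1, keepdims=True)
            params["E"] /= np.maximum(norms, 1e-12)
        order = rng.permutation(n_triples)
        epoch_loss = 0.0
        for batch_ids in np.array_split(order, n_batches):
            if not len(batch_ids):
                continue
            pos = index.triples[batch_ids]
            reps = []
            for row in pos:
                trip = tuple(int(x) for x in row)
                for _ in range(hyper.entity_neg_rate):
                    reps.append(negative_sample(trip, index, hyper.bern, rng))
                for _ in range(hyper.relation_neg_rate):
                    reps.append(
                        negative_sample(trip, index, hyper.bern, rng,
                                        corrupt_relation=True)
                    )
            neg = np.array(reps, dtype=np.int64).reshape(-1, 3)
            pos_rep = np.repeat(
                pos, hyper.entity_neg_rate + hyper.relation_neg_rate, axis=0
            ) if method in TRANSLATIONAL else pos
            loss, grads = batch_loss_grad(method, params, pos_rep, neg, hyper)
            epoch_loss += loss
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            for key, g in grads.items():
                if hyper.optimizer == "adagrad":
                    state[key] += g * g
                    params[key] -= hyper.learning_rate * g / (
                        np.sqrt(state[key]) + 1e-8
                    )
                else:
                    params[key] -= hyper.learning_rate * g
        history.append(epoch_loss / n_batches)

    entity_vectors = {e: params["E"][i].copy() for i, e in enumerate(index.entities)}
    relation_vectors = {r: params["R"][i].copy() for i, r in enumerate(index.relations)}
    projections = {}
    if method == "transr":
        projections = {r: params["M"][i].copy() for i, r in enumerate(index.relations)}
    return EmbeddingTable(
        method=method,
        dim=hyper.dim,
        entity_vectors=entity_vectors,
        relation_vectors=relation_vectors,
        relation_projections=projections,
        loss_history=history,
        seed=hyper.seed,
    )


# ---------------------------------------------------------------------------
# random walks + skip-gram
# ---------------------------------------------------------------------------

def generate_walks(kg: KnowledgeGraph, config: WalkConfig) -> list[list[str]]:
    """Random walks over outgoing triples, one batch per entity.

    Walks alternate entity and relation tokens and make at most
    ``config.depth`` entity hops. When exhaustive enumeration of an entity's
    complete walks is no larger than ``max_walks_per_entity`` the unique
    walks are emitted; otherwise that many uniform random walks are sampled.
    An entity with no outgoing edge yields the singleton walk ``[entity]``.
    """
    adj: dict[str, list[tuple[str, str]]] = {}
    for t in kg.sorted_triples():
        adj.setdefault(t.subject, []).append((t.predicate, t.object))
    rng = np.random.default_rng(config.seed)
    corpus: list[list[str]] = []
    cap = config.max_walks_per_entity
    for entity in sorted(kg.entities):
        exhaustive = _enumerate_walks(entity, adj, config.depth, cap)
        if exhaustive is not None:
            corpus.extend(exhaustive)
            continue
        seen: list[list[str]] = []
        for _ in range(cap):
            walk = [entity]
            node = entity
            for _hop in range(config.depth):
                edges = adj.get(node)
                if not edges:
                    break
                pred, obj = edges[int(rng.integers(len(edges)))]
                walk.extend([pred, obj])
                node = obj
            seen.append(walk)
        corpus.extend(seen)
    return corpus


def _enumerate_walks(
    entity: str,
    adj: Mapping[str, list[tuple[str, str]]],
    depth: int,
    cap: int,
) -> Optional[list[list[str]]]:
    """All complete walks from ``entity``, or None if more than ``cap``.

    A walk is complete when it reaches ``depth`` entity hops or a node with
    no outgoing edges.
    """
    done: list[list[str]] = []
    stack: list[tuple[list[str], int]] = [([entity], 0)]
    while stack:
        walk, hops = stack.pop()
        edges = adj.get(walk[-1])
        if hops == depth or not edges:
            done.append(walk)
            if len(done) > cap:
                return None
            continue
        for pred, obj in reversed(edges):
            stack.append((walk + [pred, obj], hops + 1))
            if len(stack) + len(done) > 4 * cap + 16:
                return None  # give up early on bushy nodes
    return done


def train_walk_embeddings(
    corpus: Sequence[Sequence[str]],
    dim: int = 100,
    config: Optional[WalkConfig] = None,
    entities: Optional[Iterable[str]] = None,
) -> EmbeddingTable:
    """Skip-gram with negative sampling over walk tokens.

    Negative tokens are drawn from the unigram distribution raised to 3/4.
    The learning rate decays linearly across all center-word updates. Tokens
    in ``entities`` absent from the corpus still receive a seeded random
    vector (logged), so every graph entity ends up with an embedding.
    """
    if config is None:
        config = WalkConfig()
    if not corpus:
        raise ValueError("empty walk corpus")
    vocab: dict[str, int] = {}
    counts: list[int] = []
    sentences: list[np.ndarray] = []
    for walk in corpus:
        ids = []
        for tok in walk:
            if tok not in vocab:
                vocab[tok] = len(vocab)
                counts.append(0)
            counts[vocab[tok]] += 1
            ids.append(vocab[tok])
        sentences.append(np.array(ids, dtype=np.int64))
    V = len(vocab)
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim))  # input vectors
    C = np.zeros((V, dim))  # output vectors

    freq = np.array(counts, dtype=float) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    total_centers = sum(len(s) for s in sentences) * max(config.sg_epochs, 1)
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    step = 0
    k = config.negative
    for _epoch in range(config.sg_epochs):
        for sent in sentences:
            n = len(sent)
            for pos in range(n):
                lr = max(lr_min, lr0 * (1.0 - step / total_centers))
                step += 1
                center = sent[pos]
                lo = max(0, pos - config.window)
                hi = min(n, pos + config.window + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1:hi]])
                if not len(ctx):
                    continue
                negs = np.searchsorted(noise_cdf, rng.random((len(ctx), k)))
                v = W[center]
                for j, c in enumerate(ctx):
                    outs = np.concatenate([[c], negs[j]])
                    labels = np.zeros(k + 1)
                    labels[0] = 1.0
                    u = C[outs]
                    z = u @ v
                    p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
                    g = (labels - p) * lr
                    dv = g @ u
                    C[outs] += np.outer(g, v)
                    v = v + dv
                W[center] = v

    entity_vectors = {}
    for tok, i in vocab.items():
        entity_vectors[tok] = W[i].copy()
    if entities is not None:
        for e in entities:
            if e not in entity_vectors:
                logger.warning("entity %s absent from walk corpus; "
                               "assigning seeded random vector", e)
                sub = np.random.default_rng(
                    (config.seed + zlib.crc32(e.encode())) % (2**31)
                )
                entity_vectors[e] = sub.uniform(-0.5 / dim, 0.5 / dim, size=dim)
    return EmbeddingTable(
        method="rdf2vec", dim=dim, entity_vectors=entity_vectors,
        seed=config.seed,
    )


def train_embeddings(
    kg: KnowledgeGraph,
    method: str,
    dim: int = 100,
    seed: int = 0,
    hyper: Optional[Hyperparameters] = None,
    walk_config: Optional[WalkConfig] = None,
) -> EmbeddingTable:
    """Uniform front door: train any of the six methods on a graph."""
    if method == "rdf2vec":
        cfg = walk_config if walk_config is not None else WalkConfig(seed=seed)
        if cfg.seed != seed:
            cfg = replace(cfg, seed=seed)
        corpus = generate_walks(kg, cfg)
        return train_walk_embeddings(corpus, dim=dim, config=cfg,
                                     entities=kg.entities)
    hp = hyper if hyper is not None else method_defaults(method, dim=dim, seed=seed)
    if (hp.dim, hp.seed) != (dim, seed):
        hp = replace(hp, dim=dim, seed=seed)
    return train_scoring_model(kg, method, hp)


def write_embedding_table(table: EmbeddingTable, path) -> None:
    """TSV of (entity, v1..vd) with a small metadata header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={table.method} dim={table.dim} seed={table.seed}\n")
        for ent in sorted(table.entity_vectors):
            vec = "\t".join(f"{v:.8g}" for v in table.entity_vectors[ent])
            fh.write(f"{ent}\t{vec}\n")
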