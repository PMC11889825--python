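import math

import numpy as np
import pytest

from patientkg.kg_builder import KnowledgeGraph, Triple
from patientkg.kg_embeddings import (
    Hyperparameters,
    WalkConfig,
    _TripleIndex,
    batch_loss_grad,
    generate_walks,
    method_defaults,
    negative_sample,
    score_triple,
    train_scoring_model,
    train_walk_embeddings,
)

from oracles import SCORE_ORACLES as ORACLES
from oracles import hole_oracle, transr_oracle


class TestScoreOracles:
    @pytest.mark.parametrize("method", ["transe", "distmult", "complex", "hole"])
    def test_vector_methods_match_brute_force(self, method):
        rng = np.random.default_rng(42)
        width = 10 if method == "complex" else 5
        for _ in range(200):
            h, r, t = rng.normal(size=(3, width))
            expected = ORACLES[method](list(h), list(r), list(t))
            assert score_triple(method, h, r, t) == pytest.approx(
                expected, abs=1e-9
            )

    def test_transr_matches_brute_force(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            h, r, t = rng.normal(size=(3, 5))
            M = rng.normal(size=(5, 5))
            expected = transr_oracle(M.tolist(), list(h), list(r), list(t))
            assert score_triple("transr", h, r, t, proj=M) == pytest.approx(
                expected, abs=1e-9
            )

    def test_transe_perfect_translation_scores_zero(self):
        h = np.array([0.3, -0.2])
        r = np.array([1.0, 0.5])
        assert score_triple("transe", h, r, h + r) == pytest.approx(0.0)

    def test_transe_hand_example(self):
        s = score_triple("transe", np.array([1.0, 0]), np.array([0, 1.0]),
                         np.array([0.0, 0]))
        assert s == pytest.approx(-math.sqrt(2))

    def test_distmult_symmetric_in_head_and_tail(self):
        rng = np.random.default_rng(1)
        h, r, t = rng.normal(size=(3, 5))
        assert score_triple("distmult", h, r, t) == pytest.approx(
            score_triple("distmult", t, r, h)
        )

    def test_hole_hand_example(self):
        s = score_triple("hole", np.array([1.0, 0]), np.array([1.0, 0]),
                         np.array([0.0, 1]))
        # (h * t) = [0, 1], dot with r = [1, 0] -> 0
        assert s == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("d", range(2, 9))
    def test_hole_fft_equals_quadratic_definition(self, d):
        rng = np.random.default_rng(d)
        h, r, t = rng.normal(size=(3, d))
        assert score_triple("hole", h, r, t) == pytest.approx(
            hole_oracle(list(h), list(r), list(t)), abs=1e-9
        )

    def test_dimension_mismatch_is_error(self):
        with pytest.raises(ValueError):
            score_triple("transe", np.ones(3), np.ones(4), np.ones(3))


# ---------------------------------------------------------------------------
# gradient checks: analytic vs central finite differences
# ---------------------------------------------------------------------------

def _random_instance(method, rng, n_ent=6, n_rel=2, dim=3, batch=4):
    width = 2 * dim if method == "complex" else dim
    params = {
        "E": rng.normal(size=(n_ent, width)),
        "R": rng.normal(size=(n_rel, width)),
    }
    if method == "transr":
        params["M"] = rng.normal(size=(n_rel, dim, dim))
    pos = np.stack([
        rng.integers(n_ent, size=batch),
        rng.integers(n_rel, size=batch),
        rng.integers(n_ent, size=batch),
    ], axis=1)
    neg = pos.copy()
    neg[:, 0] = rng.integers(n_ent, size=batch)  # corrupt heads
    return params, pos, neg


@pytest.mark.parametrize("method", ["transe", "transr", "distmult", "complex", "hole"])
def test_analytic_gradients_match_finite_differences(method):
    rng = np.random.default_rng(2024)
    hyper = method_defaults(method, dim=3, epochs=1, n_batches=1, seed=0)
    params, pos, neg = _random_instance(method, rng)
    _, grads = batch_loss_grad(method, params, pos, neg, hyper)
    eps = 1e-6
    for key in params:
        flat = params[key].ravel()
        # probe every coordinate of these small instances
        for idx in range(flat.size):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = batch_loss_grad(method, params, pos, neg, hyper)
            flat[idx] = orig - eps
            lm, _ = batch_loss_grad(method, params, pos, neg, hyper)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[key].ravel()[idx]
            assert analytic == pytest.approx(numeric, abs=1e-4), (
                f"{method} d{key}[{idx}]: {analytic} vs {numeric}"
            )


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

class TestNegativeSampling:
    def test_corruption_changes_exactly_one_slot(self, toy_train_graph):
        index = _TripleIndex(toy_train_graph)
        rng = np.random.default_rng(0)
        for row in index.triples[:10]:
            trip = tuple(int(x) for x in row)
            corr = negative_sample(trip, index, bern=False, rng=rng)
            diffs = sum(a != b for a, b in zip(trip, corr))
            assert diffs == 1
            assert corr[1] == trip[1]  # relation untouched

    def test_relation_corruption_only_when_requested(self, toy_train_graph):
        index = _TripleIndex(toy_train_graph)
        rng = np.random.default_rng(0)
        trip = tuple(int(x) for x in index.triples[0])
        corr = negative_sample(trip, index, False, rng, corrupt_relation=True)
        assert corr[0] == trip[0] and corr[2] == trip[2]
        assert corr[1] != trip[1]

    def test_seeded_rng_reproducible(self, toy_train_graph):
        index = _TripleIndex(toy_train_graph)
        trip = tuple(int(x) for x in index.triples[0])
        seq1 = [negative_sample(trip, index, True, np.random.default_rng(5))
                for _ in range(5)]
        seq2 = [negative_sample(trip, index, True, np.random.default_rng(5))
                for _ in range(5)]
        assert seq1 == seq2

    def test_single_entity_graph_is_error(self):
        kg = KnowledgeGraph()
        kg.add(":a", ":r", ":a")
        index = _TripleIndex(kg)
        with pytest.raises(ValueError):
            negative_sample((0, 0, 0), index, False, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TestScoringModelTraining:
    @pytest.mark.parametrize("method", ["transe", "distmult", "complex"])
    def test_loss_decreases_on_toy_graph(self, toy_train_graph, method):
        # toy-scale schedule for the translational model; the margin loss
        # with per-epoch renormalization moves slowly under plain SGD
        overrides = dict(epochs=50)
        if method == "transe":
            overrides = dict(epochs=300, learning_rate=0.1)
        hyper = method_defaults(method, dim=8, n_batches=4, seed=3, **overrides)
        table = train_scoring_model(toy_train_graph, method, hyper)
        assert table.loss_history[-1] < table.loss_history[0]

    def test_true_triples_outscore_corruptions(self, toy_train_graph):
        hyper = method_defaults("distmult", dim=8, epochs=120, n_batches=4, seed=3)
        table = train_scoring_model(toy_train_graph, "distmult", hyper)
        rng = np.random.default_rng(0)
        ents = sorted(toy_train_graph.entities)
        true_scores, fake_scores = [], []
        for t in toy_train_graph.sorted_triples():
            true_scores.append(table.score(t.subject, t.predicate, t.object))
            fake = ents[int(rng.integers(len(ents)))]
            if Triple(t.subject, t.predicate, fake) not in toy_train_graph:
                fake_scores.append(table.score(t.subject, t.predicate, fake))
        assert np.mean(true_scores) > np.mean(fake_scores)

    def test_zero_epochs_returns_seeded_initialization(self, toy_train_graph):
        hyper = method_defaults("transe", dim=4, epochs=0, seed=9)
        a = train_scoring_model(toy_train_graph, "transe", hyper)
        b = train_scoring_model(toy_train_graph, "transe", hyper)
        for ent in a.entity_vectors:
            np.testing.assert_array_equal(
                a.entity_vectors[ent], b.entity_vectors[ent]
            )
        assert a.loss_history == []

    def test_training_bitwise_reproducible(self, toy_train_graph):
        hyper = method_defaults("complex", dim=4, epochs=10, n_batches=4, seed=21)
        a = train_scoring_model(toy_train_graph, "complex", hyper)
        b = train_scoring_model(toy_train_graph, "complex", hyper)
        assert a.loss_history == b.loss_history
        for ent in a.entity_vectors:
            np.testing.assert_array_equal(
                a.entity_vectors[ent], b.entity_vectors[ent]
            )

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            train_scoring_model(KnowledgeGraph(), "transe")


# ---------------------------------------------------------------------------
# random walks and skip-gram
# ---------------------------------------------------------------------------

class TestWalks:
    def test_isolated_entity_singleton_walk(self):
        kg = KnowledgeGraph()
        kg.add(":a", ":r", ":b")
        walks = generate_walks(kg, WalkConfig(seed=0))
        assert [":b"] in walks  # b has no out-edges

    def test_chain_exhaustive_enumeration(self, chain_graph):
        walks = generate_walks(chain_graph, WalkConfig(depth=4, seed=0))
        from_a = [w for w in walks if w[0] == ":e/a"]
        assert from_a == [
            [":e/a", ":r", ":e/b", ":r", ":e/c", ":r", ":e/d", ":r", ":e/e"]
        ]

    def test_every_walk_is_a_graph_path(self, toy_train_graph):
        walks = generate_walks(
            toy_train_graph, WalkConfig(depth=4, max_walks_per_entity=10, seed=1)
        )
        for walk in walks:
            assert (len(walk) - 1) % 2 == 0
            hops = (len(walk) - 1) // 2
            assert hops <= 4
            for i in range(0, len(walk) - 2, 2):
                assert Triple(walk[i], walk[i + 1], walk[i + 2]) in toy_train_graph

    def test_walk_count_capped_per_entity(self, toy_train_graph):
        cap = 10
        walks = generate_walks(
            toy_train_graph, WalkConfig(depth=4, max_walks_per_entity=cap, seed=1)
        )
        starts = {}
        for w in walks:
            starts[w[0]] = starts.get(w[0], 0) + 1
        assert max(starts.values()) <= cap


class TestSkipGram:
    def test_output_dimension(self, chain_graph):
        walks = generate_walks(chain_graph, WalkConfig(seed=0))
        table = train_walk_embeddings(walks, dim=16, config=WalkConfig(seed=0))
        assert all(v.shape == (16,) for v in table.entity_vectors.values())

    def test_automorphic_twins_more_similar_than_unrelated(self):
        # star: center -> leaves; all leaves share identical walk contexts
        kg = KnowledgeGraph()
        for i in range(4):
            kg.add(":hub", ":r", f":leaf{i}")
        walks = generate_walks(kg, WalkConfig(depth=2, seed=0))
        cfg = WalkConfig(seed=0, sg_epochs=40, window=3)
        table = train_walk_embeddings(walks * 50, dim=8, config=cfg)

        def cos(a, b):
            va, vb = table.entity_vectors[a], table.entity_vectors[b]
            return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

        twin = np.mean([cos(f":leaf{i}", f":leaf{j}")
                        for i in range(4) for j in range(i + 1, 4)])
        unrelated = np.mean([cos(":hub", f":leaf{i}") for i in range(4)])
        assert twin > unrelated

    def test_absent_entity_gets_finite_seeded_vector(self, chain_graph):
        walks = generate_walks(chain_graph, WalkConfig(seed=0))
        table = train_walk_embeddings(
            walks, dim=8, config=WalkConfig(seed=0),
            entities=list(chain_graph.entities) + [":ghost"],
        )
        assert np.all(np.isfinite(table.entity_vectors[":ghost"]))

    def test_reproducible_under_fixed_seed(self, chain_graph):
        walks = generate_walks(chain_graph, WalkConfig(seed=3))
        a = train_walk_embeddings(walks, dim=8, config=WalkConfig(seed=3))
        b = train_walk_embeddings(walks, dim=8, config=WalkConfig(seed=3))
        for ent in a.entity_vectors:
            np.testing.assert_array_equal(
                a.entity_vectors[ent], b.entity_vectors[ent]
            )

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            train_walk_embeddings([], dim=4)
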