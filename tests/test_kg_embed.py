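from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from kgclf.kg_embed import (
    EmbeddingTable,
    SkipGramConfig,
    WalkConfig,
    _batch_gradient,
    _walk_pairs,
    context_distribution,
    embed_graph,
    generate_walks,
    log_prob_and_grad,
    skipgram_objective,
    train_skipgram,
)


def two_cliques(k=6):
    adj = {}
    c1, c2 = list(range(k)), list(range(k, 2 * k))
    for grp in (c1, c2):
        for a in grp:
            adj[a] = sorted(set(grp) - {a})
    adj[k - 1] = sorted(adj[k - 1] + [k])
    adj[k] = sorted(adj[k] + [k - 1])
    return adj, c1, c2


class TestWalkConfig:
    def test_defaults(self):
        cfg = WalkConfig()
        assert cfg.walk_length == 20
        assert cfg.walks_per_node == 10

    @pytest.mark.parametrize("kwargs", [{"walk_length": 0}, {"walks_per_node": 0}])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            WalkConfig(**kwargs)


class TestWalks:
    def test_empty_graph(self):
        assert generate_walks({}, WalkConfig()) == []

    def test_isolated_node_truncates(self):
        walks = generate_walks({7: []}, WalkConfig(walk_length=20, walks_per_node=3))
        assert walks == [[7], [7], [7]]

    def test_single_choice_chain(self):
        adj = {0: [1], 1: [2], 2: []}
        walks = generate_walks(adj, WalkConfig(walk_length=3, walks_per_node=1))
        assert walks[0] == [0, 1, 2]

    def test_walks_start_at_their_node_with_r_per_node(self):
        adj, *_ = two_cliques()
        cfg = WalkConfig(walk_length=5, walks_per_node=4, seed=1)
        walks = generate_walks(adj, cfg)
        assert len(walks) == 4 * len(adj)
        for i, start in enumerate(sorted(adj)):
            for r in range(4):
                assert walks[i * 4 + r][0] == start

    def test_deterministic(self):
        adj, *_ = two_cliques()
        cfg = WalkConfig(seed=9)
        assert generate_walks(adj, cfg) == generate_walks(adj, cfg)

    def test_first_step_uniform_binomial_ci(self):
        # node 0 has neighbors {1, 2}; over 10,000 seeded walks the first-step
        # frequency of node 1 must sit in 0.5 +/- 0.02
        adj = {0: [1, 2], 1: [0], 2: [0]}
        cfg = WalkConfig(walk_length=2, walks_per_node=10_000, seed=3)
        walks = [w for w in generate_walks(adj, cfg) if w[0] == 0]
        freq = np.mean([w[1] == 1 for w in walks])
        assert abs(freq - 0.5) < 0.02

    def test_corpus_frequency_tracks_degree_distribution(self):
        adj, *_ = two_cliques()
        cfg = WalkConfig(walk_length=10, walks_per_node=200, seed=5)
        counts = np.zeros(len(adj))
        total = 0
        for walk in generate_walks(adj, cfg):
            for node in walk[1:]:  # stationary part, skip forced starts
                counts[node] += 1
                total += 1
        degrees = np.array([len(adj[i]) for i in sorted(adj)], dtype=float)
        expected = degrees / degrees.sum() * total
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        # generous threshold: dof = 11, p ~ 1e-4
        assert chi2 < stats.chi2.ppf(1 - 1e-4, df=len(adj) - 1)


class TestSkipGram:
    def test_softmax_normalizes(self, rng):
        V = rng.normal(size=(5, 4))
        for w in range(5):
            assert context_distribution(V, w).sum() == pytest.approx(1.0, abs=1e-12)

    def test_analytic_gradient_matches_finite_difference(self, rng):
        V = rng.normal(0, 0.5, size=(4, 3))
        _, grad = log_prob_and_grad(V, w=1, u=2)
        eps = 1e-6
        num = np.zeros_like(V)
        for i in range(4):
            for j in range(3):
                vp, vm = V.copy(), V.copy()
                vp[i, j] += eps
                vm[i, j] -= eps
                num[i, j] = (log_prob_and_grad(vp, 1, 2)[0]
                             - log_prob_and_grad(vm, 1, 2)[0]) / (2 * eps)
        assert np.abs(grad - num).max() < 1e-5

    def test_batch_gradient_matches_pairwise(self, rng):
        V = rng.normal(0, 0.5, size=(6, 4))
        pairs = np.array([[0, 1], [2, 3], [1, 0], [4, 5]])
        total = np.zeros_like(V)
        for w, u in pairs:
            total += log_prob_and_grad(V, int(w), int(u))[1]
        assert np.allclose(_batch_gradient(V, pairs[:, 0], pairs[:, 1]), total)

    def test_empty_walks_rejected(self):
        with pytest.raises(ValueError):
            train_skipgram([], SkipGramConfig())

    def test_every_walk_node_gets_vector_of_dimension(self):
        walks = [[0, 1, 2], [3, 0]]
        table = train_skipgram(walks, SkipGramConfig(dimension=7, epochs=1))
        assert set(table.vectors) == {0, 1, 2, 3}
        assert all(v.shape == (7,) for v in table.vectors.values())

    def test_objective_nondecreasing_full_batch(self, rng):
        adj, *_ = two_cliques(4)
        walks = generate_walks(adj, WalkConfig(walk_length=8, walks_per_node=2, seed=0))
        vocab = sorted({n for w in walks for n in w})
        index = {n: i for i, n in enumerate(vocab)}
        pairs = _walk_pairs(walks, 3, index)
        V = rng.uniform(-0.5, 0.5, size=(len(vocab), 8)) / 8
        prev = skipgram_objective(V, pairs)
        for _ in range(20):
            V += 0.05 * _batch_gradient(V, pairs[:, 0], pairs[:, 1]) / len(pairs)
            cur = skipgram_objective(V, pairs)
            assert cur >= prev - 1e-9
            prev = cur

    def test_two_cliques_intra_similarity_exceeds_inter(self):
        adj, c1, c2 = two_cliques()
        walks = generate_walks(adj, WalkConfig(seed=2))
        table = train_skipgram(walks, SkipGramConfig(dimension=16, epochs=5, seed=2))

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        intra = np.mean([cos(table[a], table[b])
                         for grp in (c1, c2) for a, b in combinations(grp, 2)])
        inter = np.mean([cos(table[a], table[b]) for a in c1 for b in c2])
        assert intra > inter


class TestEmbeddingTable:
    def test_dimension_enforced(self):
        with pytest.raises(ValueError):
            EmbeddingTable(3, {0: np.zeros(4)})

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingTable(2, {0: np.array([np.nan, 0.0])})

    def test_tsv_round_trip(self, tmp_path, rng):
        table = EmbeddingTable(4, {i: rng.normal(size=4).astype(np.float32)
                                   for i in range(3)})
        table.to_tsv(tmp_path / "emb.tsv")
        back = EmbeddingTable.from_tsv(tmp_path / "emb.tsv")
        assert back.dimension == 4
        for i in range(3):
            assert np.array_equal(back[i], table[i])


class TestEmbedGraph:
    def test_all_nodes_carry_vectors(self, small_kg):
        out = embed_graph(small_kg, WalkConfig(seed=0),
                          SkipGramConfig(dimension=6, epochs=1, seed=0))
        assert all(n.embedding is not None and n.embedding.shape == (6,)
                   for n in out.nodes)

    def test_rerun_identical(self, small_kg):
        cfgs = (WalkConfig(seed=4), SkipGramConfig(dimension=6, epochs=2, seed=4))
        a = embed_graph(small_kg, *cfgs)
        b = embed_graph(small_kg, *cfgs)
        for na, nb in zip(a.nodes, b.nodes):
            assert np.array_equal(na.embedding, nb.embedding)

    def test_subgraph_restriction_leaves_others_untouched(self, small_kg):
        out = embed_graph(small_kg, WalkConfig(seed=0),
                          SkipGramConfig(dimension=6, epochs=1, seed=0),
                          node_filter=["Syndrome", "Symptoms"])
        for node in out.nodes:
            if node.entity_type in ("Syndrome", "Symptoms"):
                assert node.embedding is not None
            else:
                assert node.embedding is None

    def test_empty_graph_rejected(self, schema):
        from kgclf.kg_core import KnowledgeGraph
        with pytest.raises(ValueError):
            embed_graph(KnowledgeGraph(schema))
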