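"""node2vec walks, skip-gram training, and molecular fingerprints."""

import numpy as np
import pytest
from scipy import stats

from drugwalk.embeddings import (Node2VecParams, WalkCorpus, embed_molecule,
                                 embed_network, fingerprint_embedding,
                                 generate_walks, train_skipgram)
from drugwalk.types import DiseaseHierarchy, DrugRecord, SignedNetwork, ValidationError


def _params(**kw):
    defaults = dict(dim=16, walks_per_node=5, walk_length=10, window=3,
                    epochs=2, seed=0)
    defaults.update(kw)
    return Node2VecParams(**defaults)


class TestWalks:
    def test_every_node_starts_exactly_walks_per_node(self, small_signed_net):
        corpus = generate_walks(small_signed_net, _params(walks_per_node=7))
        starts = {}
        for s in corpus.sentences:
            starts[s[0]] = starts.get(s[0], 0) + 1
        assert all(v == 7 for v in starts.values())
        assert set(starts) == small_signed_net.nodes

    def test_path_graph_forced_alternation(self):
        net = SignedNetwork(nodes={"A", "B"}, edges=[("A", "B", 1)])
        corpus = generate_walks(net, _params(walk_length=6, walks_per_node=2))
        for s in corpus.sentences:
            for i in range(1, len(s)):
                assert s[i] != s[i - 1]
            assert len(s) == 6

    def test_isolated_node_yields_length_one_walk(self):
        net = SignedNetwork(nodes={"A", "B", "C"}, edges=[("A", "B", 1)])
        corpus = generate_walks(net, _params())
        solo = [s for s in corpus.sentences if s[0] == "C"]
        assert solo and all(s == ["C"] for s in solo)

    def test_uniform_transitions_when_p_q_one(self):
        """With p=q=1 one-step transitions from a hub are uniform
        (chi-square goodness of fit not rejected at alpha=0.01)."""
        leaves = [f"L{i}" for i in range(5)]
        edges = [("hub", leaf, 1) for leaf in leaves]
        # connect leaves in a ring so walks keep returning through the hub
        edges += [(leaves[i], leaves[(i + 1) % 5], 1) for i in range(5)]
        net = SignedNetwork(nodes={"hub", *leaves}, edges=edges)
        corpus = generate_walks(net, _params(walks_per_node=400, walk_length=20,
                                             seed=1))
        counts = {leaf: 0 for leaf in leaves}
        n_from_hub = 0
        for s in corpus.sentences:
            for a, b in zip(s, s[1:]):
                if a == "hub":
                    counts[b] += 1
                    n_from_hub += 1
        assert n_from_hub >= 10000
        observed = np.array(list(counts.values()))
        p = stats.chisquare(observed).pvalue
        assert p > 0.01

    def test_high_q_biases_back_to_previous_node(self):
        """Star graph, from a leaf through the center: with q large the next
        step returns to the same leaf with probability 1/(1+3/q) -> 1."""
        leaves = [f"L{i}" for i in range(4)]
        net = SignedNetwork(nodes={"C", *leaves},
                            edges=[("C", leaf, 1) for leaf in leaves])
        params = _params(in_out_q=1000.0, walks_per_node=200, walk_length=3,
                         seed=2)
        corpus = generate_walks(net, params)
        returns, total = 0, 0
        for s in corpus.sentences:
            if len(s) == 3 and s[0] in leaves:  # leaf -> C -> ?
                total += 1
                returns += s[2] == s[0]
        expected = 1.0 / (1.0 + 3.0 / 1000.0)
        assert total > 100
        assert returns / total > 0.98  # ~ expected 0.997
        assert abs(returns / total - expected) < 0.03

    def test_walks_deterministic_under_seed(self, small_signed_net):
        c1 = generate_walks(small_signed_net, _params(seed=5))
        c2 = generate_walks(small_signed_net, _params(seed=5))
        assert c1.sentences == c2.sentences


class TestSkipgram:
    def test_clique_pair_separation(self):
        """Two 6-cliques joined by one bridge: intra-clique cosine similarity
        exceeds cross-clique similarity after training."""
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        edges = [(x, y, 1) for nodes in (a, b)
                 for i, x in enumerate(nodes) for y in nodes[i + 1:]]
        edges.append((a[0], b[0], 1))
        net = SignedNetwork(nodes=set(a + b), edges=edges)
        params = Node2VecParams(dim=16, walks_per_node=10, walk_length=20,
                                window=3, epochs=3, seed=0)
        table = embed_network(net, params)

        def cos(u, v):
            return table[u] @ table[v] / (np.linalg.norm(table[u])
                                          * np.linalg.norm(table[v]))
        intra = np.mean([cos(x, y) for nodes in (a, b)
                         for i, x in enumerate(nodes) for y in nodes[i + 1:]])
        cross = np.mean([cos(x, y) for x in a for y in b])
        assert intra > cross

    def test_degenerate_single_node_corpus(self):
        corpus = WalkCorpus(sentences=[["X"], ["X"]])
        table = train_skipgram(corpus, _params())
        assert set(table.keys()) == {"X"}
        assert np.all(np.isfinite(table["X"]))

    def test_training_deterministic_under_seed(self, small_signed_net):
        params = _params(seed=3)
        corpus = generate_walks(small_signed_net, params)
        t1 = train_skipgram(corpus, params)
        t2 = train_skipgram(corpus, params)
        for k in t1.keys():
            np.testing.assert_array_equal(t1[k], t2[k])

    def test_embed_network_covers_non_isolated_nodes(self, small_signed_net):
        table = embed_network(small_signed_net, _params())
        assert set(table.keys()) == small_signed_net.nodes

    def test_disease_hierarchy_accepted(self):
        h = DiseaseHierarchy(terms=["r", "c1", "c2"],
                             edges=[("r", "c1"), ("r", "c2")])
        table = embed_network(h, _params())
        assert set(table.keys()) == {"r", "c1", "c2"}


class TestMolecularEmbedding:
    def test_identical_smiles_identical_vectors(self):
        v1 = fingerprint_embedding("CCO", 64)
        v2 = fingerprint_embedding("CCO", 64)
        np.testing.assert_array_equal(v1, v2)

    def test_spelling_variants_canonicalized(self):
        # same molecule written two ways; canonical-form oracle from rdkit
        from rdkit import Chem
        assert (Chem.MolToSmiles(Chem.MolFromSmiles("CCO"))
                == Chem.MolToSmiles(Chem.MolFromSmiles("OCC")))
        np.testing.assert_array_equal(fingerprint_embedding("CCO", 64),
                                      fingerprint_embedding("OCC", 64))

    def test_distinct_structures_distinct_vectors(self):
        benzene = fingerprint_embedding("c1ccccc1", 64)
        ethanol = fingerprint_embedding("CCO", 64)
        assert not np.array_equal(benzene, ethanol)

    def test_aspirin_unit_norm(self):
        v = fingerprint_embedding("CC(=O)Oc1ccccc1C(=O)O", 300)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(ValidationError):
            fingerprint_embedding("not_a_smiles(((", 64)

    def test_table_provider(self):
        from drugwalk.types import EmbeddingTable
        table = EmbeddingTable({"d1": np.arange(4.0)})
        v = embed_molecule(DrugRecord("d1"), provider="table", table=table)
        np.testing.assert_array_equal(v, [0, 1, 2, 3])

    def test_no_smiles_no_embedding_rejected(self):
        with pytest.raises(ValidationError):
            embed_molecule(DrugRecord("dX"), dim=16)
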