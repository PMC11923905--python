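"""Synthetic-data generators: boundary cases, statistical structure, determinism."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from drugwalk.diffusion import DiffusionConfig
from drugwalk.disease_networks import CorrelationNetworkConfig, differential_genes
from drugwalk.synth import (gen_disease_hierarchy, gen_drugs, gen_expression,
                            gen_planted_ddi, gen_signed_network)
from drugwalk.types import ACTIVATION, INHIBITION, ValidationError


class TestSignedNetwork:
    def test_all_activation_boundary(self):
        net = gen_signed_network(50, 150, inhib_frac=0.0, seed=1)
        assert all(g == 1 for _, _, g in net.edges)

    def test_all_inhibition_boundary(self):
        net = gen_signed_network(50, 150, inhib_frac=1.0, seed=1)
        assert all(g == -1 for _, _, g in net.edges)

    def test_realized_inhibitory_fraction(self):
        net = gen_signed_network(200, 800, inhib_frac=0.2, seed=7)
        assert 0.15 <= net.inhibitory_fraction() <= 0.25

    def test_giant_component_at_least_80_percent(self):
        net = gen_signed_network(100, 150, inhib_frac=0.2, seed=3)
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from((s, t) for s, t, _ in net.edges)
        giant = max(nx.connected_components(g), key=len)
        assert len(giant) >= 80

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValidationError):
            gen_signed_network(5, 100, seed=0)

    def test_scale_free_model(self):
        net = gen_signed_network(100, 300, inhib_frac=0.2, model="scale_free",
                                 seed=2)
        degrees = {}
        for s, t, _ in net.edges:
            degrees[s] = degrees.get(s, 0) + 1
            degrees[t] = degrees.get(t, 0) + 1
        assert max(degrees.values()) > 3 * np.median(list(degrees.values()))

    def test_deterministic(self):
        a = gen_signed_network(60, 200, inhib_frac=0.3, seed=9)
        b = gen_signed_network(60, 200, inhib_frac=0.3, seed=9)
        assert a.edges == b.edges


class TestHierarchy:
    def test_single_term_no_edges(self):
        h = gen_disease_hierarchy(1, seed=0)
        assert len(h.terms) == 1 and h.edges == []

    def test_tree_properties(self):
        h = gen_disease_hierarchy(10, seed=0)
        assert len(h.edges) == 9
        g = nx.Graph(h.edges)
        g.add_nodes_from(h.terms)
        assert nx.is_connected(g)

    def test_deterministic(self):
        assert (gen_disease_hierarchy(15, seed=4).edges
                == gen_disease_hierarchy(15, seed=4).edges)


class TestDrugs:
    def test_exact_target_count(self, small_signed_net):
        drugs = gen_drugs(10, 3, small_signed_net, seed=0)
        assert all(len(d.targets) == 3 for d in drugs)
        assert all(len({g for g, _ in d.targets}) == 3 for d in drugs)

    def test_all_activation_boundary(self, small_signed_net):
        drugs = gen_drugs(10, 2, small_signed_net, inhib_target_frac=0.0, seed=0)
        assert all(m == ACTIVATION for d in drugs for _, m in d.targets)

    def test_family_structure_shares_targets(self):
        net = gen_signed_network(100, 300, seed=0)
        drugs = gen_drugs(20, 3, net, seed=0, n_families=4)
        fam0 = [set(g for g, _ in d.targets) for d in drugs[::4]]
        # members of the same family draw from a 5-gene pool
        assert len(set().union(*fam0)) <= 5

    def test_deterministic(self, small_signed_net):
        a = gen_drugs(5, 2, small_signed_net, seed=3)
        b = gen_drugs(5, 2, small_signed_net, seed=3)
        assert all(x.targets == y.targets for x, y in zip(a, b))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.embedding, y.embedding)


@pytest.fixture(scope="module")
def tiny_world():
    net = gen_signed_network(40, 120, inhib_frac=0.2, seed=0)
    drugs = gen_drugs(12, 2, net, seed=1)
    return gen_planted_ddi(net, drugs, n_diseases=6, pos_quantile=0.9,
                           label_noise=0.0, seed=2,
                           config=DiffusionConfig(seed=0), n_combos=10)


class TestPlantedDDI:

    def test_noise_free_labels_deterministic_in_scores(self, tiny_world):
        cutoff = np.quantile(list(tiny_world.true_scores.values()), 0.9)
        for r in tiny_world.records:
            s = tiny_world.true_scores[(r.drug_ids[0], r.disease_id)]
            assert r.label == ("positive" if s > cutoff else "negative")

    def test_positive_fraction_near_quantile_complement(self, tiny_world):
        n = len(tiny_world.records)
        frac = len(tiny_world.positives) / n
        assert abs(frac - 0.1) <= 2 / np.sqrt(n)

    def test_every_record_references_known_entities(self, tiny_world):
        drug_ids = {d.drug_id for d in tiny_world.drugs}
        for r in tiny_world.records + tiny_world.combos:
            assert set(r.drug_ids) <= drug_ids
            assert r.disease_id in tiny_world.disease_signatures

    def test_combos_are_high_affinity_pairs(self, tiny_world):
        assert len(tiny_world.combos) == 10
        assert all(len(c.drug_ids) == 2 and c.label == "positive"
                   for c in tiny_world.combos)

    def test_regeneration_identical(self):
        net = gen_signed_network(30, 90, seed=5)
        drugs = gen_drugs(6, 2, net, seed=5)
        kw = dict(n_diseases=4, pos_quantile=0.9, label_noise=0.1, seed=6,
                  config=DiffusionConfig(seed=1))
        w1 = gen_planted_ddi(net, drugs, **kw)
        w2 = gen_planted_ddi(net, drugs, **kw)
        assert [r.label for r in w1.records] == [r.label for r in w2.records]
        for z in w1.disease_embeddings:
            np.testing.assert_array_equal(w1.disease_embeddings[z],
                                          w2.disease_embeddings[z])

    def test_invalid_parameters_rejected(self, tiny_world):
        with pytest.raises(ValidationError):
            gen_planted_ddi(tiny_world.network, tiny_world.drugs, 3,
                            pos_quantile=1.5)
        with pytest.raises(ValidationError):
            gen_planted_ddi(tiny_world.network, tiny_world.drugs, 3,
                            label_noise=0.7)


class TestExpression:
    def test_null_de_rate_matches_alpha(self):
        """With zero effect size, raw-p selection flags about 5% of genes
        (within binomial 99% bounds over 2000 genes)."""
        expr = gen_expression(2000, 15, 15, n_de_genes=0, effect_size=0.0,
                              seed=0)
        cfg = CorrelationNetworkConfig(de_adjust="raw", de_alpha=0.05)
        hits = len(differential_genes(expr, cfg))
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.05)
        assert lo <= hits <= hi

    def test_module_correlation_structure(self):
        expr = gen_expression(100, 20, 20, module_corr=0.9, module_size=20,
                              seed=1)
        sub = expr.values[:20]
        r = np.corrcoef(sub)
        off = r[np.triu_indices(20, k=1)]
        assert np.mean(off > 0.5) > 0.9
        cross = np.corrcoef(expr.values[:20], expr.values[20:40])[:20, 20:]
        assert np.mean(cross < -0.5) > 0.9

    def test_planted_de_genes_shifted(self):
        expr = gen_expression(50, 10, 10, n_de_genes=10, effect_size=2.0,
                              seed=2)
        case = expr.group_columns("case")
        ctrl = expr.group_columns("control")
        diff = case.mean(axis=1) - ctrl.mean(axis=1)
        assert diff[:10].mean() > 1.0
        assert abs(diff[10:].mean()) < 0.5

    def test_deterministic(self):
        a = gen_expression(30, 5, 5, seed=3)
        b = gen_expression(30, 5, 5, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
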