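"""Signed random walk: closed forms, invariants, oracle agreement."""

import numpy as np
import pytest

from drugwalk.diffusion import (DiffusionConfig, accumulate_walks,
                                diffuse_combination, diffuse_drug,
                                expected_profile_oracle, project_to_universe,
                                walk_from_target)
from drugwalk.types import GeneUniverse, SignedNetwork

from conftest import random_signed_graph


def _forced(alpha=0.0, steps=1, epochs=1, seed=0):
    return DiffusionConfig(alpha=alpha, beta=0.95, epochs=epochs, steps=steps,
                           seed=seed)


class TestClosedForms:
    def test_single_activating_edge_deposits_beta(self):
        net = SignedNetwork(nodes={"T", "A"}, edges=[("T", "A", 1)], directed=True)
        acc = accumulate_walks(net, [("T", 1)], _forced())
        assert acc == {"A": pytest.approx(0.95)}

    def test_single_inhibitory_edge_flips_sign(self):
        net = SignedNetwork(nodes={"T", "A"}, edges=[("T", "A", -1)], directed=True)
        acc = accumulate_walks(net, [("T", 1)], _forced())
        assert acc == {"A": pytest.approx(-0.95)}

    def test_double_inhibition_chain_restores_sign(self, chain_net):
        # parities 1 then 0: -beta, +beta^2
        acc = accumulate_walks(chain_net, [("T", 1)], _forced(steps=2))
        assert acc["A"] == pytest.approx(-0.95)
        assert acc["B"] == pytest.approx(0.9025)

    def test_inhibitory_seed_sign_multiplies(self, chain_net):
        acc = accumulate_walks(chain_net, [("T", -1)], _forced(steps=2))
        assert acc["A"] == pytest.approx(0.95)
        assert acc["B"] == pytest.approx(-0.9025)

    def test_forced_path_matches_oracle_exactly(self, chain_net):
        config = _forced(steps=2)
        oracle = expected_profile_oracle(chain_net, [("T", 1)], config)
        assert oracle["A"] == pytest.approx(-0.95)
        assert oracle["B"] == pytest.approx(0.9025)


class TestWalkSemantics:
    def test_target_not_in_network_rejected(self, small_signed_net):
        with pytest.raises(ValueError):
            accumulate_walks(small_signed_net, [("nope", 1)], _forced())

    def test_empty_seed_set_rejected(self, small_signed_net, universe6):
        with pytest.raises(ValueError):
            diffuse_drug(small_signed_net, [], _forced(), universe6)

    def test_outside_seeds_skipped_with_usable_remainder(self, small_signed_net,
                                                         universe6):
        prof = diffuse_drug(small_signed_net, [("A", 1), ("nope", 1)],
                            _forced(alpha=0.3, steps=5, epochs=3), universe6)
        assert np.any(prof != 0)

    def test_alpha_one_never_deposits(self, small_signed_net):
        config = DiffusionConfig(alpha=1.0, beta=0.95, epochs=5, steps=10, seed=0)
        acc = accumulate_walks(small_signed_net, [("A", 1)], config)
        assert acc == {}
        oracle = expected_profile_oracle(small_signed_net, [("A", 1)], config)
        assert oracle == {}

    def test_sink_forces_restart_without_deposit(self):
        net = SignedNetwork(nodes={"T", "A"}, edges=[("T", "A", 1)], directed=True)
        # A is a sink: steps beyond the first deposit only via fresh T->A moves
        acc = accumulate_walks(net, [("T", 1)], _forced(steps=4))
        # forced path: step1 deposit beta, step2 at sink restarts, step3 deposits beta^3
        assert acc["A"] == pytest.approx(0.95 + 0.95 ** 3)

    def test_determinism(self, small_signed_net, universe6, fast_diffusion):
        p1 = diffuse_drug(small_signed_net, [("A", 1), ("C", -1)],
                          fast_diffusion, universe6, stream_key="d")
        p2 = diffuse_drug(small_signed_net, [("A", 1), ("C", -1)],
                          fast_diffusion, universe6, stream_key="d")
        np.testing.assert_array_equal(p1, p2)

    def test_multi_seed_equals_sum_of_single_seeds(self, small_signed_net,
                                                   universe6, fast_diffusion):
        both = diffuse_drug(small_signed_net, [("A", 1), ("D", -1)],
                            fast_diffusion, universe6, stream_key="d")
        pa = diffuse_drug(small_signed_net, [("A", 1)], fast_diffusion,
                          universe6, stream_key="d")
        pd = diffuse_drug(small_signed_net, [("D", -1)], fast_diffusion,
                          universe6, stream_key="d")
        np.testing.assert_allclose(both, pa + pd, atol=1e-12)


class TestInvariants:
    def test_deposit_magnitudes_are_beta_powers(self, small_signed_net):
        """Every deposit magnitude is exactly beta^n for some step n."""
        config = DiffusionConfig(alpha=0.0, beta=0.95, epochs=1, steps=10, seed=3)

        deposits = []

        class Recorder(dict):
            def __setitem__(self, k, v):
                deposits.append(v - self.get(k, 0.0))
                super().__setitem__(k, v)

        rng = np.random.default_rng(0)
        walk_from_target(small_signed_net.adjacency(), ("A", 1), config, rng,
                         Recorder())
        allowed = {round(0.95 ** n, 12) for n in range(1, 11)}
        for d in deposits:
            assert round(abs(d), 12) in allowed

    def test_sign_parity_on_all_inhibitory_path(self):
        """alpha=0 on an all-inhibitory path: deposit sign is (-1)^n, with n
        recoverable from the magnitude beta^n."""
        nodes = [f"P{i}" for i in range(6)]
        edges = [(nodes[i], nodes[i + 1], -1) for i in range(5)]
        net = SignedNetwork(nodes=set(nodes), edges=edges, directed=True)
        config = DiffusionConfig(alpha=0.0, beta=0.95, epochs=4, steps=5, seed=1)
        acc = accumulate_walks(net, [(nodes[0], 1)], config)
        for node, val in acc.items():
            n = nodes.index(node)
            assert np.sign(val) == (-1) ** n
            assert abs(val) == pytest.approx(4 * 0.95 ** n)

    def test_l1_norm_bound(self, fast_diffusion):
        rng = np.random.default_rng(7)
        for _ in range(5):
            net = random_signed_graph(rng, n_nodes=8)
            seeds = [("N0", 1), ("N1", -1)]
            acc = accumulate_walks(net, seeds, fast_diffusion, stream_key="x")
            bound = (len(seeds) * fast_diffusion.epochs
                     * sum(0.95 ** n for n in range(1, 16)))
            assert sum(abs(v) for v in acc.values()) <= bound + 1e-9

    def test_monte_carlo_matches_oracle(self):
        """Empirical mean over many epochs within 3 SE of the exact
        expectation, per node, on random 6-node signed graphs."""
        rng = np.random.default_rng(42)
        n_epochs = 2000
        total, bad = 0, 0
        for g in range(5):
            net = random_signed_graph(rng, n_nodes=6)
            start = sorted(net.nodes)[0]
            config = DiffusionConfig(alpha=0.3, beta=0.95, epochs=n_epochs,
                                     steps=8, seed=100 + g)
            acc = accumulate_walks(net, [(start, 1)], config, stream_key="mc")
            expect = expected_profile_oracle(
                net, [(start, 1)],
                DiffusionConfig(alpha=0.3, beta=0.95, epochs=1, steps=8))
            # per-epoch deposits for an SE estimate
            per_epoch = []
            adj = net.adjacency()
            rng2 = np.random.default_rng(9)
            one = DiffusionConfig(alpha=0.3, beta=0.95, epochs=1, steps=8)
            for _ in range(300):
                a = {}
                walk_from_target(adj, (start, 1), one, rng2, a)
                per_epoch.append(a)
            for node in net.nodes:
                vals = np.array([a.get(node, 0.0) for a in per_epoch])
                se = vals.std(ddof=1) / np.sqrt(n_epochs)
                if se == 0:
                    continue
                z = abs(acc.get(node, 0.0) / n_epochs - expect.get(node, 0.0)) / se
                total += 1
                bad += z >= 3
        assert bad / total < 0.01


class TestCombination:
    def test_single_drug_combination_identity(self, small_signed_net, universe6,
                                              fast_diffusion):
        single = diffuse_drug(small_signed_net, [("A", 1)], fast_diffusion,
                              universe6, stream_key="dA")
        combo = diffuse_combination(small_signed_net, {"dA": [("A", 1)]},
                                    fast_diffusion, universe6)
        np.testing.assert_array_equal(single, combo)

    def test_additivity_and_order_invariance(self, small_signed_net, universe6,
                                             fast_diffusion):
        sets = {"dA": [("A", 1)], "dB": [("B", -1), ("D", 1)]}
        combo = diffuse_combination(small_signed_net, sets, fast_diffusion,
                                    universe6)
        pa = diffuse_drug(small_signed_net, sets["dA"], fast_diffusion,
                          universe6, stream_key="dA")
        pb = diffuse_drug(small_signed_net, sets["dB"], fast_diffusion,
                          universe6, stream_key="dB")
        np.testing.assert_allclose(combo, pa + pb, atol=1e-12)
        reordered = diffuse_combination(
            small_signed_net, dict(reversed(list(sets.items()))),
            fast_diffusion, universe6)
        np.testing.assert_array_equal(combo, reordered)


class TestProjection:
    def test_node_outside_universe_dropped(self):
        u = GeneUniverse(["A", "B"])
        prof = project_to_universe({"A": 0.5, "X": 0.3}, u)
        np.testing.assert_array_equal(prof, [0.5, 0.0])

    def test_unvisited_universe_gene_zero(self):
        u = GeneUniverse(["A", "B", "C"])
        prof = project_to_universe({}, u)
        assert not prof.any()
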