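"""Signed random-walk diffusion of drug effects over a molecular network.

A drug is represented by its signed target set: each target gene is a walk
start point carrying Sign(T) = +1 (the drug activates it) or -1 (inhibits).
From each start the walker runs ``epochs`` independent walks of ``steps``
steps.  At every step it either restarts at the start gene (probability
``alpha``) or traverses a uniformly random incident edge; arriving at node
x at step n it deposits

    beta^n * Sign(T) * (-1)^(number of inhibitory edges since last restart)

into x's accumulator.  Restarts teleport to the start, reset the inhibitory
parity, deposit nothing, and still consume a step (the decay index keeps
advancing).  Values from all steps, epochs and start points add; nothing is
normalized.  The accumulated node values, aligned to a fixed gene universe,
form the drug's diffusion profile — its feature vector downstream.

Combinations diffuse each drug in turn into one shared accumulator.  Random
substreams are keyed by (seed, drug key, start gene), which makes the
combination profile exactly the sum of the per-drug profiles and invariant
to drug order.

``expected_profile_oracle`` computes the exact expectation of the
accumulator on the lifted (node, parity) state space by matrix iteration;
it exists for verification and the synthetic planted signal, not as a
production path.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import GeneUniverse, SignedNetwork

logger = logging.getLogger("drugwalk")

TargetSeed = Tuple[str, int]  # (gene, +1|-1)


@dataclass
class DiffusionConfig:
    """Walk hyperparameters; defaults are the pipeline's operating point."""

    alpha: float = 0.3   # restart probability per step
    beta: float = 0.95   # geometric decay of deposited values
    epochs: int = 15     # independent walks per start gene
    steps: int = 15      # steps per walk
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0,1]")
        if not (0 < self.beta < 1):
            raise ValueError("beta must be in (0,1)")
        if self.epochs < 1 or self.steps < 1:
            raise ValueError("epochs and steps must be >= 1")


def _substream(seed: int, stream_key: str, gene: str) -> np.random.Generator:
    """Deterministic per-(drug, start gene) random stream."""
    k1 = zlib.crc32(stream_key.encode())
    k2 = zlib.crc32(gene.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, k1, k2)))


def walk_from_target(adj: Mapping[str, List[Tuple[str, int]]], target: TargetSeed,
                     config: DiffusionConfig, rng: np.random.Generator,
                     accumulator: Dict[str, float]) -> Dict[str, float]:
    """Run ``config.epochs`` walks from one signed target, adding into ``accumulator``."""
    start, sign = target
    if start not in adj:
        raise ValueError(f"target gene {start!r} not in network")
    alpha, beta = config.alpha, config.beta
    for _ in range(config.epochs):
        current = start
        parity = 0
        for n in range(1, config.steps + 1):
            if alpha > 0 and rng.random() < alpha:
                current, parity = start, 0          # restart: no deposit, decay advances
                continue
            neighbors = adj[current]
            if not neighbors:
                current, parity = start, 0          # sink forces a restart
                continue
            nxt, edge_sign = neighbors[int(rng.integers(len(neighbors)))]
            parity ^= (edge_sign == -1)
            accumulator[nxt] = accumulator.get(nxt, 0.0) + beta ** n * sign * (-1) ** parity
            current = nxt
    return accumulator


def accumulate_walks(network: SignedNetwork, seeds: Sequence[TargetSeed],
                     config: DiffusionConfig, stream_key: str = "",
                     accumulator: Optional[Dict[str, float]] = None) -> Dict[str, float]:
    """Multi-start walk: every target is an independent start point; values add."""
    if accumulator is None:
        accumulator = {}
    adj = network.adjacency()
    usable = [(g, s) for g, s in seeds if g in network.nodes]
    skipped = [g for g, _ in seeds if g not in network.nodes]
    if skipped:
        logger.warning("skipping %d seed genes outside the network: %s",
                       len(skipped), skipped[:5])
    if not usable:
        raise ValueError("no seed gene is present in the network")
    for gene, sign in usable:
        rng = _substream(config.seed, stream_key, gene)
        walk_from_target(adj, (gene, sign), config, rng, accumulator)
    return accumulator


def project_to_universe(node_values: Mapping[str, float],
                        universe: GeneUniverse) -> np.ndarray:
    """Align walk output to the fixed gene universe.

    Universe genes never visited get 0; network nodes outside the universe
    (kept during the walk so paths may pass through them) are dropped here.
    """
    out = np.zeros(len(universe))
    for gene, val in node_values.items():
        if gene in universe:
            out[universe.index(gene)] = val
    return out


def diffuse_drug(network: SignedNetwork, seeds: Sequence[TargetSeed],
                 config: DiffusionConfig, universe: GeneUniverse,
                 stream_key: str = "") -> np.ndarray:
    """Diffusion profile of a single drug over the gene universe."""
    if not seeds:
        raise ValueError("empty target seed set")
    acc = accumulate_walks(network, seeds, config, stream_key=stream_key)
    return project_to_universe(acc, universe)


def diffuse_combination(network: SignedNetwork,
                        seed_sets: Mapping[str, Sequence[TargetSeed]],
                        config: DiffusionConfig,
                        universe: GeneUniverse) -> np.ndarray:
    """Combination profile: each drug diffuses into the same accumulator.

    Substreams are keyed by drug id, so the result equals the sum of the
    individual ``diffuse_drug`` profiles (run with ``stream_key=drug_id``)
    and does not depend on drug order.
    """
    if not seed_sets:
        raise ValueError("empty combination")
    acc: Dict[str, float] = {}
    for drug_id in sorted(seed_sets):
        seeds = seed_sets[drug_id]
        if not seeds:
            raise ValueError(f"drug {drug_id!r} has an empty target set")
        # each drug's walks finish before its totals are added, so the
        # combination equals the elementwise sum of single-drug profiles
        # bit for bit (same addition order as profile_a + profile_b)
        drug_acc = accumulate_walks(network, seeds, config, stream_key=drug_id)
        for node, val in drug_acc.items():
            acc[node] = acc.get(node, 0.0) + val
    return project_to_universe(acc, universe)


# ---------------------------------------------------------------------------
# Exact expectation oracle on the lifted (node, parity) chain
# ---------------------------------------------------------------------------

def expected_profile_oracle(network: SignedNetwork, seeds: Sequence[TargetSeed],
                            config: DiffusionConfig,
                            exact_steps: Optional[int] = None) -> Dict[str, float]:
    """Exact expected accumulator value per node, by transition-matrix power.

    States are (node, parity).  Each step moves restart mass ``alpha`` (plus
    all mass on sinks) to (start, 0) without depositing, and spreads
    (1-alpha)/deg over incident edges, flipping parity on inhibitory ones;
    a traversal arriving at (x, p) at step n deposits beta^n * sign * (-1)^p.
    Expected deposits are summed over n = 1..steps and multiplied by epochs.
    """
    steps = exact_steps if exact_steps is not None else config.steps
    nodes = sorted(network.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    S = 2 * len(nodes)  # state (v, p) -> 2*idx[v] + p

    adj = network.adjacency()
    # traversal-only transition matrix (restart handled separately)
    T = np.zeros((S, S))
    for v in nodes:
        deg = len(adj[v])
        if deg == 0:
            continue
        w = (1.0 - config.alpha) / deg
        for p in (0, 1):
            s = 2 * idx[v] + p
            for x, g in adj[v]:
                p2 = p ^ (g == -1)
                T[s, 2 * idx[x] + p2] += w

    expected = np.zeros(len(nodes))
    for start, sign in seeds:
        if start not in idx:
            continue
        start_state = 2 * idx[start]
        q = np.zeros(S)
        q[start_state] = 1.0
        for n in range(1, steps + 1):
            arrivals = q @ T                       # mass arriving by edge traversal
            per_node = arrivals[0::2] - arrivals[1::2]   # (-1)^parity weighting
            expected += config.beta ** n * sign * per_node
            q_next = arrivals.copy()
            q_next[start_state] += 1.0 - arrivals.sum()  # restart + sink mass
            q = q_next
    expected *= config.epochs
    return {v: float(expected[i]) for v, i in idx.items() if expected[i] != 0.0}
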