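"""Seeded synthetic data with the statistical structure each stage assumes.

The generators emulate, at desk scale, the data sources the pipeline was
designed for: a signed gene-interaction network (~80% activating edges, as
in curated signaling maps), a tree-shaped disease vocabulary, drugs with a
handful of signed targets, and paired case/control expression with planted
differential genes and correlated modules.

``gen_planted_ddi`` plants a recoverable drug-disease signal *through the
diffusion mechanism itself*: each disease carries a sparse signature vector
over the gene universe, the true affinity of (drug, disease) is the inner
product of the drug's exact expected diffusion profile with that signature,
and pairs in the top tail of the affinity distribution are labelled
positive.  A pipeline that reproduces the diffusion operator can therefore
recover the labels; one that does not, cannot — the planted world tests the
mechanism, not luck.  Disease embeddings are the signatures corrupted with
Gaussian noise, so the scorer never sees the clean planting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .diffusion import DiffusionConfig, expected_profile_oracle, project_to_universe
from .types import (ACTIVATION, INHIBITION, DDIRecord, DiseaseHierarchy,
                    DrugRecord, ExpressionMatrix, GeneUniverse, SignedNetwork,
                    ValidationError)

logger = logging.getLogger("drugwalk")


@dataclass
class PlantedWorld:
    network: SignedNetwork
    universe: GeneUniverse
    drugs: List[DrugRecord]
    disease_signatures: Dict[str, np.ndarray]   # clean planted signatures
    disease_embeddings: Dict[str, np.ndarray]   # noisy versions fed to the scorer
    records: List[DDIRecord]                    # every drug x disease pair, labelled
    combos: List[DDIRecord]                     # positive combination records
    true_scores: Dict[Tuple[str, str], float]
    expected_profiles: Dict[str, np.ndarray]
    seed: int = 0
    params: Dict = field(default_factory=dict)

    @property
    def positives(self) -> List[DDIRecord]:
        return [r for r in self.records if r.label == "positive"]

    @property
    def negatives(self) -> List[DDIRecord]:
        return [r for r in self.records if r.label == "negative"]

    def target_sets(self) -> Dict[str, List[Tuple[str, int]]]:
        return {d.drug_id: d.seed_set() for d in self.drugs}


def gen_signed_network(n_nodes: int, n_edges: int, inhib_frac: float = 0.2,
                       model: str = "erdos", seed: int = 0,
                       max_resample: int = 50) -> SignedNetwork:
    """Random signed network with a giant component covering >= 80% of nodes.

    Exactly round(inhib_frac * n_edges) edges are inhibitory.  ``model`` is
    "erdos" (uniform edge placement) or "scale_free" (preferential
    attachment degree distribution).
    """
    import networkx as nx

    if not (0 <= inhib_frac <= 1):
        raise ValidationError("inhib_frac must be in [0,1]")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges or n_nodes < 2:
        raise ValidationError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    names = [f"G{i:04d}" for i in range(n_nodes)]
    for attempt in range(max_resample):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        if model == "erdos":
            g = nx.gnm_random_graph(n_nodes, n_edges,
                                    seed=int(rng.integers(2 ** 31)))
        elif model == "scale_free":
            m = max(1, round(n_edges / n_nodes))
            g = nx.barabasi_albert_graph(n_nodes, m,
                                         seed=int(rng.integers(2 ** 31)))
        else:
            raise ValidationError(f"unknown network model {model!r}")
        giant = max(nx.connected_components(g), key=len)
        if len(giant) >= 0.8 * n_nodes:
            break
    else:
        raise ValidationError("could not reach an 80% giant component")
    edge_list = sorted(g.edges())
    n_inh = round(inhib_frac * len(edge_list))
    signs = np.ones(len(edge_list), dtype=int)
    signs[rng.permutation(len(edge_list))[:n_inh]] = -1
    edges = [(names[a], names[b], int(s)) for (a, b), s in zip(edge_list, signs)]
    return SignedNetwork(nodes=set(names), edges=edges, directed=False)


def gen_disease_hierarchy(n_terms: int, branching: int = 3,
                          seed: int = 0) -> DiseaseHierarchy:
    """Random tree: each new term attaches to a uniform parent with spare
    branching capacity; n_terms nodes, n_terms - 1 edges, connected."""
    if n_terms < 1:
        raise ValidationError("need at least one term")
    rng = np.random.default_rng(seed)
    terms = [f"DZ{i:04d}" for i in range(n_terms)]
    child_count = np.zeros(n_terms, dtype=int)
    edges = []
    for i in range(1, n_terms):
        candidates = [j for j in range(i) if child_count[j] < branching]
        if not candidates:  # branching exhausted: fall back to any earlier node
            candidates = list(range(i))
        parent = candidates[int(rng.integers(len(candidates)))]
        child_count[parent] += 1
        edges.append((terms[parent], terms[i]))
    return DiseaseHierarchy(terms=terms, edges=edges)


def gen_drugs(n_drugs: int, targets_per_drug: int, network: SignedNetwork,
              inhib_target_frac: float = 0.3, seed: int = 0,
              embed_dim: int = 64,
              n_families: Optional[int] = None) -> List[DrugRecord]:
    """Drugs with ``targets_per_drug`` distinct targets drawn from network
    nodes, each mode sampled, plus a random unit-norm embedding vector.

    With ``n_families`` set, drugs are grouped into families sharing a
    small target pool (targets_per_drug + 2 genes per family), emulating
    pharmacological classes whose members hit overlapping targets — the
    similarity structure that lets pair-based scoring generalize across
    related drugs.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    pools = None
    if n_families is not None:
        pools = []
        for _ in range(n_families):
            pool_idx = rng.choice(len(nodes), size=targets_per_drug + 2,
                                  replace=False)
            pools.append([nodes[j] for j in pool_idx])
    drugs = []
    for i in range(n_drugs):
        if pools is not None:
            pool = pools[i % len(pools)]
            genes = [pool[j] for j in rng.choice(len(pool),
                                                 size=targets_per_drug,
                                                 replace=False)]
        else:
            genes = [nodes[j] for j in rng.choice(len(nodes),
                                                  size=targets_per_drug,
                                                  replace=False)]
        modes = [INHIBITION if rng.random() < inhib_target_frac else ACTIVATION
                 for _ in genes]
        vec = rng.normal(size=embed_dim)
        vec /= np.linalg.norm(vec)
        drugs.append(DrugRecord(f"D{i:03d}", targets=list(zip(genes, modes)),
                                embedding=vec))
    return drugs


def gen_planted_ddi(network: SignedNetwork, drugs: Sequence[DrugRecord],
                    n_diseases: int, pos_quantile: float = 0.92,
                    label_noise: float = 0.0,
                    config: Optional[DiffusionConfig] = None,
                    seed: int = 0, universe: Optional[GeneUniverse] = None,
                    signature_genes: int = 12, signature_noise_sd: float = 0.1,
                    n_combos: int = 0, n_prototypes: Optional[int] = None,
                    prototype_jitter_sd: float = 0.3,
                    embedding_dim: Optional[int] = None) -> PlantedWorld:
    """Label every drug x disease pair through the diffusion oracle.

    True affinity(drug, disease) = <expected diffusion profile, signature>;
    pairs above the ``pos_quantile`` of all affinities are positive, then
    labels flip independently with probability ``label_noise``.  Disease
    embeddings are signatures plus N(0, signature_noise_sd) noise, padded or
    truncated to ``embedding_dim`` (default: the universe size).

    With ``n_combos`` > 0, random (drug pair, disease) candidates are scored
    by the sum of the two expected profiles against the signature, and the
    ``n_combos`` highest-affinity candidates become the positive combination
    list (curated combination therapies are all positive instances).
    """
    if not (0 < pos_quantile < 1):
        raise ValidationError("pos_quantile must be in (0,1)")
    if not (0 <= label_noise < 0.5):
        raise ValidationError("label_noise must be in [0, 0.5)")
    config = config or DiffusionConfig(seed=seed)
    if universe is None:
        universe = GeneUniverse(sorted(network.nodes))
    rng = np.random.default_rng(seed)

    expected_profiles = {}
    for d in drugs:
        seeds = [(g, s) for g, s in d.seed_set() if g in network.nodes]
        if not seeds:
            raise ValidationError(f"drug {d.drug_id} has no targets in the network")
        expected_profiles[d.drug_id] = project_to_universe(
            expected_profile_oracle(network, seeds, config), universe)

    dim = embedding_dim if embedding_dim is not None else len(universe)
    prototypes = None
    if n_prototypes is not None:
        # disease families: each disease perturbs one of a few prototype
        # signatures, mirroring related conditions sharing molecular bases
        prototypes = []
        for _ in range(n_prototypes):
            proto = np.zeros(len(universe))
            idx = rng.choice(len(universe),
                             size=min(signature_genes, len(universe)),
                             replace=False)
            proto[idx] = rng.normal(size=len(idx))
            prototypes.append(proto)
    signatures, embeddings = {}, {}
    for i in range(n_diseases):
        zid = f"Z{i:03d}"
        if prototypes is not None:
            base = prototypes[i % len(prototypes)]
            sig = base.copy()
            support = np.flatnonzero(base)
            sig[support] += rng.normal(0.0, prototype_jitter_sd,
                                       size=len(support))
        else:
            sig = np.zeros(len(universe))
            idx = rng.choice(len(universe),
                             size=min(signature_genes, len(universe)),
                             replace=False)
            sig[idx] = rng.normal(size=len(idx))
        signatures[zid] = sig
        noisy = sig + rng.normal(0.0, signature_noise_sd, size=len(sig))
        if dim >= len(sig):
            emb = np.concatenate([noisy, np.zeros(dim - len(sig))])
        else:
            emb = noisy[:dim]
        embeddings[zid] = emb

    true_scores = {}
    for d in drugs:
        for zid in signatures:
            true_scores[(d.drug_id, zid)] = float(
                expected_profiles[d.drug_id] @ signatures[zid])
    cutoff = float(np.quantile(list(true_scores.values()), pos_quantile))
    records = []
    for (did, zid), s in sorted(true_scores.items()):
        label = "positive" if s > cutoff else "negative"
        if label_noise > 0 and rng.random() < label_noise:
            label = "negative" if label == "positive" else "positive"
        records.append(DDIRecord([did], zid, label))

    combos: List[DDIRecord] = []
    if n_combos > 0:
        drug_ids = [d.drug_id for d in drugs]
        n_candidates = 10 * n_combos
        combo_scores = []
        seen = set()
        tries = 0
        while len(combo_scores) < n_candidates and tries < 50 * n_candidates:
            tries += 1
            a, b = rng.choice(len(drug_ids), size=2, replace=False)
            zid = f"Z{int(rng.integers(n_diseases)):03d}"
            key = (tuple(sorted((drug_ids[a], drug_ids[b]))), zid)
            if key in seen:
                continue
            seen.add(key)
            s = float((expected_profiles[drug_ids[a]]
                       + expected_profiles[drug_ids[b]]) @ signatures[zid])
            combo_scores.append((s, [drug_ids[a], drug_ids[b]], zid))
        combo_scores.sort(key=lambda t: -t[0])
        combos = [DDIRecord(ds, zid, "positive")
                  for _, ds, zid in combo_scores[:n_combos]]

    return PlantedWorld(
        network=network, universe=universe, drugs=list(drugs),
        disease_signatures=signatures, disease_embeddings=embeddings,
        records=records, combos=combos, true_scores=true_scores,
        expected_profiles=expected_profiles, seed=seed,
        params={"pos_quantile": pos_quantile, "label_noise": label_noise,
                "signature_genes": signature_genes,
                "signature_noise_sd": signature_noise_sd,
                "diffusion": config})


def gen_expression(n_genes: int, n_case: int, n_ctrl: int, n_de_genes: int = 0,
                   effect_size: float = 1.0, module_corr: float = 0.0,
                   module_size: int = 20, seed: int = 0) -> ExpressionMatrix:
    """Case/control expression: standard-normal controls, a mean shift of
    ``effect_size`` on the first ``n_de_genes`` genes in cases, and two
    latent-factor modules (A: genes 0..m-1, B: genes m..2m-1) with
    within-module correlation ``module_corr`` — positive within each module,
    negative between A and B by construction (opposite factor loadings)."""
    if n_de_genes > n_genes:
        raise ValidationError("n_de_genes exceeds n_genes")
    rng = np.random.default_rng(seed)
    n_samples = n_case + n_ctrl
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    groups = {s: ("case" if i < n_case else "control")
              for i, s in enumerate(samples)}
    eps = rng.normal(size=(n_genes, n_samples))
    values = eps.copy()
    if module_corr > 0:
        a = np.sqrt(module_corr)
        f = rng.normal(size=n_samples)
        m = min(module_size, n_genes // 2)
        loading = np.zeros(n_genes)
        loading[:m] = a          # module A
        loading[m:2 * m] = -a    # module B: anti-correlated with A
        values = loading[:, None] * f[None, :] + np.sqrt(1 - loading[:, None] ** 2) * eps
    if n_de_genes > 0 and effect_size != 0:
        values[:n_de_genes, :n_case] += effect_size
    return ExpressionMatrix(genes=genes, samples=samples, values=values,
                            groups=groups)
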