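"""Node and molecule embeddings.

Gene and disease networks are embedded with node2vec: second-order biased
random walks over the unsigned, undirected view of the graph (signs matter
only in diffusion, not here), followed by skip-gram with negative sampling
treating walks as sentences and nodes as words.  The skip-gram trainer is a
vectorised NumPy implementation of SGNS, fully seeded.

Molecules are embedded by a deterministic structural fingerprint: the
SMILES is canonicalised, then hashed circular atom environments (radius 2)
are counted into ``dim`` buckets and L2-normalised — a pure function of the
molecular graph.  Precomputed vectors can be supplied instead through an
``EmbeddingTable`` provider.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .types import (DiseaseHierarchy, DrugRecord, EmbeddingTable,
                    SignedNetwork, ValidationError)

logger = logging.getLogger("drugwalk")


@dataclass
class Node2VecParams:
    dim: int = 300
    walks_per_node: int = 20
    walk_length: int = 40
    return_p: float = 1.0
    in_out_q: float = 1.0
    window: int = 5
    epochs: int = 5
    negatives: int = 5
    lr: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if min(self.dim, self.walks_per_node, self.walk_length,
               self.window, self.epochs) < 1:
            raise ValueError("dim, walks, length, window, epochs must be positive")
        if self.return_p <= 0 or self.in_out_q <= 0:
            raise ValueError("p and q must be > 0")


@dataclass
class WalkCorpus:
    sentences: List[List[str]]
    provenance: Dict = field(default_factory=dict)


def _neighbor_map(network: Union[SignedNetwork, DiseaseHierarchy]) -> Dict[str, List[str]]:
    """Unsigned, undirected adjacency with sorted neighbor lists (deterministic)."""
    if isinstance(network, SignedNetwork):
        pairs = [(s, t) for s, t, _ in network.edges]
        nodes = set(network.nodes)
    else:
        pairs = list(network.edges)
        nodes = set(network.terms)
    adj: Dict[str, set] = {v: set() for v in nodes}
    for a, b in pairs:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return {v: sorted(ns) for v, ns in adj.items()}


def generate_walks(network: Union[SignedNetwork, DiseaseHierarchy],
                   params: Node2VecParams, seed: Optional[int] = None) -> WalkCorpus:
    """Second-order biased walks: from previous node t at current v, the
    unnormalised weight to neighbor x is 1/p if x == t, 1 if x is adjacent
    to t, 1/q otherwise.  Every node starts exactly ``walks_per_node``
    walks; isolated nodes yield length-1 walks.
    """
    adj = _neighbor_map(network)
    if not adj:
        raise ValidationError("cannot walk an empty network")
    adj_sets = {v: set(ns) for v, ns in adj.items()}
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p, q = params.return_p, params.in_out_q
    sentences = []
    n_isolated = 0
    for start in sorted(adj):
        for _ in range(params.walks_per_node):
            walk = [start]
            if not adj[start]:
                n_isolated += 1
                sentences.append(walk)
                continue
            current = start
            prev = None
            while len(walk) < params.walk_length:
                neighbors = adj[current]
                if not neighbors:
                    break  # sink truncates (directed graphs only)
                if prev is None or (p == 1.0 and q == 1.0):
                    nxt = neighbors[int(rng.integers(len(neighbors)))]
                else:
                    w = np.empty(len(neighbors))
                    prev_adj = adj_sets[prev]
                    for i, x in enumerate(neighbors):
                        if x == prev:
                            w[i] = 1.0 / p
                        elif x in prev_adj:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / q
                    w /= w.sum()
                    nxt = neighbors[int(rng.choice(len(neighbors), p=w))]
                walk.append(nxt)
                prev, current = current, nxt
            sentences.append(walk)
    if n_isolated:
        logger.warning("%d isolated-node walks of length 1", n_isolated)
    return WalkCorpus(sentences=sentences,
                      provenance={"n_nodes": len(adj), "params": params})


def train_skipgram(corpus: WalkCorpus, params: Node2VecParams) -> EmbeddingTable:
    """Skip-gram with negative sampling over the walk corpus.

    Linear learning-rate decay, unigram^0.75 negative distribution, one
    vector per node that appears in the corpus (input vectors reported).
    """
    if not corpus.sentences:
        raise ValidationError("empty walk corpus")
    vocab = sorted({w for s in corpus.sentences for w in s})
    w2i = {w: i for i, w in enumerate(vocab)}
    V, d = len(vocab), params.dim

    counts = np.zeros(V)
    pairs_c, pairs_o = [], []
    for sent in corpus.sentences:
        ids = [w2i[w] for w in sent]
        for i, c in enumerate(ids):
            counts[c] += 1
            lo = max(0, i - params.window)
            hi = min(len(ids), i + params.window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs_c.append(c)
                    pairs_o.append(ids[j])
    pairs_c = np.asarray(pairs_c, dtype=np.int64)
    pairs_o = np.asarray(pairs_o, dtype=np.int64)

    rng = np.random.default_rng(params.seed)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    if len(pairs_c) == 0:  # degenerate: only length-1 sentences
        return EmbeddingTable({w: W_in[w2i[w]].copy() for w in vocab})

    noise = counts ** 0.75
    noise /= noise.sum()
    k = params.negatives
    # modest batches keep the accumulated-gradient approximation of
    # sequential SGD stable when the vocabulary is small (repeated indices)
    batch = 256
    n_pairs = len(pairs_c)
    total_steps = params.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            lr = params.lr * max(1e-4, 1.0 - step / total_steps)
            step += 1
            idx = order[s:s + batch]
            c, o = pairs_c[idx], pairs_o[idx]
            neg = rng.choice(V, size=(len(idx), k), p=noise)
            vin = W_in[c]                                  # B x d
            # positive pair
            z = np.clip(np.einsum("bd,bd->b", vin, W_out[o]), -8.0, 8.0)
            g = (1.0 / (1.0 + np.exp(-z)) - 1.0)           # sigma(z) - 1
            d_in = g[:, None] * W_out[o]
            np.add.at(W_out, o, -lr * g[:, None] * vin)
            # negatives
            zn = np.clip(np.einsum("bd,bkd->bk", vin, W_out[neg]), -8.0, 8.0)
            gn = 1.0 / (1.0 + np.exp(-zn))                 # sigma(z) - 0
            d_in += np.einsum("bk,bkd->bd", gn, W_out[neg])
            np.add.at(W_out, neg.ravel(),
                      (-lr * gn[:, :, None] * vin[:, None, :]).reshape(-1, d))
            np.add.at(W_in, c, -lr * d_in)
    return EmbeddingTable({w: W_in[w2i[w]].copy() for w in vocab})


def embed_network(network: Union[SignedNetwork, DiseaseHierarchy],
                  params: Node2VecParams) -> EmbeddingTable:
    """node2vec: walk corpus + skip-gram; covers every node that appears in a walk."""
    corpus = generate_walks(network, params)
    return train_skipgram(corpus, params)


# ---------------------------------------------------------------------------
# Molecular embedding providers
# ---------------------------------------------------------------------------

def embed_molecule(drug: DrugRecord, dim: int = 300,
                   provider: str = "fingerprint",
                   table: Optional[EmbeddingTable] = None) -> np.ndarray:
    """300-d (by default) vector for a drug molecule.

    provider="fingerprint": canonical SMILES -> hashed circular-environment
    count fingerprint (radius 2) folded into ``dim`` buckets, L2-normalised.
    provider="table": look the drug up in a precomputed EmbeddingTable.
    """
    if provider == "table":
        if table is None or drug.drug_id not in table:
            raise ValidationError(f"no precomputed embedding for {drug.drug_id!r}")
        return np.asarray(table[drug.drug_id], dtype=float)
    if provider != "fingerprint":
        raise ValueError(f"unknown provider {provider!r}")
    if drug.smiles is None:
        if drug.embedding is not None:
            return np.asarray(drug.embedding, dtype=float)
        raise ValidationError(f"drug {drug.drug_id!r} has no SMILES and no embedding")
    return fingerprint_embedding(drug.smiles, dim)


def fingerprint_embedding(smiles: str, dim: int) -> np.ndarray:
    """Hashed Morgan (ECFP-like, radius 2) count fingerprint of the canonical molecule."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    # round-trip through canonical SMILES so spelling variants hash identically
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=dim)
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(dim)
    for bit, count in fp.GetNonzeroElements().items():
        vec[bit] = count
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec
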