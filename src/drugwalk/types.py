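"""Domain types shared across the pipeline.

The pipeline moves a drug's effect through three representations: a set of
signed targets on a gene network, a diffusion profile (per-gene accumulated
perturbation values over a fixed gene universe), and finally a match score
against a disease embedding.  The types here are deliberately thin —
validated containers, no behaviour beyond invariant checks.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("drugwalk")

ACTIVATION = "activation"
INHIBITION = "inhibition"
IRRELEVANT = "irrelevant"

#: canonical 3-class ordering used by the target classifier output layer
TARGET_CLASSES = (ACTIVATION, INHIBITION, IRRELEVANT)

SIGN_SYNONYMS = {
    "+1": 1, "1": 1, "activation": 1, "act": 1,
    "-1": -1, "−1": -1, "inhibition": -1, "inh": -1,
}


class ValidationError(ValueError):
    """Raised when an input violates a type invariant."""


@dataclass
class SignedNetwork:
    """Gene-interaction graph with activation (+1) / inhibition (-1) edges."""

    nodes: set
    edges: List[Tuple[str, str, int]]
    directed: bool = False

    def __post_init__(self):
        seen = {}
        for s, t, g in self.edges:
            if g not in (1, -1):
                raise ValidationError(f"edge ({s},{t}) has invalid sign {g!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValidationError(f"edge ({s},{t}) endpoint not in node set")
            if (s, t) in seen:
                logger.warning("duplicate edge (%s,%s): last occurrence wins", s, t)
            seen[(s, t)] = g
        if len(seen) != len(self.edges):
            self.edges = [(s, t, g) for (s, t), g in seen.items()]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> Dict[str, List[Tuple[str, int]]]:
        """Per-node incident edge list as (neighbor, sign).

        For directed networks only out-edges are walkable; undirected
        networks list each edge from both endpoints.
        """
        adj: Dict[str, List[Tuple[str, int]]] = {v: [] for v in self.nodes}
        for s, t, g in self.edges:
            adj[s].append((t, g))
            if not self.directed:
                adj[t].append((s, g))
        return adj

    def inhibitory_fraction(self) -> float:
        if not self.edges:
            return 0.0
        return sum(1 for _, _, g in self.edges if g == -1) / len(self.edges)


@dataclass
class GeneUniverse:
    """Ordered gene list; position defines the index in every profile vector."""

    genes: List[str]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene universe contains duplicates")
        if not self.genes:
            raise ValidationError("gene universe is empty")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        return self._index[gene]


@dataclass
class EmbeddingTable:
    """Identifier -> fixed-dimension real vector."""

    vectors: Dict[str, np.ndarray]

    def __post_init__(self):
        dims = set()
        for k, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"non-finite embedding for {k!r}")
            self.vectors[k] = v
            dims.add(v.shape[0])
        if len(dims) > 1:
            raise ValidationError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self.dim = dims.pop() if dims else 0

    def __getitem__(self, key: str) -> np.ndarray:
        return self.vectors[key]

    def __contains__(self, key: str) -> bool:
        return key in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def keys(self):
        return self.vectors.keys()


@dataclass
class DrugRecord:
    drug_id: str
    smiles: Optional[str] = None
    targets: List[Tuple[str, str]] = field(default_factory=list)  # (gene, mode)
    embedding: Optional[np.ndarray] = None

    def __post_init__(self):
        genes = [g for g, _ in self.targets]
        if len(set(genes)) != len(genes):
            raise ValidationError(f"drug {self.drug_id}: duplicate target genes")
        for g, mode in self.targets:
            if mode not in (ACTIVATION, INHIBITION):
                raise ValidationError(f"drug {self.drug_id}: invalid mode {mode!r}")

    def seed_set(self) -> List[Tuple[str, int]]:
        """Targets as (gene, ±1) pairs, the diffusion start points."""
        return [(g, 1 if m == ACTIVATION else -1) for g, m in self.targets]


@dataclass
class DrugTargetRecord:
    drug_id: str
    gene_id: str
    label: str

    def __post_init__(self):
        if self.label not in TARGET_CLASSES:
            raise ValidationError(f"invalid drug-target label {self.label!r}")


@dataclass
class DiseaseHierarchy:
    """Tree-structured disease vocabulary (MeSH-like); edges are parent-child."""

    terms: List[str]
    edges: List[Tuple[str, str]]

    def __post_init__(self):
        term_set = set(self.terms)
        if len(term_set) != len(self.terms):
            raise ValidationError("duplicate disease terms")
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on term {a!r}")
            if a not in term_set or b not in term_set:
                raise ValidationError(f"edge ({a},{b}) references unknown term")


@dataclass
class DDIRecord:
    """Drug(-combination)-disease interaction instance.

    ``drug_ids`` holds one drug for single-drug records and two or more for
    combination-therapy records.
    """

    drug_ids: List[str]
    disease_id: str
    label: str  # "positive" | "negative"

    def __post_init__(self):
        if not self.drug_ids:
            raise ValidationError("DDI record with empty drug list")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValidationError("duplicate drugs within one DDI record")
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"invalid DDI label {self.label!r}")

    def key(self) -> Tuple[Tuple[str, ...], str]:
        return (tuple(sorted(self.drug_ids)), self.disease_id)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with case/control sample groups."""

    genes: List[str]
    samples: List[str]
    values: np.ndarray
    groups: Dict[str, str]  # sample -> "case" | "control"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples")
        for s in self.samples:
            if self.groups.get(s) not in ("case", "control"):
                raise ValidationError(f"sample {s!r} missing case/control assignment")
        # rows with missing values are dropped, not imputed
        bad = ~np.all(np.isfinite(self.values), axis=1)
        if bad.any():
            kept = [g for g, b in zip(self.genes, bad) if not b]
            logger.warning("dropping %d genes with missing values", int(bad.sum()))
            self.values = self.values[~bad]
            self.genes = kept

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        return self.values[:, idx]


@dataclass
class RunConfig:
    """Every stage hyperparameter, with pipeline defaults.

    Defaults are the published operating point of the method: diffusion
    restart 0.3 / decay 0.95 with 15 epochs of 15 steps; 300-d node
    embeddings from 20 walks of length 40 per node with p=q=1; target-caller
    thresholds 0.88 (inhibition) / 0.44 (activation); a 10:1
    negative:positive sampling ratio with an 80/20 split and SMOTE (k=5) on
    the training portion only.
    """

    # diffusion
    alpha: float = 0.3
    beta: float = 0.95
    walk_epochs: int = 15
    walk_steps: int = 15
    # node embedding
    embed_dim: int = 300
    walks_per_node: int = 20
    walk_length: int = 40
    return_p: float = 1.0
    in_out_q: float = 1.0
    window: int = 5
    sg_epochs: int = 5
    # target net
    target_hidden: int = 1024
    target_dropout: float = 0.2
    focal_gamma: float = 2.0
    target_lr: float = 1e-4
    target_wd: float = 1e-3
    target_epochs: int = 100
    target_batch: int = 256
    inhib_threshold: float = 0.88
    act_threshold: float = 0.44
    # ddi net
    ddi_hidden: Tuple[int, ...] = (4096, 1024, 256, 64)
    ddi_dropout: float = 0.5
    ddi_lr: float = 1e-3
    ddi_wd: float = 1e-3
    ddi_epochs: int = 50
    ddi_batch: int = 512
    # sampling
    neg_ratio: int = 10
    train_frac: float = 0.8
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.alpha < 1):
            raise ValidationError("alpha must be in [0,1)")
        if not (0 < self.beta < 1):
            raise ValidationError("beta must be in (0,1)")
        if not (0 < self.train_frac < 1):
            raise ValidationError("train_frac must be in (0,1)")
        for name in ("walk_epochs", "walk_steps", "embed_dim", "walks_per_node",
                     "walk_length", "window", "sg_epochs", "target_hidden",
                     "target_epochs", "target_batch", "ddi_epochs", "ddi_batch",
                     "neg_ratio", "smote_k"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("target_dropout", "ddi_dropout"):
            if not (0 <= getattr(self, name) < 1):
                raise ValidationError(f"{name} must be in [0,1)")
        if not (0 < self.inhib_threshold < 1 and 0 < self.act_threshold < 1):
            raise ValidationError("call thresholds must be in (0,1)")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
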