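"""Drug-target interaction calling: activation / inhibition / irrelevant.

A drug-gene pair is featurised by concatenating the 300-d drug embedding
and the 300-d gene embedding (drug first).  A three-layer fully connected
network (600 -> 1024 -> 3, ELU, batch norm, 20% dropout) trained with focal
loss — cross-entropy modulated by (1-p_t)^gamma to keep the rare activation
class from being drowned out — produces class probabilities by softmax.

Calls are thresholded asymmetrically: inhibition requires p >= 0.88,
activation p >= 0.44, checked inhibition-first (the stricter threshold);
pairs clearing neither threshold get no call.  The resulting signed target
set is what diffusion consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import MLP, focal_loss, softmax, train_mlp
from .types import (ACTIVATION, INHIBITION, IRRELEVANT, TARGET_CLASSES,
                    DrugRecord, DrugTargetRecord, EmbeddingTable,
                    ValidationError)

logger = logging.getLogger("drugwalk")


@dataclass
class TargetNetConfig:
    input_dim: int = 600
    hidden: int = 1024
    dropout: float = 0.2
    lr: float = 1e-4
    weight_decay: float = 1e-3
    epochs: int = 100
    batch_size: int = 256
    focal_gamma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0,1)")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be >= 0")


@dataclass
class CallThresholds:
    inhibition: float = 0.88
    activation: float = 0.44
    order: str = "inh-first"  # or "act-first"

    def __post_init__(self):
        if not (0 < self.inhibition < 1 and 0 < self.activation < 1):
            raise ValueError("thresholds must be in (0,1)")
        if self.order not in ("inh-first", "act-first"):
            raise ValueError("order must be 'inh-first' or 'act-first'")


@dataclass
class TargetModel:
    net: MLP
    config: TargetNetConfig
    loss_trace: List[float]

    def predict_probs(self, features: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, rows ordered (activation, inhibition, irrelevant)."""
        return softmax(self.net.predict(np.atleast_2d(features)))


def build_pair_features(drug_vec: np.ndarray, gene_vec: np.ndarray) -> np.ndarray:
    """Concatenate drug embedding then gene embedding into one pair feature."""
    drug_vec = np.asarray(drug_vec, dtype=float)
    gene_vec = np.asarray(gene_vec, dtype=float)
    if drug_vec.ndim != 1 or gene_vec.ndim != 1 or drug_vec.shape != gene_vec.shape:
        raise ValidationError(
            f"drug/gene embedding dims {drug_vec.shape} vs {gene_vec.shape} "
            "must be equal 1-d vectors")
    if not (np.all(np.isfinite(drug_vec)) and np.all(np.isfinite(gene_vec))):
        raise ValidationError("non-finite embedding in pair features")
    return np.concatenate([drug_vec, gene_vec])


def _features_and_labels(records: Sequence[DrugTargetRecord],
                         drug_table: EmbeddingTable,
                         gene_table: EmbeddingTable):
    X, y = [], []
    class_index = {c: i for i, c in enumerate(TARGET_CLASSES)}
    for r in records:
        if r.drug_id not in drug_table:
            raise ValidationError(f"record references unknown drug {r.drug_id!r}")
        if r.gene_id not in gene_table:
            raise ValidationError(f"record references unknown gene {r.gene_id!r}")
        X.append(build_pair_features(drug_table[r.drug_id], gene_table[r.gene_id]))
        y.append(class_index[r.label])
    return np.asarray(X), np.asarray(y, dtype=int)


def train_target_net(records: Sequence[DrugTargetRecord],
                     drug_table: EmbeddingTable, gene_table: EmbeddingTable,
                     config: Optional[TargetNetConfig] = None) -> TargetModel:
    """Train the 3-class pair classifier; requires every class in the data."""
    config = config or TargetNetConfig()
    X, y = _features_and_labels(records, drug_table, gene_table)
    present = set(int(c) for c in np.unique(y))
    if present != {0, 1, 2}:
        missing = [TARGET_CLASSES[i] for i in {0, 1, 2} - present]
        raise ValidationError(f"training data lacks class(es): {missing}")
    net = MLP([config.input_dim, config.hidden, 3], activation="elu",
              dropout=config.dropout, batchnorm=True, seed=config.seed)
    trace = train_mlp(net, X, y, loss="focal", lr=config.lr,
                      weight_decay=config.weight_decay, epochs=config.epochs,
                      batch_size=config.batch_size, seed=config.seed,
                      gamma=config.focal_gamma)
    logger.info("target net trained: loss %.4f -> %.4f", trace[0], trace[-1])
    return TargetModel(net=net, config=config, loss_trace=trace)


def call_from_probs(p_act: float, p_inh: float,
                    thresholds: CallThresholds) -> Optional[str]:
    """Threshold rule for one pair; None means no call."""
    if thresholds.order == "inh-first":
        if p_inh >= thresholds.inhibition:
            return INHIBITION
        if p_act >= thresholds.activation:
            return ACTIVATION
    else:
        if p_act >= thresholds.activation:
            return ACTIVATION
        if p_inh >= thresholds.inhibition:
            return INHIBITION
    return None


def call_targets(model: TargetModel, drug_vec: np.ndarray,
                 gene_table: EmbeddingTable,
                 thresholds: Optional[CallThresholds] = None,
                 genes: Optional[Sequence[str]] = None) -> List[Tuple[str, str]]:
    """Predicted signed target set of a drug over the gene table.

    Output order follows sorted gene id, so it is invariant to the
    caller's gene ordering.
    """
    thresholds = thresholds or CallThresholds()
    gene_ids = sorted(genes) if genes is not None else sorted(gene_table.keys())
    feats = np.stack([build_pair_features(drug_vec, gene_table[g]) for g in gene_ids])
    probs = model.predict_probs(feats)
    out = []
    for g, (p_act, p_inh, _) in zip(gene_ids, probs):
        mode = call_from_probs(float(p_act), float(p_inh), thresholds)
        if mode is not None:
            out.append((g, mode))
    return out


def merge_with_curated(predicted: Sequence[Tuple[str, str]],
                       curated: Sequence[Tuple[str, str]]) -> List[Tuple[str, str]]:
    """Curated targets override predicted calls for the same gene."""
    merged = dict(predicted)
    merged.update(dict(curated))
    return sorted(merged.items())
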