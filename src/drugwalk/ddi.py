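"""Drug-disease interaction scoring.

Feature rows concatenate a drug's diffusion profile (over the gene
universe) with the disease embedding.  Known interactions are the
positives; negatives are sampled uniformly from the unknown drug x disease
pairs at 10 negatives per positive.  The merged set is split 80/20, the
training portion is rebalanced (SMOTE by default — synthetic positives
interpolated between nearest minority neighbours), and a 6-layer fully
connected network (hidden 4096/1024/256/64, leaky ReLU, batch norm, 50%
dropout, BCE-with-logits, Adam with lr = weight decay = 1e-3) produces a
match score whose sign is the decision: > 0 effective, < 0 unrelated.
The per-epoch checkpoint with the highest validation F1 is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .evaluation import compute_metrics
from .nn import MLP, train_mlp
from .types import DDIRecord, ValidationError

logger = logging.getLogger("drugwalk")


@dataclass
class DDINetConfig:
    input_dim: int = 19277  # |universe| + disease embedding dim at full scale
    hidden: Tuple[int, ...] = (4096, 1024, 256, 64)
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 50
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden sizes must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0,1)")


@dataclass
class SamplingPlan:
    negative_ratio: int = 10
    train_fraction: float = 0.8
    strategy: str = "smote"  # smote | random_down | none
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0,1)")
        if self.strategy not in ("smote", "random_down", "none"):
            raise ValueError(f"unknown balancing strategy {self.strategy!r}")


def sample_negatives(positives: Sequence[DDIRecord], drugs: Sequence[str],
                     diseases: Sequence[str], ratio: int = 10,
                     seed: int = 0) -> List[DDIRecord]:
    """Uniform sample of unknown (drug, disease) pairs, labelled negative.

    The pool is every drug x disease pair not among the positives; exactly
    ratio * n_positives pairs are drawn without replacement.
    """
    pos_keys = {(r.drug_ids[0], r.disease_id) for r in positives}
    pool = [(d, z) for d in sorted(drugs) for z in sorted(diseases)
            if (d, z) not in pos_keys]
    need = ratio * len(positives)
    if need > len(pool):
        raise ValidationError(
            f"negative pool of {len(pool)} pairs cannot supply {need} negatives")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=need, replace=False)
    return [DDIRecord([pool[i][0]], pool[i][1], "negative") for i in sorted(idx)]


def split_dataset(records: Sequence, train_fraction: float = 0.8,
                  seed: int = 0) -> Tuple[list, list]:
    """Random partition of the merged set (not stratified): round(f*N) train."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train:]]
    return train, val


def smote_upsample(X: np.ndarray, y: np.ndarray, k: int = 5,
                   seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Interpolate synthetic minority rows until the classes balance.

    Each synthetic row is x + lambda * (x_nn - x) for a random minority row
    x, one of its k nearest minority neighbours x_nn (Euclidean), and
    lambda ~ U[0,1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    n_needed = int(abs(counts[1 - minority] - counts[minority]))
    if n_needed == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    if len(Xm) < k + 1:
        raise ValidationError(
            f"minority class has {len(Xm)} rows; SMOTE with k={k} needs at "
            f"least {k + 1} — use a smaller k")
    nn_index = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, neigh = nn_index.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(len(Xm), size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    lam = rng.random(n_needed)
    x = Xm[base]
    x_nn = Xm[neigh[base, pick]]
    synth = x + lam[:, None] * (x_nn - x)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out


def random_downsample(X: np.ndarray, y: np.ndarray,
                      seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Drop majority rows uniformly until the classes balance."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(y == majority)
    keep = rng.choice(maj_idx, size=counts[minority], replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(y == minority), keep]))
    return X[idx], y[idx]


def balance_training_set(X: np.ndarray, y: np.ndarray,
                         plan: SamplingPlan) -> Tuple[np.ndarray, np.ndarray]:
    if plan.strategy == "smote":
        return smote_upsample(X, y, k=plan.smote_k, seed=plan.seed)
    if plan.strategy == "random_down":
        return random_downsample(X, y, seed=plan.seed)
    return X, y


def build_feature_rows(records: Sequence[DDIRecord],
                       profiles: Dict[str, np.ndarray],
                       disease_emb: Dict[str, np.ndarray]):
    """FeatureRow matrix: [diffusion profile | disease embedding], label 1/0."""
    X, y, keys = [], [], []
    for r in records:
        if len(r.drug_ids) == 1:
            prof = profiles[r.drug_ids[0]]
        else:  # combination rows use the precomputed combination profile
            prof = profiles[";".join(sorted(r.drug_ids))]
        X.append(np.concatenate([prof, disease_emb[r.disease_id]]))
        y.append(1 if r.label == "positive" else 0)
        keys.append(r.key())
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite value in feature rows")
    return X, np.asarray(y, dtype=int), keys


@dataclass
class DDIModel:
    net: MLP
    config: DDINetConfig
    best_epoch: int
    best_val_f1: float
    loss_trace: List[float] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Raw logits; > 0 means predicted effective."""
        return self.net.predict(np.atleast_2d(X)).ravel()


def train_ddi_net(X_train: np.ndarray, y_train: np.ndarray,
                  X_val: np.ndarray, y_val: np.ndarray,
                  config: Optional[DDINetConfig] = None,
                  selection: str = "train") -> DDIModel:
    """Train the scorer, keeping the per-epoch checkpoint with the best F1.

    ``selection`` names the set the checkpoint F1 is computed on: "train"
    (default — keeps the validation metrics untouched by model selection)
    or "val".
    """
    config = config or DDINetConfig()
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training set contains a single class")
    if selection not in ("train", "val"):
        raise ValueError("selection must be 'train' or 'val'")
    sizes = [config.input_dim, *config.hidden, 1]
    net = MLP(sizes, activation="leaky_relu", dropout=config.dropout,
              batchnorm=True, seed=config.seed)
    best = {"f1": -1.0, "epoch": -1, "state": None}
    X_sel, y_sel = (X_train, y_train) if selection == "train" else (X_val, y_val)

    def checkpoint(epoch, model):
        scores = model.predict(X_sel).ravel()
        f1 = compute_metrics(scores, y_sel, threshold=0.0).f1
        if f1 > best["f1"]:
            best.update(f1=f1, epoch=epoch, state=model.state_dict())

    trace = train_mlp(net, X_train, y_train, loss="bce", lr=config.lr,
                      weight_decay=config.weight_decay, epochs=config.epochs,
                      batch_size=config.batch_size, seed=config.seed,
                      epoch_callback=checkpoint)
    net.load_state_dict(best["state"])
    logger.info("ddi net: best %s F1 %.4f at epoch %d", selection,
                best["f1"], best["epoch"])
    return DDIModel(net=net, config=config, best_epoch=best["epoch"],
                    best_val_f1=best["f1"], loss_trace=trace)


def score_pair(model: DDIModel, profile: np.ndarray,
               disease_vec: np.ndarray) -> float:
    """Match score of one drug profile against one disease embedding."""
    return float(model.score(np.concatenate([profile, disease_vec]))[0])
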