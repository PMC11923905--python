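"""Combination-therapy scoring, perturbation controls, and few-shot fine-tuning.

A combination is scored by diffusing every member drug into one shared
accumulator (see ``diffusion.diffuse_combination``) and passing the joint
profile to the single-drug scorer.  Two controls probe the score: the mean
of the members' individual scores, and a perturbed combination in which one
member is swapped for a random pool drug.  Because labelled combinations
are scarce, the single-drug model is fine-tuned few-shot: one perturbed
negative per positive combination, split ~3:1 into train/validation
(225/76 at the published scale), continuing training at a reduced learning
rate with best-validation-F1 checkpoint selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .ddi import DDIModel, DDINetConfig, score_pair
from .diffusion import DiffusionConfig, diffuse_combination
from .evaluation import compute_metrics, paired_test
from .nn import train_mlp
from .types import DDIRecord, GeneUniverse, SignedNetwork, ValidationError

logger = logging.getLogger("drugwalk")


@dataclass
class ComboExperimentConfig:
    train_size: int = 225
    val_size: int = 76
    finetune_epochs: int = 20
    finetune_lr: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.train_size < 1 or self.val_size < 1:
            raise ValueError("split sizes must be positive")


def combination_profile(network: SignedNetwork,
                        target_sets: Mapping[str, Sequence[Tuple[str, int]]],
                        drug_ids: Sequence[str], config: DiffusionConfig,
                        universe: GeneUniverse) -> np.ndarray:
    missing = [d for d in drug_ids if d not in target_sets or not target_sets[d]]
    if missing:
        raise ValidationError(f"no target set for drug(s) {missing}")
    return diffuse_combination(network, {d: target_sets[d] for d in drug_ids},
                               config, universe)


def score_combination(model: DDIModel, network: SignedNetwork,
                      combo: DDIRecord,
                      target_sets: Mapping[str, Sequence[Tuple[str, int]]],
                      disease_vec: np.ndarray, diffusion_config: DiffusionConfig,
                      universe: GeneUniverse) -> float:
    """Direct score of a combination: joint diffusion profile vs the disease."""
    prof = combination_profile(network, target_sets, combo.drug_ids,
                               diffusion_config, universe)
    return score_pair(model, prof, disease_vec)


def average_single_scores(model: DDIModel, profiles: Mapping[str, np.ndarray],
                          drug_ids: Sequence[str],
                          disease_vec: np.ndarray) -> float:
    """Arithmetic mean of the member drugs' individual scores."""
    return float(np.mean([score_pair(model, profiles[d], disease_vec)
                          for d in drug_ids]))


def perturb_combination(combo: DDIRecord, drug_pool: Sequence[str],
                        seed: int = 0,
                        forbidden: Optional[set] = None,
                        max_tries: int = 1000) -> DDIRecord:
    """Replace one random member with a random pool drug outside the combo.

    ``forbidden`` is a set of combination keys the result must avoid
    (used when perturbations serve as negative samples).
    """
    rng = np.random.default_rng(seed)
    pool = sorted(set(drug_pool) - set(combo.drug_ids))
    if not pool:
        raise ValidationError("drug pool has no replacement candidates")
    for _ in range(max_tries):
        pos = int(rng.integers(len(combo.drug_ids)))
        repl = pool[int(rng.integers(len(pool)))]
        new_drugs = list(combo.drug_ids)
        new_drugs[pos] = repl
        rec = DDIRecord(new_drugs, combo.disease_id, "negative")
        if forbidden is None or rec.key() not in forbidden:
            return rec
    raise ValidationError("could not find a non-colliding perturbation")


def make_finetune_dataset(positive_combos: Sequence[DDIRecord],
                          drug_pool: Sequence[str], seed: int = 0,
                          train_size: Optional[int] = None,
                          val_size: Optional[int] = None
                          ) -> Tuple[List[DDIRecord], List[DDIRecord]]:
    """One perturbed negative per positive, then a combo-level train/val split.

    Splits of 225/76 at the published scale; smaller sets fall back to a
    75/25 split.  Negatives never collide with any positive combination.
    """
    if not positive_combos:
        raise ValidationError("no positive combinations to fine-tune on")
    pos_keys = {c.key() for c in positive_combos}
    rng = np.random.default_rng(seed)
    pairs = []
    for i, combo in enumerate(positive_combos):
        pos = DDIRecord(list(combo.drug_ids), combo.disease_id, "positive")
        neg = perturb_combination(combo, drug_pool,
                                  seed=int(rng.integers(2 ** 31)),
                                  forbidden=pos_keys)
        pairs.append((pos, neg))
    n = len(pairs)
    if train_size is None or val_size is None or train_size + val_size > n:
        train_size = int(round(0.75 * n))
    order = rng.permutation(n)
    train, val = [], []
    for j, i in enumerate(order):
        (train if j < train_size else val).extend(pairs[i])
    return train, val


def finetune(model: DDIModel, X_train: np.ndarray, y_train: np.ndarray,
             X_val: np.ndarray, y_val: np.ndarray,
             config: Optional[ComboExperimentConfig] = None) -> DDIModel:
    """Continue training on combination rows; all layers update at the
    reduced fine-tune learning rate; best-validation-F1 checkpoint wins."""
    config = config or ComboExperimentConfig()
    net = model.net.clone()
    if config.finetune_epochs == 0:
        return DDIModel(net=net, config=model.config, best_epoch=-1,
                        best_val_f1=compute_metrics(net.predict(X_val).ravel(),
                                                    y_val).f1)
    best = {"f1": -1.0, "epoch": -1, "state": None}

    def checkpoint(epoch, m):
        f1 = compute_metrics(m.predict(X_val).ravel(), y_val, threshold=0.0).f1
        if f1 > best["f1"]:
            best.update(f1=f1, epoch=epoch, state=m.state_dict())

    trace = train_mlp(net, X_train, y_train, loss="bce",
                      lr=config.finetune_lr,
                      weight_decay=model.config.weight_decay,
                      epochs=config.finetune_epochs,
                      batch_size=min(model.config.batch_size, max(8, len(y_train))),
                      seed=config.seed, epoch_callback=checkpoint)
    net.load_state_dict(best["state"])
    logger.info("fine-tune: best val F1 %.4f at epoch %d", best["f1"], best["epoch"])
    return DDIModel(net=net, config=model.config, best_epoch=best["epoch"],
                    best_val_f1=best["f1"], loss_trace=trace)


def paired_combo_comparison(a_scores: Sequence[float], b_scores: Sequence[float],
                            test: str = "sign") -> Tuple[List[Tuple[float, float]], float]:
    """Per-combo score pairs plus a paired-test p-value (a greater than b)."""
    pairs = list(zip(a_scores, b_scores))
    p = paired_test(a_scores, b_scores, test=test, alternative="greater")
    return pairs, p
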