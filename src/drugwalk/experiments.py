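"""End-to-end experiment harness on the planted synthetic world.

These functions wire the pipeline stages together at desk scale: a
220-node signed network whose first 200 nodes form the gene universe (the
remaining 20 model signaling nodes outside the universe), 60 drugs with 3
signed targets each, 20 diseases with sparse planted signatures, every
drug x disease pair labelled through the diffusion oracle, and 80 positive
combination therapies.  All stochastic steps derive from a single seed.

The scorer here runs with hidden layers (256, 64, 32, 16) — the published
architecture's shape scaled to the 400-d synthetic feature space — and 40
training epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import ddi
from .combination import (ComboExperimentConfig, finetune,
                          make_finetune_dataset)
from .ddi import (DDIModel, DDINetConfig, SamplingPlan, balance_training_set,
                  build_feature_rows, sample_negatives, split_dataset,
                  train_ddi_net)
from .diffusion import DiffusionConfig, diffuse_combination, diffuse_drug
from .evaluation import MetricReport, compute_metrics
from .synth import PlantedWorld, gen_drugs, gen_planted_ddi, gen_signed_network
from .types import DDIRecord, GeneUniverse, SignedNetwork


def make_world(seed: int = 0, n_universe: int = 200, n_extra_nodes: int = 20,
               n_edges: int = 660, inhib_frac: float = 0.19,
               n_drugs: int = 60, targets_per_drug: int = 3,
               n_diseases: int = 20, pos_quantile: float = 0.93,
               label_noise: float = 0.01, n_combos: int = 80,
               n_families: int = 12, n_prototypes: int = 5,
               diffusion: Optional[DiffusionConfig] = None) -> PlantedWorld:
    """Standard planted world.

    The inhibitory fraction mirrors curated signaling maps (roughly one
    inhibition per four activations); drugs fall into 12 families with
    overlapping target pools and diseases into 5 prototype groups, the
    similarity structure (drug classes, related conditions) that real
    drug-disease data carries and pair-based scoring relies on.
    """
    n_nodes = n_universe + n_extra_nodes
    network = gen_signed_network(n_nodes, n_edges, inhib_frac=inhib_frac,
                                 model="erdos", seed=seed)
    universe = GeneUniverse(sorted(network.nodes)[:n_universe])
    drugs = gen_drugs(n_drugs, targets_per_drug, network,
                      inhib_target_frac=0.3, seed=seed + 1,
                      n_families=n_families)
    config = diffusion or DiffusionConfig(seed=seed)
    return gen_planted_ddi(network, drugs, n_diseases,
                           pos_quantile=pos_quantile, label_noise=label_noise,
                           config=config, seed=seed + 2, universe=universe,
                           n_combos=n_combos, n_prototypes=n_prototypes)


def monte_carlo_profiles(world: PlantedWorld,
                         config: Optional[DiffusionConfig] = None
                         ) -> Dict[str, np.ndarray]:
    """Per-drug diffusion profiles from the actual stochastic walker."""
    config = config or world.params["diffusion"]
    target_sets = world.target_sets()
    return {d: diffuse_drug(world.network, target_sets[d], config,
                            world.universe, stream_key=d)
            for d in sorted(target_sets)}


def desk_net_config(input_dim: int, seed: int = 0, epochs: int = 150) -> DDINetConfig:
    return DDINetConfig(input_dim=input_dim, hidden=(64, 16),
                        dropout=0.5, lr=1e-3, weight_decay=1e-2,
                        epochs=epochs, batch_size=64, seed=seed)


@dataclass
class ScaledModel:
    """DDI scorer plus the feature standardisation fitted on its training set."""

    model: DDIModel
    mu: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mu) / self.sd

    def score(self, X: np.ndarray) -> np.ndarray:
        return self.model.score(self.transform(X))


def fit_scaler(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


@dataclass
class ExperimentResult:
    model: ScaledModel
    report: MetricReport
    X_val: np.ndarray
    y_val: np.ndarray
    profiles: Dict[str, np.ndarray]


def run_planted_experiment(world: PlantedWorld, seed: int = 0,
                           ratio: int = 10, strategy: str = "smote",
                           permute_labels: bool = False,
                           profiles: Optional[Dict[str, np.ndarray]] = None,
                           epochs: int = 150) -> ExperimentResult:
    """Negative sampling -> split -> balance -> train -> validation metrics.

    ``permute_labels`` shuffles labels within the training and validation
    portions independently (after the split) — the null experiment whose
    AUC should hover at chance.  Permuting before the split would let train
    and validation share the permutation's chance per-drug/per-disease
    positive rates, which any legitimate learner generalises.
    """
    positives = world.positives
    drug_ids = sorted({d.drug_id for d in world.drugs})
    disease_ids = sorted(world.disease_signatures)
    negatives = sample_negatives(positives, drug_ids, disease_ids,
                                 ratio=ratio, seed=seed)
    records = positives + negatives
    if profiles is None:
        profiles = monte_carlo_profiles(world)
    train, val = split_dataset(records, train_fraction=0.8, seed=seed)
    X_tr, y_tr, _ = build_feature_rows(train, profiles, world.disease_embeddings)
    X_val, y_val, _ = build_feature_rows(val, profiles, world.disease_embeddings)
    if permute_labels:
        rng = np.random.default_rng(seed + 1)
        y_tr = rng.permutation(y_tr)
        y_val = rng.permutation(y_val)
    mu, sd = fit_scaler(X_tr)
    plan = SamplingPlan(negative_ratio=ratio, strategy=strategy, seed=seed)
    X_bal, y_bal = balance_training_set((X_tr - mu) / sd, y_tr, plan)
    inner = train_ddi_net(X_bal, y_bal, (X_val - mu) / sd, y_val,
                          desk_net_config(X_tr.shape[1], seed=seed, epochs=epochs))
    model = ScaledModel(inner, mu, sd)
    report = compute_metrics(model.score(X_val), y_val, threshold=0.0)
    return ExperimentResult(model=model, report=report, X_val=X_val,
                            y_val=y_val, profiles=profiles)


def null_auc(world: PlantedWorld, seed: int = 0, n_permutations: int = 20,
             profiles: Optional[Dict[str, np.ndarray]] = None,
             epochs: int = 40) -> float:
    """Mean validation AUC of the label-permuted control over several
    permutation replicates (a single replicate's AUC carries sampling noise
    of about 0.07 at this validation size)."""
    if profiles is None:
        profiles = monte_carlo_profiles(world)
    aucs = [run_planted_experiment(world, seed=seed + 100 * (i + 1),
                                   profiles=profiles, permute_labels=True,
                                   epochs=epochs).report.auc
            for i in range(n_permutations)]
    return float(np.mean(aucs))


def precision_1x_vs_10x(world: PlantedWorld, seed: int = 0,
                        profiles: Optional[Dict[str, np.ndarray]] = None
                        ) -> Tuple[float, float]:
    """Precision of the 1x-trained and 10x-trained models on the same
    1:10-imbalanced validation set (the sampling-protocol comparison)."""
    if profiles is None:
        profiles = monte_carlo_profiles(world)
    res_10x = run_planted_experiment(world, seed=seed, ratio=10,
                                     strategy="smote", profiles=profiles)
    # 1x model: balanced training (equal positives and negatives, no SMOTE)
    positives = world.positives
    drug_ids = sorted({d.drug_id for d in world.drugs})
    disease_ids = sorted(world.disease_signatures)
    neg_1x = sample_negatives(positives, drug_ids, disease_ids, ratio=1,
                              seed=seed + 10)
    train_1x, _ = split_dataset(positives + neg_1x, train_fraction=0.8, seed=seed)
    X_tr, y_tr, _ = build_feature_rows(train_1x, profiles,
                                       world.disease_embeddings)
    mu, sd = fit_scaler(X_tr)
    inner = train_ddi_net((X_tr - mu) / sd, y_tr,
                          (res_10x.X_val - mu) / sd, res_10x.y_val,
                          desk_net_config(X_tr.shape[1], seed=seed))
    model_1x = ScaledModel(inner, mu, sd)
    prec_1x = compute_metrics(model_1x.score(res_10x.X_val), res_10x.y_val).precision
    return prec_1x, res_10x.report.precision


def combination_rows(world: PlantedWorld, records: Sequence[DDIRecord],
                     config: Optional[DiffusionConfig] = None):
    """Feature rows for combination records: joint diffusion profile + disease."""
    config = config or world.params["diffusion"]
    target_sets = world.target_sets()
    profiles = {}
    for r in records:
        key = ";".join(sorted(r.drug_ids))
        if key not in profiles:
            profiles[key] = diffuse_combination(
                world.network, {d: target_sets[d] for d in r.drug_ids},
                config, world.universe)
    return build_feature_rows(records, profiles, world.disease_embeddings)


def fewshot_experiment(world: PlantedWorld, model: ScaledModel, seed: int = 0,
                       config: Optional[ComboExperimentConfig] = None
                       ) -> Tuple[float, float]:
    """(zero-shot F1, fine-tuned F1) on held-out combination therapies.

    Rows are standardised with the single-drug model's scaler, so the
    domain shift the fine-tuning corrects (joint profiles roughly double
    the single-drug scale) is visible to both models equally.
    """
    config = config or ComboExperimentConfig(seed=seed)
    pool = sorted({d.drug_id for d in world.drugs})
    train_recs, val_recs = make_finetune_dataset(world.combos, pool, seed=seed)
    X_tr, y_tr, _ = combination_rows(world, train_recs)
    X_val, y_val, _ = combination_rows(world, val_recs)
    Xt, Xv = model.transform(X_tr), model.transform(X_val)
    zero_f1 = compute_metrics(model.model.score(Xv), y_val, threshold=0.0).f1
    tuned = finetune(model.model, Xt, y_tr, Xv, y_val, config)
    ft_f1 = compute_metrics(tuned.score(Xv), y_val, threshold=0.0).f1
    return zero_f1, ft_f1


def rewire_network(network: SignedNetwork, frac: float = 0.5,
                   seed: int = 0) -> SignedNetwork:
    """Randomly re-place a fraction of edges (signs kept); degrades the
    topology the planted signal diffuses through while preserving size."""
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    edges = list(network.edges)
    existing = {(min(s, t), max(s, t)) for s, t, _ in edges}
    n_rewire = int(round(frac * len(edges)))
    which = rng.choice(len(edges), size=n_rewire, replace=False)
    for i in which:
        s, t, g = edges[i]
        existing.discard((min(s, t), max(s, t)))
        for _ in range(100):
            a, b = rng.choice(len(nodes), size=2, replace=False)
            key = (min(nodes[a], nodes[b]), max(nodes[a], nodes[b]))
            if key not in existing:
                edges[i] = (nodes[a], nodes[b], g)
                existing.add(key)
                break
    return SignedNetwork(nodes=set(nodes), edges=edges, directed=network.directed)


def ablation_fold_f1(world: PlantedWorld, seed: int = 0, k: int = 5,
                     ratio: int = 4) -> Tuple[List[float], List[float]]:
    """K-fold F1 of the full pipeline vs the same pipeline with the
    diffusion profile replaced by the drug's structure-level embedding."""
    from .evaluation import kfold_cv

    profiles = monte_carlo_profiles(world)
    flat = {d.drug_id: np.concatenate(
        [d.embedding, np.zeros(len(world.universe) - len(d.embedding))])
        for d in world.drugs}
    positives = world.positives
    drug_ids = sorted({d.drug_id for d in world.drugs})
    disease_ids = sorted(world.disease_signatures)
    negatives = sample_negatives(positives, drug_ids, disease_ids,
                                 ratio=ratio, seed=seed)
    records = positives + negatives

    def fit_score_factory(feat):
        X, y, _ = build_feature_rows(records, feat, world.disease_embeddings)

        def fit_score(X_tr, y_tr, X_val, fold_seed):
            mu, sd = fit_scaler(X_tr)
            Xb, yb = balance_training_set(
                (X_tr - mu) / sd, y_tr,
                SamplingPlan(strategy="smote", seed=fold_seed))
            m = train_ddi_net(Xb, yb, Xb, yb,
                              desk_net_config(X_tr.shape[1], seed=fold_seed,
                                              epochs=60))
            return m.score((X_val - mu) / sd)
        return X, y, fit_score

    X, y, fs = fit_score_factory(profiles)
    reports_full, _ = kfold_cv(X, y, fs, k=k, seed=seed)
    X2, y2, fs2 = fit_score_factory(flat)
    reports_flat, _ = kfold_cv(X2, y2, fs2, k=k, seed=seed)
    return ([r.f1 for r in reports_full], [r.f1 for r in reports_flat])
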