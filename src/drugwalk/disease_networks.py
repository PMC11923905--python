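"""Disease-specific signed networks from paired case/control expression.

Differentially expressed genes (Welch t-test, Benjamini-Hochberg at 0.05)
are connected by co-expression: every DE gene pair with Pearson correlation
p < 0.05 (and optionally |r| >= 0.5) becomes an undirected edge whose sign
is the sign of the correlation — positive co-expression reads as promotive,
negative as inhibitory.  The resulting network substitutes for the common
signaling network in the diffusion stage; everything downstream is
unchanged, which isolates the effect of the network itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ddi import (DDINetConfig, SamplingPlan, balance_training_set,
                  build_feature_rows, sample_negatives, split_dataset,
                  train_ddi_net)
from .diffusion import DiffusionConfig, diffuse_drug
from .evaluation import compute_metrics
from .types import (DDIRecord, ExpressionMatrix, GeneUniverse, SignedNetwork,
                    ValidationError)

logger = logging.getLogger("drugwalk")


@dataclass
class CorrelationNetworkConfig:
    de_alpha: float = 0.05
    de_adjust: str = "bh"        # "bh" | "raw"
    edge_p: float = 0.05
    r_threshold: float = 0.5     # 0 disables the |r| cutoff
    corr_samples: str = "case"   # "case" | "all"

    def __post_init__(self):
        if not (0 < self.de_alpha < 1 and 0 < self.edge_p < 1):
            raise ValueError("cutoffs must be in (0,1)")
        if self.r_threshold < 0:
            raise ValueError("r threshold must be >= 0")
        if self.de_adjust not in ("bh", "raw"):
            raise ValueError("de_adjust must be 'bh' or 'raw'")
        if self.corr_samples not in ("case", "all"):
            raise ValueError("corr_samples must be 'case' or 'all'")


def differential_genes(expr: ExpressionMatrix,
                       config: Optional[CorrelationNetworkConfig] = None) -> List[str]:
    """DE genes by Welch two-sample t-test, ordered by (adjusted) p ascending."""
    config = config or CorrelationNetworkConfig()
    case = expr.group_columns("case")
    ctrl = expr.group_columns("control")
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group for the t-test")
    _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance-in-both-groups genes
    if config.de_adjust == "bh":
        p_used = multipletests(p, method="fdr_bh")[1]
    else:
        p_used = p
    selected = [(p_used[i], expr.genes[i]) for i in range(len(expr.genes))
                if p_used[i] < config.de_alpha]
    selected.sort()
    return [g for _, g in selected]


def correlation_network(expr: ExpressionMatrix, de_genes: Sequence[str],
                        config: Optional[CorrelationNetworkConfig] = None
                        ) -> SignedNetwork:
    """Pearson co-expression network over the DE genes.

    Edge iff two-sided p < edge_p and |r| >= r_threshold; sign = sign(r).
    Correlations use case samples by default (the disease-state network).
    Zero-variance genes are skipped with a warning.
    """
    config = config or CorrelationNetworkConfig()
    cols = (expr.group_columns("case") if config.corr_samples == "case"
            else expr.values)
    n = cols.shape[1]
    if config.corr_samples == "case" and n < 3:
        raise ValidationError("need >= 3 case samples for correlation p-values")
    gene_idx = {g: i for i, g in enumerate(expr.genes)}
    genes = [g for g in de_genes if g in gene_idx]
    sub = cols[[gene_idx[g] for g in genes], :]
    sd = sub.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("skipping %d zero-variance genes", int((~keep).sum()))
        genes = [g for g, k in zip(genes, keep) if k]
        sub = sub[keep]
    edges: List[Tuple[str, str, int]] = []
    if len(genes) >= 2:
        r = np.corrcoef(sub)
        np.clip(r, -1.0, 1.0, out=r)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if p[i, j] < config.edge_p and abs(r[i, j]) >= config.r_threshold:
                    edges.append((genes[i], genes[j], 1 if r[i, j] > 0 else -1))
    return SignedNetwork(nodes=set(genes), edges=edges, directed=False)


def build_disease_network(expr: ExpressionMatrix,
                          config: Optional[CorrelationNetworkConfig] = None
                          ) -> SignedNetwork:
    """DE selection then co-expression edges, in one call."""
    config = config or CorrelationNetworkConfig()
    return correlation_network(expr, differential_genes(expr, config), config)


def swap_network_and_rescore(network: SignedNetwork,
                             target_sets: Mapping[str, Sequence[Tuple[str, int]]],
                             disease_id: str,
                             disease_emb: Mapping[str, np.ndarray],
                             positive_drugs: Sequence[str],
                             all_drugs: Sequence[str],
                             universe: GeneUniverse,
                             diffusion_config: DiffusionConfig,
                             net_config: DDINetConfig,
                             seed: int = 0) -> float:
    """Train and evaluate the scorer with diffusion run on ``network``.

    Protocol: positives are the drugs treating the disease, an equal number
    of other drugs are sampled as negatives, 80/20 split; returns accuracy
    on the balanced validation set.
    """
    positives = [DDIRecord([d], disease_id, "positive") for d in sorted(positive_drugs)]
    negatives = sample_negatives(positives, all_drugs, [disease_id],
                                 ratio=1, seed=seed)
    records = positives + negatives
    profiles = {}
    for r in records:
        d = r.drug_ids[0]
        if d not in profiles:
            seeds = [(g, s) for g, s in target_sets[d] if g in network.nodes]
            if not seeds:  # drug disconnected from this network: flat profile
                profiles[d] = np.zeros(len(universe))
            else:
                profiles[d] = diffuse_drug(network, seeds, diffusion_config,
                                           universe, stream_key=d)
    train, val = split_dataset(records, train_fraction=0.8, seed=seed)
    X_tr, y_tr, _ = build_feature_rows(train, profiles, disease_emb)
    X_val, y_val, _ = build_feature_rows(val, profiles, disease_emb)
    model = train_ddi_net(X_tr, y_tr, X_val, y_val, net_config)
    return compute_metrics(model.score(X_val), y_val, threshold=0.0).accuracy
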