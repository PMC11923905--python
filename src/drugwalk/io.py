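"""Readers and writers for the pipeline's delimited-text formats.

All tabular I/O is tab-separated by default (comma accepted); identifiers
are opaque strings.  Loaders validate rather than coerce: unknown tokens
raise, duplicates are logged exactly once and resolved by a documented rule
(edges: last wins; universe: first wins; records: deduplicated).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .types import (ACTIVATION, INHIBITION, SIGN_SYNONYMS, DDIRecord,
                    DiseaseHierarchy, DrugRecord, DrugTargetRecord,
                    EmbeddingTable, ExpressionMatrix, GeneUniverse,
                    SignedNetwork, ValidationError)

logger = logging.getLogger("drugwalk")

PathLike = Union[str, Path]


def _split(line: str) -> List[str]:
    line = line.rstrip("\n")
    return line.split("\t") if "\t" in line else line.split(",")


class ParseError(ValueError):
    pass


def load_signed_network(path: PathLike, directed: bool = False) -> SignedNetwork:
    """Read an edge list ``source<TAB>target<TAB>sign``.

    Sign tokens +1/1/activation/act and -1/−1/inhibition/inh are accepted;
    anything else is rejected.  Duplicate (source, target) pairs resolve
    last-wins with a logged warning.
    """
    nodes, edges = set(), []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _split(line)
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            s, t, tok = (p.strip() for p in parts)
            if tok.lower() not in SIGN_SYNONYMS:
                raise ValidationError(f"{path}:{lineno}: unknown sign token {tok!r}")
            nodes.update((s, t))
            edges.append((s, t, SIGN_SYNONYMS[tok.lower()]))
    net = SignedNetwork(nodes=nodes, edges=edges, directed=directed)
    logger.info("loaded network %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def save_signed_network(net: SignedNetwork, path: PathLike) -> None:
    with open(path, "w") as fh:
        for s, t, g in net.edges:
            fh.write(f"{s}\t{t}\t{'+1' if g == 1 else '-1'}\n")


def load_gene_universe(path: PathLike) -> GeneUniverse:
    """One identifier per line; first occurrence wins on duplicates."""
    seen, order = set(), []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g:
                continue
            if g in seen:
                logger.warning("duplicate universe gene %s: first occurrence kept", g)
                continue
            seen.add(g)
            order.append(g)
    if not order:
        raise ValidationError(f"{path}: empty gene universe")
    return GeneUniverse(order)


def save_gene_universe(universe: GeneUniverse, path: PathLike) -> None:
    Path(path).write_text("\n".join(universe.genes) + "\n")


def load_embeddings(path: PathLike) -> EmbeddingTable:
    """First column identifier, remaining columns floats; rows must agree in width."""
    vectors: Dict[str, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _split(line)
            vec = np.array([float(x) for x in parts[1:]], dtype=float)
            if dim is None:
                dim = vec.shape[0]
            elif vec.shape[0] != dim:
                raise ValidationError(
                    f"{path}:{lineno}: dimension mismatch ({vec.shape[0]} vs {dim})")
            vectors[parts[0]] = vec
    return EmbeddingTable(vectors)


def save_embeddings(table: EmbeddingTable, path: PathLike) -> None:
    # %.12g keeps the round trip lossless well past 9 significant digits
    with open(path, "w") as fh:
        for k, v in table.vectors.items():
            fh.write(k + "\t" + "\t".join(f"{x:.12g}" for x in v) + "\n")


def load_expression(path: PathLike, group_map: Dict[str, str]) -> ExpressionMatrix:
    """Genes x samples table with a header row of sample identifiers."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    samples = [str(c) for c in df.columns]
    for s in samples:
        if s not in group_map:
            raise ValidationError(f"sample {s!r} missing from group map")
    mat = ExpressionMatrix(genes=[str(g) for g in df.index], samples=samples,
                           values=df.to_numpy(dtype=float),
                           groups={s: group_map[s] for s in samples})
    logger.info("loaded expression %s: %d genes, %d case / %d control", path,
                len(mat.genes),
                sum(1 for s in samples if group_map[s] == "case"),
                sum(1 for s in samples if group_map[s] == "control"))
    return mat


def load_group_map(path: PathLike) -> Dict[str, str]:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _split(line)
            if len(parts) != 2 or parts[1].strip() not in ("case", "control"):
                raise ValidationError(f"{path}:{lineno}: expected 'sample<TAB>case|control'")
            out[parts[0].strip()] = parts[1].strip()
    return out


_MODE_TOKENS = {"activation": ACTIVATION, "act": ACTIVATION, "+1": ACTIVATION,
                "1": ACTIVATION, "inhibition": INHIBITION, "inh": INHIBITION,
                "-1": INHIBITION, "−1": INHIBITION}


def load_drug_records(path: PathLike) -> List[DrugRecord]:
    """``drug_id<TAB>smiles<TAB>gene:mode;gene:mode`` (smiles and targets optional)."""
    records = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _split(line)
            drug_id = parts[0].strip()
            smiles = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
            targets = []
            if len(parts) > 2 and parts[2].strip():
                for tok in parts[2].split(";"):
                    gene, _, mode = tok.strip().partition(":")
                    if mode.lower() not in _MODE_TOKENS:
                        raise ValidationError(f"{path}:{lineno}: unknown mode {mode!r}")
                    targets.append((gene, _MODE_TOKENS[mode.lower()]))
            if drug_id in records:
                logger.warning("duplicate drug record %s: last occurrence kept", drug_id)
            records[drug_id] = DrugRecord(drug_id, smiles=smiles, targets=targets)
    return list(records.values())


def load_target_records(path: PathLike) -> List[DrugTargetRecord]:
    """``drug_id<TAB>gene_id<TAB>label`` with label activation|inhibition|irrelevant."""
    out, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _split(line)
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            d, g, lab = (p.strip() for p in parts)
            if (d, g) in seen:
                logger.warning("duplicate drug-target record (%s,%s) dropped", d, g)
                continue
            seen.add((d, g))
            out.append(DrugTargetRecord(d, g, lab))
    return out


def load_ddi_records(path: PathLike) -> List[DDIRecord]:
    """``drugA;drugB<TAB>disease<TAB>positive|negative`` (single or combination)."""
    out, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _split(line)
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            drugs = [d.strip() for d in parts[0].split(";") if d.strip()]
            rec = DDIRecord(drugs, parts[1].strip(), parts[2].strip())
            if (rec.key(), rec.label) in seen:
                logger.warning("duplicate DDI record at %s:%d dropped", path, lineno)
                continue
            seen.add((rec.key(), rec.label))
            out.append(rec)
    return out


def save_ddi_records(records: List[DDIRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{';'.join(r.drug_ids)}\t{r.disease_id}\t{r.label}\n")


def load_disease_hierarchy(path: PathLike) -> DiseaseHierarchy:
    """Parent-child edge list; the term set is the union of endpoints."""
    edges, terms = [], []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _split(line)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            edges.append((a, b))
            for t in (a, b):
                if t not in seen:
                    seen.add(t)
                    terms.append(t)
    return DiseaseHierarchy(terms=terms, edges=edges)


def save_disease_hierarchy(h: DiseaseHierarchy, path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in h.edges:
            fh.write(f"{a}\t{b}\n")


def save_profile_matrix(profiles: Dict[str, np.ndarray], universe, path: PathLike) -> None:
    """Drugs x universe matrix, one row per drug, header row of gene ids."""
    with open(path, "w") as fh:
        fh.write("drug\t" + "\t".join(universe.genes) + "\n")
        for drug_id, vec in profiles.items():
            fh.write(drug_id + "\t" + "\t".join(f"{x:.12g}" for x in vec) + "\n")


def load_profile_matrix(path: PathLike):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {str(d): df.loc[d].to_numpy(dtype=float) for d in df.index}


def curated_counts() -> dict:
    """Scale of the curated source datasets (drugs, diseases, edges, splits)."""
    import json
    from importlib import resources

    with resources.files("drugwalk._data").joinpath("curated_counts.json").open() as fh:
        return json.load(fh)
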