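"""Embed a disease hierarchy with node2vec and inspect the geometry.

Generates a random tree standing in for a hierarchical disease vocabulary,
runs biased random walks + skip-gram, and compares cosine similarity of a
parent-child pair against a random distant pair: related terms should sit
closer in the embedding space.
"""

import numpy as np

from drugwalk.embeddings import Node2VecParams, embed_network
from drugwalk.synth import gen_disease_hierarchy

hierarchy = gen_disease_hierarchy(n_terms=60, branching=3, seed=0)
params = Node2VecParams(dim=32, walks_per_node=10, walk_length=20,
                        window=4, epochs=3, seed=0)
table = embed_network(hierarchy, params)


def cos(a, b):
    return float(table[a] @ table[b]
                 / (np.linalg.norm(table[a]) * np.linalg.norm(table[b])))


parent, child = hierarchy.edges[0]
far_a, far_b = hierarchy.terms[1], hierarchy.terms[-1]
print(f"embedded {len(table)} terms in {params.dim} dimensions")
print(f"cosine(parent {parent}, child {child})   = {cos(parent, child):+.3f}")
print(f"cosine(distant {far_a}, {far_b}) = {cos(far_a, far_b):+.3f}")
print("parent-child similarity should exceed the distant-pair similarity")
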