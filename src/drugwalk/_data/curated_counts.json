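{
  "comment": "Scale of the curated source datasets the pipeline was built for.",
  "drug_disease": {
    "drugs": 7940,
    "diseases": 2986,
    "known_interactions": 88161,
    "feature_length": 19277
  },
  "drug_target": {
    "entries": 16508,
    "activation": 2024,
    "inhibition": 6969,
    "irrelevant": 7525
  },
  "signed_network": {
    "genes": 6009,
    "activation_edges": 33398,
    "inhibition_edges": 7960
  },
  "disease_hierarchy": {"terms": 29349, "edges": 39784},
  "gene_universe": 18977,
  "combination_therapies": {"total": 301, "train": 225, "validation": 76, "paired_subset": 104}
}
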