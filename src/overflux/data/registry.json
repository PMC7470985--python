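[
  {"name": "acetate", "carbon_count": 2, "network_node": "acetyl_coa", "secreted": true},
  {"name": "succinate", "carbon_count": 4, "network_node": "succinyl_coa", "secreted": true},
  {"name": "formate", "carbon_count": 1, "network_node": "pyruvate", "secreted": true},
  {"name": "propionate", "carbon_count": 3, "network_node": "succinyl_coa", "secreted": true},
  {"name": "lactate", "carbon_count": 3, "network_node": "pyruvate", "secreted": true},
  {"name": "histidine", "carbon_count": 6, "network_node": "purine", "secreted": true},
  {"name": "cysteine", "carbon_count": 3, "network_node": "serine_cycle", "secreted": true},
  {"name": "cystine", "carbon_count": 6, "network_node": "serine_cycle", "secreted": true},
  {"name": "glutathione", "carbon_count": 10, "network_node": "serine_cycle", "secreted": true},
  {"name": "asparagine", "carbon_count": 4, "network_node": "oxaloacetate_aspartate", "secreted": true},
  {"name": "alanine", "carbon_count": 3, "network_node": "oxaloacetate_aspartate", "secreted": true}
]
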