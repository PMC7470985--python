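{
  "nodes": [
    {"id": "glucose", "label": "glucose", "kind": "intracellular"},
    {"id": "pyruvate", "label": "pyruvate", "kind": "intracellular"},
    {"id": "acetyl_coa", "label": "acetyl-CoA", "kind": "intracellular"},
    {"id": "oxaloacetate_aspartate", "label": "oxaloacetate/aspartate", "kind": "intracellular"},
    {"id": "succinyl_coa", "label": "succinyl-CoA", "kind": "intracellular"},
    {"id": "serine_cycle", "label": "serine cycle", "kind": "intracellular"},
    {"id": "purine", "label": "purine", "kind": "intracellular"}
  ],
  "backbone": [
    ["glucose", "pyruvate"],
    ["pyruvate", "acetyl_coa"],
    ["pyruvate", "oxaloacetate_aspartate"],
    ["oxaloacetate_aspartate", "succinyl_coa"],
    ["pyruvate", "serine_cycle"],
    ["glucose", "purine"]
  ]
}
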