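# Dimension tree for the type-2 diabetes comparison (insulin glargine vs
# NPH insulin): HbA1c reduction under efficacy, nocturnal hypoglycemia
# under safety, equal top-level weights.
id: overall
label: Overall
weight: 1
children:
  - id: efficacy
    label: efficacy
    weight: 0.5
    children:
      - id: hba1c_reduction
        label: HbA1c
        weight: 1
        criterion: efficacy
        target: HbA1c
        direction: decrease
  - id: safety
    label: safety
    weight: 0.5
    children:
      - id: nocturnal_hypoglycemia
        label: nocturnal hypoglycemia
        weight: 1
        criterion: safety
        target: nocturnal_hypoglycemia
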