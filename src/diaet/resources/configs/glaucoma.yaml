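# Dimension tree for the glaucoma comparison (latanoprost vs timolol):
# efficacy and safety weighted equally, one endpoint and one adverse effect.
id: overall
label: Overall
weight: 1
children:
  - id: efficacy
    label: efficacy
    weight: 0.5
    children:
      - id: iop_reduction
        label: diurnal IOP
        weight: 1
        criterion: efficacy
        target: diurnal_IOP
        direction: decrease
  - id: safety
    label: safety
    weight: 0.5
    children:
      - id: conjunctival_hyperemia
        label: conjunctival hyperemia
        weight: 1
        criterion: safety
        target: conjunctival_hyperemia
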