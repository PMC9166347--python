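# Default English sentence templates, one per argument role and outcome.
# Placeholders use Python str.format syntax; available names:
#   {t} {t_prime}  - candidate and comparator treatment names
#   {n}            - number of distinct clinical studies under the node
#   {label}        - dimension label
#   {weights}      - "weight of <child>: <w>" list for aggregated nodes
#   {confidence}   - reported degree of confidence
#   {study}        - citation label of the study (atomic arguments only)
root_accepted: >-
  Taking into account the evidence from {n} clinical studies comparing {t} to
  {t_prime}, it can be concluded that {t} is superior to {t_prime} ({weights}).
root_rejected: >-
  Taking into account the evidence from {n} clinical studies comparing {t} to
  {t_prime}, it can not be concluded that {t} is superior to {t_prime}
  ({weights}).
inner_accepted: >-
  The evidence in {n} clinical studies shows that {t} is superior to {t_prime}
  in terms of {label} ({weights}).
inner_rejected: >-
  The evidence in {n} clinical studies does not show that {t} is superior to
  {t_prime} in terms of {label} ({weights}).
leaf_accepted: >-
  The evidence in {n} clinical studies shows that {t} is superior to {t_prime}
  in terms of {label}.
leaf_rejected: >-
  The evidence in {n} clinical studies does not show that {t} is superior to
  {t_prime} in terms of {label}.
atomic_support: >-
  {study} shows that {t} is superior to {t_prime} in terms of {label}.
atomic_contradict: >-
  {study} shows that {t} is NOT superior to {t_prime} in terms of {label}.
no_evidence: >-
  No study shows that {t} is superior to {t_prime} in terms of {label}.
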