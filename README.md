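# diaet

**Dynamic interactive argumentation trees for clinical-trial evidence
synthesis.**

Systematic reviews answer the question "is treatment *t* superior to
treatment *t′*?" by aggregating the evidence of many randomized controlled
trials — a slow, manual process. `diaet` automates the synthesis step: given
a semantic knowledge base of trial results (RDF/Turtle) and a weighted
hierarchy of clinical endpoints (a *dimension tree*), it builds a
hierarchical argument whose root concludes on overall superiority, whose
inner nodes conclude per dimension (efficacy, safety, individual endpoints
and adverse effects), and whose leaves are the individual studies' claims.
Because the whole tree is recomputed in milliseconds, reviewers can interact
with it: change dimension weights, exclude studies, filter by trial
metadata, and sweep the acceptance threshold to see exactly when a
conclusion flips.

It is aimed at evidence-based-medicine researchers and systematic-review
automation work; the two shipped reference cases are glaucoma (latanoprost
vs timolol: intraocular-pressure reduction, conjunctival hyperemia) and
type-2 diabetes (insulin glargine vs NPH insulin: HbA1c reduction, nocturnal
hypoglycemia).

## The calculus

Every trial that reports a leaf dimension for both drugs yields an **atomic
argument** with degree of confidence ⟦AtA⟧ ∈ {0, 1}: 1 if the trial's
evidence satisfies the leaf's superiority criterion, 0 if it contradicts it.
The criteria are:

* **efficacy** — drug 1 changes the endpoint from baseline strictly further
  in the desired direction than drug 2 (ties contradict);
* **safety** — drug 1 leads to strictly fewer incidences of the adverse
  event, compared as incidence proportions when arm sizes are known and as
  raw counts otherwise (ties contradict).

Every dimension node yields an **aggregated argument** whose degree of
confidence is the weight-normalized mean of its premises,

    ⟦AgA⟧ = (1/Z) · Σᵢ w_i · ⟦Aᵢ⟧ ,      Z = Σᵢ w_i ,

with weights w_i taken from the dimension tree (atomic arguments weigh 1, so
a leaf's confidence is the fraction of reporting studies that support the
claim). An argument is **accepted** when its confidence is not less than the
acceptance threshold τ (default 0.5 — a majority of the weighted evidence;
τ = 1 demands unanimity). All arithmetic is exact rational; only display
rounds. Dimensions without evidence are reported as such and drop out of
both the sum and Z rather than counting as contradiction.

## Worked example

Generate the glaucoma fixture (11 trials; all 11 support latanoprost on
diurnal IOP reduction, 1 of 6 reporting trials supports it on conjunctival
hyperemia) and build the tree:

```bash
diaet generate --fixture glaucoma --out glaucoma.ttl
diaet build --kb glaucoma.ttl --dims glaucoma \
    --t latanoprost --t2 timolol --tau 0.5 --reporting paper
```

prints (atomic lines abbreviated):

```
↦ Taking into account the evidence from 11 clinical studies comparing latanoprost to timolol,
  it can be concluded that latanoprost is superior to timolol (weight of efficacy: 0.5; weight of safety: 0.5).
  ⇒ The evidence in 11 clinical studies shows that latanoprost is superior to timolol in terms of efficacy (weight of diurnal IOP: 1).
    ⇒ The evidence in 11 clinical studies shows that latanoprost is superior to timolol in terms of diurnal IOP.
      → Camras 2001 shows that latanoprost is superior to timolol in terms of diurnal_IOP.
      ...
  ⇒ The evidence in 6 clinical studies does not show that latanoprost is superior to timolol in terms of safety (weight of conjunctival hyperemia: 1).
    ⇒ The evidence in 6 clinical studies does not show that latanoprost is superior to timolol in terms of conjunctival hyperemia.
      → Camras 2001 shows that latanoprost is superior to timolol in terms of conjunctival_hyperemia.
      → Hedman 2002 shows that latanoprost is NOT superior to timolol in terms of conjunctival_hyperemia.
      ...

root confidence: 0.59
```

The numbers behind this: the IOP leaf has confidence 11/11 = 1, the
hyperemia leaf 1/6 ≈ 0.17; with efficacy and safety both weighted 0.5 the
root is 0.5·1 + 0.5·0.17 = 0.59 ≥ τ, so the overall superiority claim is
accepted while the safety claim (0.17 < 0.5) is rejected. Sensitivity
analysis flips it:

```bash
diaet build --kb glaucoma.ttl --dims glaucoma --t latanoprost --t2 timolol \
    --weight efficacy=0.3 --weight safety=0.7
# → "... it can not be concluded ..."   (0.3·1 + 0.7·0.17 = 0.42 < 0.5)

diaet build --kb glaucoma.ttl --dims glaucoma --t latanoprost --t2 timolol \
    --exclude CT_07
# → IOP leaf drops to 10/11 = 0.9; overall conclusion still accepted
```

and `diaet sweep ... --step 0.01` partitions τ ∈ [0, 1] into the ranges
with constant outcomes (here the safety branch flips at 1/6 and the root at
7/12). The library API mirrors the CLI: `load_kb`, `parse_dimension_config`,
`build_diaet`, `run_scenarios`, `sweep_thresholds`, `verbalize_tree`,
`export` (JSON / Graphviz DOT / text); see `docs/methods.md` for the model
details and design choices.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the glaucoma fixture from scratch, rebuilds the argument trees,
and writes the measured quantities as JSON: the IOP and conjunctival-
hyperemia leaf confidences, the root confidence under equal weights (rounded
reporting mode), the root confidence after reweighting efficacy/safety to
0.3/0.7, and the IOP leaf confidence after excluding the one study that
reports IOP but not hyperemia. The seed only varies the sampled numeric
effect values; the reported confidences are invariant to it by construction.
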