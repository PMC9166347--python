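# Methods

This note records the model implemented by `diaet`, the choices made where
the published description of this family of tools leaves the design open,
and what the synthetic fixtures do and do not establish.

## Model

An *argument* is a tuple (C, t, {t′}, d, {p₁…pₘ}): a superiority conclusion
C for treatment t against comparator t′ along dimension d, justified by
premises p. Only pairwise comparison is supported (the comparator set is a
singleton).

**Atomic arguments.** For each leaf dimension of the configured dimension
tree and each trial that reports that dimension for both treatments, one
atomic argument is instantiated. Its confidence is 1 if the trial's paired
evidence satisfies the leaf's superiority criterion, else 0:

* *Efficacy leaves* bind an endpoint id and a desired direction. Support
  means drug 1's change from baseline is strictly larger in the desired
  direction than drug 2's. The single reported per-arm summary (mean change)
  is used verbatim; when a KB stores baseline and final values instead, the
  loader derives change = final − baseline. A unit mismatch between the two
  arms is a data error.
* *Safety leaves* bind an adverse-event id. Support means strictly fewer
  incidences under drug 1 — incidence proportions (affected/arm size,
  compared as exact rationals) when both arm sizes are present, raw counts
  otherwise. A count exceeding its arm size is a data error.
* *Ties.* Equal changes or equal incidence contradict (confidence 0):
  "no worse" is not "superior". The published description states this only
  for safety; we apply the same rule to efficacy for symmetry.
* Statistical-significance flags in the evidence are carried on the pair but
  ignored by the criteria, which compare magnitudes only; significance-aware
  criteria would slot in at `make_atomic_argument`.

**Aggregation.** Every dimension node yields an aggregated argument with
confidence (1/Z)·Σ wᵢ·⟦Aᵢ⟧, Z = Σ wᵢ, over its premises; weights come from
the dimension tree and need not sum to 1 (Z normalizes, so sibling weights
are scale-invariant). Atomic arguments weigh 1, hence a leaf's confidence is
supporting/reporting. All confidences are exact `fractions.Fraction`s.

**Acceptance.** A node is accepted iff its exact confidence ≥ τ ("not less
than"), τ ∈ [0, 1], default 0.5. Acceptance never looks at rounded values;
this keeps the boundary case (confidence exactly τ) well defined.

**Construction.** The argument tree is built by one recursive descent over
the dimension tree — one call per dimension node, so termination is
structural and the recursion depth is the tree depth. Unknown drug names or
an empty KB produce a root with status `no_evidence` ("no conclusion
possible"), not an exception.

## Evidence without data, filtering, and the reference count

Two situations must not be conflated: a dimension *contradicted* by trials
and a dimension *without data*.

* A leaf with no reporting trial (or none left after filtering) has status
  `no_evidence`; it is excluded from its parent's weighted sum **and** from
  Z, i.e. the parent renormalizes over its evidenced children. Scoring such
  leaves 0 would treat missing data as contradiction. If every child lacks
  evidence the parent is `no_evidence` too.
* Filtering (explicit study exclusion, or bounds on publication year,
  duration, participants, mean age) removes a trial's atomic argument from
  the premises, but the leaf's normalization count stays the number of
  studies reporting the dimension in the KB: excluding one of 11 supporting
  trials yields 10/11 ≈ 0.9, not 10/10. This reproduces the published tool's
  printed arithmetic and makes exclusion informative (removing support
  lowers confidence; removing contradiction leaves it unchanged). A bound on
  a metadata field a trial does not report excludes that trial, since the
  bound cannot be verified.

## Reporting modes

Internally everything is exact; display rounds half-up to two decimals.
Published summaries sometimes sum already-rounded child values, so two modes
exist:

* `exact` — round the exact rational once at the end. The glaucoma root
  7/12 = 0.5833… renders "0.58".
* `paper_rounded` — recompute each node's weighted sum over its children's
  2-decimal reported values, bottom-up, then round. The same root renders
  0.5·1.00 + 0.5·0.17 = 0.585 → "0.59".

Neither mode is "the" truth; acceptance always uses exact values. One known
published figure (a post-exclusion root of 0.53) is reproduced by neither
mode (exact: 71/132 → 0.54; rounded intermediates: 0.54) and is documented
rather than forced.

Verbalization reports the raw configured weights (the published outputs are
ambiguous between raw and normalized weights; raw is what the user wrote and
is scale-equivalent anyway).

## Threshold sweeps

`sweep_thresholds` builds the tree once and re-evaluates acceptance on a
decimal grid (default step 0.01, τ ∈ {0, 0.01, …, 1}), merging consecutive
grid points with identical per-dimension outcome patterns into maximal
closed ranges — the presentation style of published threshold tables. The
true flip points are the distinct exact confidences in the tree; they are
exposed as `exact_breakpoints` for diagnostics. Accepted sets are antitone
in τ by construction.

## Knowledge-base layer

KBs are RDF 1.1 Turtle in a small documented vocabulary
(`resources/schema.ttl`, prefix `ctro:`): trial → arm → {drug name, endpoint
results, adverse-event counts}, plus trial metadata. Because no RDF library
is assumed at runtime, the package ships its own Turtle-subset
parser/serializer (named IRIs, typed/plain literals, `@prefix`; no blank
nodes or collections) and a basic-graph-pattern engine that evaluates the
query templates in `resources/queries/` (triple patterns with variables and
`LCASE` equality filters — the fragment of SPARQL the retrieval needs).
Drug, endpoint and event names match case-insensitively after whitespace
normalization; no ontology-based synonym resolution is attempted. Trials
reporting a dimension in only one arm cannot form a comparison pair and are
dropped from that leaf with a logged warning.

## Synthetic fixtures

`synthetic.generate_kb` materializes a prescribed evidence structure: per
endpoint/event, exact numbers of supporting, contradicting, tying and
non-reporting trials, with roles assigned to trials in id order. Effect
values are sampled with a minimum margin (0.1 endpoint units; 2 percentage
points of incidence, with equal arm sizes so proportion order equals count
order) so floating-point comparison can never blur a prescribed role; exact
ties occur only when requested. Metadata is drawn uniformly from configurable
ranges (defaults: years 1995–2005, 4–52 weeks, 50–400 participants, mean age
55–70 — plausible for the two reference indications). Generation is
deterministic per seed, and every prescribed confidence is invariant to the
seed.

The built-in fixtures state the two reference cases: `glaucoma` — 11 trials,
11/11 supporting on diurnal IOP, 1 supporting / 5 contradicting / 5
non-reporting on conjunctival hyperemia; `t2dm` — 9 trials, 9/9 supporting
on nocturnal hypoglycemia and 4/9 on HbA1c reduction by default. The 4/9
efficacy count is a reconstruction: it is the only fraction with denominator
≤ 9 whose acceptance flips inside the published efficacy flip window
(0.44, 0.45], not a reported per-study tally, and it is parameterizable
(`t2dm_spec`). The published three-range threshold table for this case is
mutually inconsistent with any single support-count assignment under equal
weights and is therefore not asserted by any test.

What a green test on synthetic data establishes: the calculus (retrieval,
criteria, aggregation, acceptance, sensitivity machinery) is exact on KBs
whose structure is known. What it does not establish: anything about real
extraction quality, real trial heterogeneity (the generator draws one clean
summary per arm, no missingness within reported dimensions, no biased
metadata), or synonym/unit harmonization across real publications.

## Numerical and degenerate-input choices

* Weights: non-negative exact rationals; floats from configs go through
  their decimal string (0.3 → 3/10). All-zero sibling weights raise a
  degenerate-weights error rather than silently producing 0/0.
* Rounding: half-up via `decimal` at 50-digit precision; exact halves (e.g.
  0.585) terminate and round deterministically.
* Zero-trial KBs load with a warning; queries on absent drugs/endpoints
  return empty lists, not errors; filter bounds with min > max are
  validation errors.
* Deterministic ordering throughout: evidence sorted by study id, serialized
  Turtle sorted by subject/predicate, JSON/DOT exports byte-stable.

## Limitations

Pairwise comparison only; one evidence record per trial arm and dimension;
no OWL reasoning, no external registry linkage, no multilingual output; the
Turtle subset rejects blank nodes, so third-party KBs may need rewriting
into the documented vocabulary.
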