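# Methods

This note records the model underlying the package, the defaults and the
design choices taken where the problem was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Workflow models and measurement contexts

An experimental design is a typed directed graph. The *flow* subgraph
(materials, activities, branch/fork control nodes) must be acyclic with at
least one start node, and materials and activities must alternate along
flow edges, with branch/fork nodes transparent; the alternation check
resolves each control node to its nearest non-control neighbours on both
sides. Loops (repeated assay steps indexed by a variable) are out of scope
and rejected as cycles. Variables attach only to activities:
`parameter_of` edges run parameter/constant → activity, `measurement_of`
edges run activity → measurement, and each measurement attaches to exactly
one activity.

The context of a measurement is the union, over all flow paths from a
start node to the measuring activity, of the parameters and constants
attached to activities on the path. Branches and forks are distinct node
kinds (choice vs. division of material) but are deliberately treated
identically by path tracing; taking the union across alternative branch
arms is the conservative choice — a parameter on any arm may condition the
measurement. In an acyclic graph the union over paths equals the
attachments of the measuring activity and its flow ancestors, which is how
the implementation computes it; the test suite checks this against an
independent exhaustive path-enumeration oracle on hundreds of random
designs.

Column order of the derived data-entry form is not semantically meaningful
but must be canonical so that re-serialized models produce identical
forms: variables sort by the topological position (lexicographic
topological order of the flow graph) of their earliest attachment
activity, ties broken by node id; measurements follow, ordered the same
way. Constants are flagged *fixed per experiment*: they carry one value
per experiment rather than varying per data point.

The schema deliberately does not force specific variables to be
parameters or measurements. In the reference tract-tracing design both
the injection location and the mapped labeling location are parameters
(the analyst chooses where to inject and which regions to survey), but a
design that models the labeling location as a measurement validates
equally well; whether location is condition or outcome is a modelling
question the formalism leaves open.

In the reference design the taxonomic-class constant is attached to the
injection activity — the first activity touching the subject — because
variables attach to activities, not materials. An `injected subject`
material node sits between injection and perfusion to preserve
material/activity alternation.

## Observation tables

One row is one data point: a single labeling report for a single
injection, with experiment and publication provenance. Validation checks
that a row's keys equal the derived form, that every value lies in its
column's domain, and that constant-role columns are consistent within an
experiment. Missing-but-present labeling density is encoded with the
explicit `present-unknown` category rather than an empty cell, so absence
of a value is always distinguishable from unreported density.

Region extents are flat-encoded for CSV cells with the
`rel(ABBREV)|rel(ABBREV)|note(...)` mini-grammar (relations
`coextensive_with`, `part_of`, `overlaps`). The grammar exists because a
flat text encoding of the drawn-region widget is needed for spreadsheet
interchange; JSON-lines tables use the same encoding so the two formats
are interconvertible.

## Atlas reasoning

`proper_part_of` is stored as the asserted parent relation; queries use
its transitive closure, which must be acyclic (checked at load). `overlaps`
is symmetric and irreflexive and is *not* propagated through containment:
the four-disjunct `part-of-or-overlaps` relation includes exactly one hop
of overlap-with-a-part, nothing more, because the defined relation is the
specification. Nothing is auto-asserted — in particular, overlap between a
region and its parent's other children is not assumed; only relations
present in the input file hold.

Disjuncts are evaluated in a fixed order (identity, containment, direct
overlap, overlap-of-part) with short-circuiting, and for disjunct 4 the
lexicographically smallest witnessing part is recorded, so reasoning
trails are deterministic. Every positive verdict carries a `GeoTrail`
whose steps use only asserted relations (plus the extent's own
assertions); `GeoTrail.replay` re-derives the verdict from the steps and
is exercised by the tests.

Extent resolution adjusts the verdict class for what the assertion itself
claims. A `coextensive_with N` assertion inherits N's verdict against the
target unchanged. A `part_of N` assertion can never yield `identical`
(the extent is strictly inside N) and is demoted to `contained`. An
`overlaps N` assertion is always overlap-class: `overlap` when N is the
target itself, `overlap_of_part` otherwise — including the weakest case
where N itself only overlaps the target, which is retained as (flagged)
evidence rather than discarded, since a qualitative representation cannot
exclude that the shared territory is involved. When several assertions
match, the strongest verdict wins (`identical > contained > overlap >
overlap_of_part`), so a spreading injection that both overlaps one region
and is coextensive with another reports the stronger relation for each
query target.

## Interpretation

The anterograde rule accepts both `fibers` and `terminals` labeling (both
are axonal label); only `cellular` labeling satisfies the retrograde rule.
Tracer transport directions are configuration, not code: a registry maps
chemical names to `anterograde`/`retrograde`, and interpretation refuses
unregistered chemicals by name.

The density → strength map is configurable with one hard constraint:
totality over the seven-point density scale plus `present-unknown`, `no
label` → `none`, and monotone non-decreasing along the density order. The
shipped default is

| density | strength |
|---|---|
| no label | none |
| very sparse label, sparse label | weak |
| sparse/moderate label, moderate label | moderate |
| moderate/dense label, dense label | strong |
| present-unknown | weak |

`present-unknown` maps to the weakest positive level: it asserts existence
of labeling without density, so discarding it would lose evidence and any
higher level would overstate it.

Negative reports (`no label`) are retained in tables but excluded from
evidence; a pair with only negative reports renders as `none:0`. Injection
spread (an extent touching more than one top-level region) does not cap
strength; it sets a flag surfaced in the provenance report, because
ambiguity about the source region is an analyst's judgement call, not an
arithmetic one. Likewise the default matrix aggregates all positive
evidence including overlap-class matches (flagged `via_overlap`), with a
`--direct-only` switch to exclude them; when a row matches both through
containment and overlap via different assertions, the stronger (contained)
verdict is recorded.

`directness` summarises both geometric matches: `direct` when injection
and labeling both matched identically, `via_part` when containment was
needed, `via_overlap` when either match is overlap-class.

## Synthetic corpora

`fixtures.random_corpus` emulates a noiseless curated literature: an atlas
built as a forest of top-level regions with subtrees up to `depth` (default
2) deep, a ground-truth connectome over distinct top-level regions, and at
least one observation row per true projection whose density encodes the
true strength under the default map (a random density label from the
matching band). Injections land in the true region or a proper part, or —
with probability `overlap_fraction` (default 0.3) — are drawn as extents
that merely overlap it, exercising overlap reasoning; `no label`
distractor rows cover some unconnected pairs. Defaults (18 regions, 12
projections) keep a single corpus interpretable in well under a second
while still producing multi-level hierarchies, both tracer directions and
both geometric match classes.

What the generator does *not* emulate: reporting noise or curation error
(densities never contradict the ground truth), conflicting studies,
nomenclature mismatches across atlases, cross-tree overlaps, or negative
evidence for true projections. Recovery tests on these corpora therefore
show that the interpretation pipeline is a faithful inverse of the
encoding rules — not that it is robust to noisy or inconsistent
literature, which real curation requires an analyst to resolve through
the provenance display.

Atlas overlap pairs in generated corpora are confined within one top-level
subtree; extents that should match only by overlap assert `overlaps`
against a proper part of the target. This keeps the ground truth
identifiable (no spurious cross-tree evidence) while still exercising
disjuncts 3 and 4.

## Numerical and procedural choices

* All randomness uses Python's `random.Random` seeded explicitly;
  identical seeds and knobs give byte-identical serialized artifacts.
* Canonical ordering everywhere (sorted node/edge storage, lexicographic
  topological order, sorted region lists) makes every output
  deterministic; no timestamps are embedded in data outputs.
* Model documents are JSON with a published JSON Schema
  (`src/kefed/schemas/model.schema.json`); structural checks are
  implemented natively and report JSON-pointer locations. Semantic
  invariant violations are returned as data (a validation report), never
  exceptions, so a validator UI can show all problems at once.
* The oracle cross-checks in the acceptance layer (exhaustive path
  enumeration, fixpoint transitive closure, direct four-disjunct
  evaluation) are written against plain dictionaries, independent of the
  graph library used by the implementation.
* Test and acceptance problem sizes (random designs of ≤ 20 nodes, atlases
  of ≤ 10 regions with all ordered pairs checked, 50–200 seeds per
  property) were chosen so the whole suite runs in seconds while every
  code path — branches, forks, shared parameters, multi-parent regions,
  overlap witnesses — is exercised.

## Known limitations

* No loops in designs, no statistical aggregation across measurement
  contexts (e.g. means over subjects); both require extending the context
  calculus.
* Ontology annotation is a stored CURIE string; no terminology service is
  consulted.
* The mereology is deliberately minimal: no metric geometry, no
  external-connection or tangential-parthood distinctions, and overlap
  information is used only as the defined relation prescribes.
* Evidence aggregation is a max over an ordinal scale; it does not weight
  by study count, injection spread or directness. These factors are
  surfaced per evidence row for the analyst instead.
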