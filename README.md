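# kefed

Knowledge engineering from experimental design: workflow-graph models of
experimental protocols, qualitative spatial reasoning over a brain-region
atlas, and rule-based interpretation of tract-tracing observations into a
neural connection matrix with drill-down provenance.

The package is aimed at biocurators and neuroinformatics developers who
need to capture *observations* from published experiments in a form that
keeps their full parameter context, and then derive *interpretations*
(here: "region A projects to region B with strength s") whose every cell
can be traced back to the supporting data.

## The formalism

**Experimental designs as workflow graphs.** A protocol is a directed
acyclic graph alternating *materials* (subject, brain, tissue sections)
and *activities* (injection, sectioning, mapping), optionally divided by
branch/fork control nodes. Variables attach to activities: *parameters*
and *constants* describe the conditions of an activity, *measurements*
record its outputs. The key derivation: a measurement's **context** is the
set of parameters and constants attached to activities on any workflow
path from a start node back to the measuring activity. The context union
over all measurements, plus the measurements themselves, yields the
data-entry form — so every recorded value carries the conditions needed to
interpret it. For the built-in tract-tracing design this derivation
produces the classic five-quantity observation record (injection location,
tracer chemical, mapped labeling location, labeling type, labeling
density) plus the fixed taxonomic class.

**Qualitative atlas reasoning.** Brain regions form a containment
hierarchy under an irreflexive, transitive `proper_part_of` relation, plus
a symmetric `overlaps` relation for regions that share territory. The
admissibility test used when matching experimental locations against a
region of interest is the defined relation

```
part-of-or-overlaps(sub, super) ⇔
      sub = super
    ∨ proper-part-of⁺(sub, super)
    ∨ overlaps(sub, super)
    ∨ ∃r: proper-part-of⁺(r, super) ∧ overlaps(sub, r)
```

Injection sites and labeling territories are arbitrarily drawn *extents*
expressed as qualified assertions against named regions
(`coextensive_with(ENTl)`, `part_of(RSPv)`, `overlaps(ENT)`); resolving an
extent against a target region applies the relation above and returns a
verdict (`identical`/`contained`/`overlap`/`overlap_of_part`) with a
replayable reasoning trail.

**Interpretation rules.** Tracer transport direction turns observations
into directed evidence: an *anterograde* tracer travels from cell bodies
to axon terminals, so an anterograde injection matching the origin with
axonal label (`fibers`/`terminals`) matching the termination supports
origin → termination; a *retrograde* tracer travels from axons back to
cell bodies, so a retrograde injection matching the termination with
`cellular` label matching the origin supports the same projection.
Labeling density (a seven-point ordinal scale plus `present-unknown`) maps
monotonically onto connection strength (`none < weak < moderate <
strong`); `no label` rows are negative reports and contribute no evidence.
The connection matrix holds, per ordered region pair, the strongest
strength over the pair's evidence and the evidence count.

## Worked example

The built-in fixtures reconstruct a five-study evidence set for the
projection from hippocampal field CA1 to entorhinal cortex (ENT):

```sh
kefed fixtures export --what reference-model --out demo
kefed fixtures export --what demo-atlas --out demo
kefed fixtures export --what worked-example --out demo
cd demo
kefed matrix evidence --model reference-model.json --data worked-example.csv \
    --atlas demo-atlas.csv --config worked-example-config.json \
    --origin CA1 --termination ENT
```

prints

```
publication experiment_id  row_index origin termination strength   direction  directness  injection_spread                                   trail
  Beckstead  beckstead-e1          0    CA1         ENT     weak  retrograde      direct             False injection:identical; labeling:identical
  Beckstead  beckstead-e2          1    CA1         ENT     weak  retrograde    via_part             False injection:contained; labeling:identical
  Beckstead  beckstead-e3          2    CA1         ENT     weak  retrograde    via_part             False injection:contained; labeling:identical
     Deacon     deacon-e1          3    CA1         ENT     weak  retrograde via_overlap              True   injection:overlap; labeling:identical
     Deacon     deacon-e2          4    CA1         ENT     weak  retrograde via_overlap              True   injection:overlap; labeling:identical
     Deacon     deacon-e3          5    CA1         ENT     weak  retrograde via_overlap              True   injection:overlap; labeling:identical
  Swanson-a  swanson-a-e1          6    CA1         ENT     weak  retrograde      direct             False injection:identical; labeling:identical
  Swanson-b  swanson-b-e1          7    CA1         ENT     weak  retrograde      direct             False injection:identical; labeling:identical
  van-Groen  van-groen-e1          8    CA1         ENT     weak anterograde      direct             False injection:identical; labeling:identical
  van-Groen  van-groen-e2          9    CA1         ENT     weak anterograde      direct             False injection:identical; labeling:identical

10 evidence rows from 5 publications
```

Ten observation rows from five publications support CA1 → ENT: injections
into named subregions of ENT count through containment reasoning
(`via_part`), and the three spreading injections that merely overlapped
ENT count through overlap reasoning (`via_overlap`, with the injection
spread flagged). All strengths are `weak` because the source reports
presence only (`present-unknown` density). Aggregating into a matrix:

```sh
kefed matrix build --model reference-model.json --data worked-example.csv \
    --atlas demo-atlas.csv --config worked-example-config.json \
    --regions CA1,ENT,POST,RSP
```

```
origin,CA1,ENT,POST,RSP
CA1,-,weak:10,none:0,none:0
ENT,none:0,-,none:0,none:0
POST,none:0,none:0,-,none:0
RSP,none:0,none:0,none:0,-
```

Each cell is `strength:count`; only CA1 → ENT has evidence, and the
per-cell drill-down above is exactly its provenance. A `--direct-only`
switch excludes the overlap-class evidence from the aggregation.

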