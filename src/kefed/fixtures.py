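"""Built-in reference artifacts and seeded random generators.

``reference_model`` reconstructs the generic tract-tracing protocol (rat
subject → injection → perfusion → brain → sectioning → sections →
immunohistochemistry → slides → neuroanatomical mapping) with its variables;
``demo_atlas`` the small hippocampal-system parcellation used by the worked
example; ``worked_example`` the five-study CA1 → entorhinal-cortex evidence
set.  ``random_design``/``random_atlas``/``random_corpus`` produce seeded
synthetic inputs for property testing: identical seed and knobs give an
identical artifact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .atlas import Atlas, Region, write_atlas
from .data import ObservationRow, ObservationTable, RegionExtent, write_table
from .errors import GeneratorParameterError
from .interpreter import (
    DENSITY_LEVELS,
    PRESENT_UNKNOWN,
    DEFAULT_BINDING,
    Strength,
    TracerRegistry,
    default_config,
)
from .model import KefedEdge, KefedModel, KefedNode, ValueDomain, write_model

__all__ = [
    "reference_model",
    "demo_atlas",
    "worked_example",
    "CorpusSpec",
    "random_corpus",
    "random_design",
    "random_atlas",
    "export_fixtures",
]

REFERENCE_MODEL_ID = "tract-tracing"

#: node ids of the reference model's variables (match the default binding)
TAXONOMIC_CLASS = "taxonomic-class"
INJECTION_CHEMICAL = DEFAULT_BINDING.injection_chemical
INJECTION_LOCATION = DEFAULT_BINDING.injection_location
MAPPED_LOCATION = DEFAULT_BINDING.labeling_location
LABELING_TYPE = DEFAULT_BINDING.labeling_type
LABELING_DENSITY = DEFAULT_BINDING.labeling_density


def reference_model() -> KefedModel:
    """The generic tract-tracing experimental design.

    The workflow alternates materials and activities from the experimental
    subject through material processing to neuroanatomical analysis.  The
    injection activity carries the taxonomic-class constant and the
    injection location/chemical parameters; the mapping activity carries
    the surveyed (mapped) location parameter and the two measurements:
    labeling type (nominal: cellular, fibers, terminals) and labeling
    density (the seven-point ordinal scale plus ``present-unknown``).
    """
    free_text = ValueDomain(kind="free_text")
    extent = ValueDomain(kind="region_extent")
    nodes = [
        # materials
        KefedNode("subject", "material", "experimental subject", "obi:OBI_0100026"),
        KefedNode("injected-subject", "material", "injected subject"),
        KefedNode("brain", "material", "brain", "fma:FMA_50801"),
        KefedNode("tissue-sections", "material", "tissue sections", "nif:birnlex_2169"),
        KefedNode("slides", "material", "immunostained slides"),
        # activities
        KefedNode("injection", "activity", "injection", "obi:OBI_0000426"),
        KefedNode("perfusion", "activity", "perfusion", "obi:OBI_0000919"),
        KefedNode("sectioning", "activity", "tissue sectioning", "nif:birnlex_2156"),
        KefedNode("immunohistochemistry", "activity", "immunohistochemistry",
                  "nif:nlx_inv_20090609"),
        KefedNode("mapping", "activity", "neuroanatomical mapping and analysis",
                  "obi:OBI_0600020"),
        # variables
        KefedNode(TAXONOMIC_CLASS, "constant", "taxonomic class", domain=free_text),
        KefedNode(INJECTION_CHEMICAL, "parameter", "injection chemical", domain=free_text),
        KefedNode(INJECTION_LOCATION, "parameter", "injection location", domain=extent),
        KefedNode(MAPPED_LOCATION, "parameter", "mapped location", domain=extent),
        KefedNode(LABELING_TYPE, "measurement", "labeling type",
                  domain=ValueDomain(kind="nominal", levels=("cellular", "fibers", "terminals"))),
        KefedNode(LABELING_DENSITY, "measurement", "labeling density",
                  domain=ValueDomain(kind="ordinal",
                                     levels=(*DENSITY_LEVELS, PRESENT_UNKNOWN))),
    ]
    flow = [
        ("subject", "injection"), ("injection", "injected-subject"),
        ("injected-subject", "perfusion"), ("perfusion", "brain"),
        ("brain", "sectioning"), ("sectioning", "tissue-sections"),
        ("tissue-sections", "immunohistochemistry"), ("immunohistochemistry", "slides"),
        ("slides", "mapping"),
    ]
    edges = [KefedEdge(s, t, "flow") for s, t in flow]
    edges += [
        KefedEdge(TAXONOMIC_CLASS, "injection", "parameter_of"),
        KefedEdge(INJECTION_CHEMICAL, "injection", "parameter_of"),
        KefedEdge(INJECTION_LOCATION, "injection", "parameter_of"),
        KefedEdge(MAPPED_LOCATION, "mapping", "parameter_of"),
        KefedEdge("mapping", LABELING_TYPE, "measurement_of"),
        KefedEdge("mapping", LABELING_DENSITY, "measurement_of"),
    ]
    return KefedModel(
        id=REFERENCE_MODEL_ID,
        name="generic tract-tracing experiment",
        description=("Workflow model of a tract-tracing experiment: tracer "
                     "injection, histological processing, and mapping of "
                     "transported label onto a brain parcellation."),
        nodes=tuple(nodes), edges=tuple(edges))


#: synthetic stand-ins for the unnamed areas the Deacon injections spread into
SYNTHETIC_NEIGHBOURS = ("ADJ1", "ADJ2", "ADJ3")


def demo_atlas() -> Atlas:
    """Small hippocampal-system demo parcellation.

    Entorhinal cortex (ENT) has lateral/medial parts (ENTl, ENTm); the
    retrosplenial area (RSP) has dorsal and ventral parts, the ventral one
    further divided (RSPv-a, RSPv-b/c).  The ADJ* regions are synthetic
    stand-ins for the unnamed areas adjacent to ENT that the worked
    example's spreading injections also covered.  The base atlas asserts
    no overlap pairs: overlap enters through drawn extents in the data.
    """
    regions = [
        Region("CA1", "field CA1 of the hippocampus", "demo"),
        Region("ENT", "entorhinal cortex", "demo"),
        Region("ENTl", "entorhinal cortex, lateral part", "demo"),
        Region("ENTm", "entorhinal cortex, medial part", "demo"),
        Region("POST", "postsubiculum", "demo"),
        Region("RSP", "retrosplenial area", "demo"),
        Region("RSPd", "retrosplenial area, dorsal part", "demo"),
        Region("RSPv", "retrosplenial area, ventral part", "demo"),
        Region("RSPv-a", "retrosplenial area, ventral part, zone a", "demo"),
        Region("RSPv-b/c", "retrosplenial area, ventral part, zones b/c", "demo"),
    ] + [Region(a, f"synthetic region adjacent to ENT ({a})", "demo-synthetic")
         for a in SYNTHETIC_NEIGHBOURS]
    ppo = [
        ("ENTl", "ENT"), ("ENTm", "ENT"),
        ("RSPd", "RSP"), ("RSPv", "RSP"),
        ("RSPv-a", "RSPv"), ("RSPv-b/c", "RSPv"),
    ]
    return Atlas(regions, proper_part_of=ppo)


def _coext(abbrev: str) -> RegionExtent:
    return RegionExtent(assertions=(("coextensive_with", abbrev),))


def worked_example() -> tuple[ObservationTable, TracerRegistry]:
    """The five-study CA1 → ENT evidence set.

    Retrograde studies: one with three injections into ENT and its
    lateral/medial parts, one with three spreading injections that each
    overlapped ENT plus an adjacent area, and two single-injection
    experiments published separately — all with cellular label in CA1.
    One anterograde study made two injections into CA1 and found terminal
    label in ENT.  Densities are recorded as ``present-unknown`` because
    the source reports presence only.
    """
    def row(exp: str, pub: str, chemical: str, injection: RegionExtent,
            mapped: RegionExtent, ltype: str) -> ObservationRow:
        return ObservationRow(experiment_id=exp, publication=pub, values={
            TAXONOMIC_CLASS: "Rattus norvegicus",
            INJECTION_CHEMICAL: chemical,
            INJECTION_LOCATION: injection,
            MAPPED_LOCATION: mapped,
            LABELING_TYPE: ltype,
            LABELING_DENSITY: PRESENT_UNKNOWN,
        })

    rows = [
        # retrograde, three injections: ENT and its two named parts
        row("beckstead-e1", "Beckstead", "HRP", _coext("ENT"), _coext("CA1"), "cellular"),
        row("beckstead-e2", "Beckstead", "HRP", _coext("ENTl"), _coext("CA1"), "cellular"),
        row("beckstead-e3", "Beckstead", "HRP", _coext("ENTm"), _coext("CA1"), "cellular"),
        # retrograde, three spreading injections overlapping ENT
        row("deacon-e1", "Deacon", "HRP",
            RegionExtent((("overlaps", "ENT"), ("overlaps", "ADJ1"))),
            _coext("CA1"), "cellular"),
        row("deacon-e2", "Deacon", "HRP",
            RegionExtent((("overlaps", "ENT"), ("overlaps", "ADJ2"))),
            _coext("CA1"), "cellular"),
        row("deacon-e3", "Deacon", "HRP",
            RegionExtent((("overlaps", "ENT"), ("overlaps", "ADJ3"))),
            _coext("CA1"), "cellular"),
        # two separately published single-injection retrograde experiments
        row("swanson-a-e1", "Swanson-a", "HRP", _coext("ENT"), _coext("CA1"), "cellular"),
        row("swanson-b-e1", "Swanson-b", "HRP", _coext("ENT"), _coext("CA1"), "cellular"),
        # anterograde, two injections into CA1, terminal label in ENT
        row("van-groen-e1", "van-Groen", "PHAL", _coext("CA1"), _coext("ENT"), "terminals"),
        row("van-groen-e2", "van-Groen", "PHAL", _coext("CA1"), _coext("ENT"), "terminals"),
    ]
    registry = TracerRegistry({"HRP": "retrograde", "PHAL": "anterograde"})
    return ObservationTable(model_id=REFERENCE_MODEL_ID, rows=rows), registry


# ---------------------------------------------------------------------------
# seeded random generators


def random_design(seed: int, max_activities: int = 4) -> KefedModel:
    """A random valid workflow model (bounded size) for property testing.

    Activities consume one or two existing materials (sometimes through a
    branch or fork), produce a new material, and carry random parameters
    and constants; a random non-empty subset of activities gets
    measurements.  Parameters are occasionally shared between activities,
    exercising the union semantics of context derivation.
    """
    rng = random.Random(seed)
    nodes: list[KefedNode] = [KefedNode("m0", "material", "m0")]
    edges: list[KefedEdge] = []
    materials = ["m0"]
    params: list[str] = []
    free_text = ValueDomain(kind="free_text")
    n_act = rng.randint(1, max(1, max_activities))
    n_ctrl = n_param = 0
    for k in range(n_act):
        aid = f"a{k}"
        nodes.append(KefedNode(aid, "activity", aid))
        n_src = 1 if len(materials) == 1 or rng.random() < 0.6 else 2
        for src in rng.sample(materials, n_src):
            if rng.random() < 0.25:
                ckind = rng.choice(["branch", "fork"])
                cid = f"{ckind[0]}{n_ctrl}"
                n_ctrl += 1
                nodes.append(KefedNode(cid, ckind, cid))
                edges.append(KefedEdge(src, cid, "flow"))
                edges.append(KefedEdge(cid, aid, "flow"))
            else:
                edges.append(KefedEdge(src, aid, "flow"))
        for _ in range(rng.randint(0, 2)):
            kind = "constant" if rng.random() < 0.3 else "parameter"
            pid = f"p{n_param}"
            n_param += 1
            nodes.append(KefedNode(pid, kind, pid, domain=free_text))
            edges.append(KefedEdge(pid, aid, "parameter_of"))
            params.append(pid)
        if params and rng.random() < 0.25:
            edges.append(KefedEdge(rng.choice(params), aid, "parameter_of"))
        mid = f"m{k + 1}"
        nodes.append(KefedNode(mid, "material", mid))
        edges.append(KefedEdge(aid, mid, "flow"))
        materials.append(mid)
    n_meas = rng.randint(1, min(2, n_act))
    for j, aid in enumerate(rng.sample([f"a{k}" for k in range(n_act)], n_meas)):
        mid = f"meas{j}"
        nodes.append(KefedNode(mid, "measurement", mid, domain=free_text))
        edges.append(KefedEdge(aid, mid, "measurement_of"))
    return KefedModel(id=f"random-design-{seed}", nodes=tuple(nodes), edges=tuple(edges))


def random_atlas(seed: int, n_regions: int = 12, parent_prob: float = 0.7,
                 extra_parent_prob: float = 0.15, overlap_prob: float = 0.15) -> Atlas:
    """A random atlas (containment DAG + overlap pairs) for property testing."""
    if n_regions <= 0:
        raise GeneratorParameterError("n_regions must be positive")
    rng = random.Random(seed)
    names = [f"R{i}" for i in range(n_regions)]
    ppo: list[tuple[str, str]] = []
    for i in range(1, n_regions):
        if rng.random() < parent_prob:
            ppo.append((names[i], names[rng.randrange(i)]))
            if i > 1 and rng.random() < extra_parent_prob:
                j = rng.randrange(i)
                if (names[i], names[j]) not in ppo:
                    ppo.append((names[i], names[j]))
    overlaps = [(names[i], names[j])
                for i in range(n_regions) for j in range(i + 1, n_regions)
                if rng.random() < overlap_prob]
    return Atlas([Region(n, atlas_source="random") for n in names],
                 proper_part_of=ppo, overlaps=overlaps)


@dataclass(frozen=True)
class CorpusSpec:
    """Knobs of the synthetic tract-tracing corpus generator."""

    seed: int
    n_regions: int = 18
    depth: int = 2
    overlap_fraction: float = 0.3
    n_experiments: int = 12
    ground_truth: Optional[dict] = None


# density labels that encode each positive strength under the default map
_STRENGTH_DENSITIES = {
    Strength.WEAK: ("very sparse label", "sparse label"),
    Strength.MODERATE: ("sparse/moderate label", "moderate label"),
    Strength.STRONG: ("moderate/dense label", "dense label"),
}


def random_corpus(spec: CorpusSpec) -> tuple[Atlas, ObservationTable, TracerRegistry, dict]:
    """A seeded synthetic corpus with a known ground-truth connectome.

    The atlas is a forest of top-level regions with subtrees up to
    ``spec.depth`` deep; ground-truth projections connect distinct
    top-level regions.  Every projection is reported by at least one
    observation row whose density encodes its strength under the default
    density→strength map; injections land in the region itself or a
    proper part, or (with probability ``overlap_fraction``) are drawn as
    extents that merely overlap it.  Negative ``no label`` distractor
    rows cover some unconnected pairs.  Reporting is noiseless: running
    the interpretation pipeline over the top-level regions recovers the
    ground truth exactly.
    """
    if spec.n_regions <= 0:
        raise GeneratorParameterError("n_regions must be positive")
    if spec.depth < 0:
        raise GeneratorParameterError("depth must be non-negative")
    if not 0.0 <= spec.overlap_fraction <= 1.0:
        raise GeneratorParameterError("overlap_fraction must lie in [0, 1]")
    rng = random.Random(spec.seed)

    n_roots = max(2, min(spec.n_regions, spec.n_regions // (spec.depth + 2) + 2))
    names = [f"R{i}" for i in range(spec.n_regions)]
    roots = names[:n_roots]
    depth_of = {r: 0 for r in roots}
    root_of = {r: r for r in roots}
    ppo: list[tuple[str, str]] = []
    for name in names[n_roots:]:
        eligible = [r for r in names if r in depth_of and depth_of[r] < spec.depth]
        parent = rng.choice(eligible) if eligible else rng.choice(roots)
        ppo.append((name, parent))
        depth_of[name] = depth_of.get(parent, 0) + 1
        root_of[name] = root_of[parent]

    overlaps: list[tuple[str, str]] = []
    if spec.overlap_fraction > 0:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if root_of[a] == root_of[b] and a != b and rng.random() < spec.overlap_fraction * 0.2:
                    overlaps.append((a, b))
    atlas = Atlas([Region(n, atlas_source="synthetic") for n in names],
                  proper_part_of=ppo, overlaps=overlaps)
    # drop overlap pairs that accidentally pair ancestor/descendant: keep atlas
    # semantics clean (a region does not 'overlap' its own part)
    clean = [(a, b) for a, b in overlaps
             if b not in atlas.ancestors(a) and a not in atlas.ancestors(b)]
    if len(clean) != len(overlaps):
        atlas = Atlas([Region(n, atlas_source="synthetic") for n in names],
                      proper_part_of=ppo, overlaps=clean)

    members = {r: sorted({n for n in names if root_of[n] == r}) for r in roots}

    if spec.ground_truth is not None:
        truth = {tuple(k): (v if isinstance(v, Strength) else Strength.from_label(str(v)))
                 for k, v in spec.ground_truth.items()}
        for o, t in truth:
            if o not in roots or t not in roots or o == t:
                raise GeneratorParameterError(
                    f"ground-truth pair ({o!r}, {t!r}) must join distinct top-level regions")
    else:
        pairs = [(o, t) for o in roots for t in roots if o != t]
        rng.shuffle(pairs)
        chosen = pairs[:min(spec.n_experiments, len(pairs))]
        truth = {p: rng.choice((Strength.WEAK, Strength.MODERATE, Strength.STRONG))
                 for p in sorted(chosen)}

    registry = TracerRegistry({"HRP": "retrograde", "PHAL": "anterograde"})

    def pick_site(region: str) -> str:
        pool = members[region]
        return rng.choice(pool)

    def extent_for(region: str, allow_overlap: bool) -> RegionExtent:
        if allow_overlap and rng.random() < spec.overlap_fraction:
            parts = sorted(atlas.descendants(region))
            target = rng.choice(parts) if parts else region
            return RegionExtent(assertions=(("overlaps", target),))
        return _coext(pick_site(region))

    rows: list[ObservationRow] = []
    exp_n = 0

    def emit(origin: str, termination: str, density: str):
        nonlocal exp_n
        retro = rng.random() < 0.5
        if retro:
            inj, lab, chem, ltype = termination, origin, "HRP", "cellular"
        else:
            inj, lab, chem, ltype = origin, termination, "PHAL", rng.choice(("fibers", "terminals"))
        rows.append(ObservationRow(
            experiment_id=f"exp-{exp_n:03d}", publication=f"pub-{exp_n:03d}",
            values={
                TAXONOMIC_CLASS: "Rattus norvegicus",
                INJECTION_CHEMICAL: chem,
                INJECTION_LOCATION: extent_for(inj, allow_overlap=True),
                MAPPED_LOCATION: extent_for(lab, allow_overlap=False),
                LABELING_TYPE: ltype,
                LABELING_DENSITY: density,
            }))
        exp_n += 1

    for (o, t), s in sorted(truth.items()):
        emit(o, t, rng.choice(_STRENGTH_DENSITIES[s]))
        if rng.random() < 0.3:  # corroborating weaker-or-equal report
            weaker = rng.choice([x for x in Strength if Strength.NONE < x <= s])
            emit(o, t, rng.choice(_STRENGTH_DENSITIES[weaker]))

    negatives = [(o, t) for o in roots for t in roots if o != t and (o, t) not in truth]
    rng.shuffle(negatives)
    for o, t in negatives[:min(3, len(negatives))]:
        emit(o, t, "no label")

    table = ObservationTable(model_id=REFERENCE_MODEL_ID, rows=rows)
    return atlas, table, registry, dict(truth)


# ---------------------------------------------------------------------------
# export


def export_fixtures(what: str, outdir: Union[str, Path]) -> list[Path]:
    """Write a fixture in the standard on-disk formats; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = reference_model()
    written: list[Path] = []
    if what == "reference-model":
        p = out / "reference-model.json"
        write_model(model, p)
        written.append(p)
    elif what == "demo-atlas":
        p = out / "demo-atlas.csv"
        write_atlas(demo_atlas(), p)
        written.append(p)
    elif what == "worked-example":
        table, registry = worked_example()
        p = out / "worked-example.csv"
        write_table(table, p, model)
        written.append(p)
        import json as _json

        _, scale = default_config()
        cfg = {"tracers": registry.as_dict(),
               "density_map": {k: v.label for k, v in scale.density_map.items()}}
        pc = out / "worked-example-config.json"
        pc.write_text(_json.dumps(cfg, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(pc)
    else:
        raise GeneratorParameterError(
            f"unknown fixture {what!r}; expected reference-model, demo-atlas or worked-example")
    return written
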