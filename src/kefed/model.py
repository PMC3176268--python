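"""Experimental-design graphs and measurement-context derivation.

An experimental protocol is represented as a directed acyclic workflow of
*materials* (the subject, tissue, slides, ...) and *activities* (injection,
sectioning, analysis, ...), optionally divided by *branch*/*fork* control
nodes.  Variables hang off activities: *parameters* and *constants* describe
the conditions under which an activity runs (``parameter_of`` edges), and
*measurements* record its outputs (``measurement_of`` edges).

The payoff of the representation is that each measurement carries an
explicit context: every parameter or constant attached to an activity on
some workflow path from a start node to the measuring activity indexes the
measurement.  :func:`derive_context` computes that set, and
:func:`derive_form` assembles the contexts of all measurements into the
column schema of a data-entry table, so observation records always retain
the conditions needed to interpret them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import networkx as nx

from .errors import (
    DocumentParseError,
    ModelValidationError,
    NodeKindError,
    UnknownNodeError,
)

__all__ = [
    "ValueDomain",
    "KefedNode",
    "KefedEdge",
    "KefedModel",
    "MeasurementContext",
    "FormColumn",
    "FormSpec",
    "Violation",
    "ValidationReport",
    "validate_model",
    "derive_context",
    "derive_form",
    "read_model",
    "write_model",
    "model_from_dict",
    "model_to_dict",
    "model_schema",
]

DOMAIN_KINDS = ("nominal", "ordinal", "free_text", "region_extent", "numeric")
NODE_KINDS = ("activity", "material", "parameter", "constant", "measurement", "branch", "fork")
EDGE_KINDS = ("flow", "parameter_of", "measurement_of")

#: node kinds that may carry a value domain
VARIABLE_KINDS = frozenset({"parameter", "constant", "measurement"})
#: node kinds that may appear in the workflow (flow) subgraph
FLOW_KINDS = frozenset({"material", "activity", "branch", "fork"})
#: control-flow nodes transparent to path tracing
CONTROL_KINDS = frozenset({"branch", "fork"})

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*:\S+$")


@dataclass(frozen=True)
class ValueDomain:
    """The set of values a variable may take.

    ``levels`` is meaningful for nominal and ordinal kinds (for ordinal
    domains the order of ``levels`` is the scale order); ``units`` for
    numeric ones.
    """

    kind: str
    levels: tuple[str, ...] = ()
    units: Optional[str] = None

    def contains(self, value: object) -> bool:
        """Whether ``value`` is a member of this domain.

        Region extents are validated structurally by the data layer; here
        any object exposing ``assertions`` is accepted.
        """
        if self.kind in ("nominal", "ordinal"):
            return isinstance(value, str) and value in self.levels
        if self.kind == "free_text":
            return isinstance(value, str)
        if self.kind == "numeric":
            return isinstance(value, (int, float)) and not isinstance(value, bool)
        if self.kind == "region_extent":
            return hasattr(value, "assertions")
        return False


@dataclass(frozen=True)
class KefedNode:
    id: str
    kind: str
    label: str = ""
    ontology_term: Optional[str] = None
    domain: Optional[ValueDomain] = None

    @property
    def is_variable(self) -> bool:
        return self.kind in VARIABLE_KINDS


@dataclass(frozen=True)
class KefedEdge:
    source: str
    target: str
    kind: str


def _node_sort_key(n: KefedNode):
    return n.id


def _edge_sort_key(e: KefedEdge):
    return (e.kind, e.source, e.target)


@dataclass(frozen=True)
class KefedModel:
    """A complete experimental design.

    Nodes and edges are stored in a canonical sorted order, so two models
    built from the same elements compare equal regardless of the order in
    which a document listed them.
    """

    id: str
    name: str = ""
    description: str = ""
    nodes: tuple[KefedNode, ...] = ()
    edges: tuple[KefedEdge, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes, key=_node_sort_key)))
        object.__setattr__(self, "edges", tuple(sorted(set(self.edges), key=_edge_sort_key)))

    # -- lookups ---------------------------------------------------------
    def node(self, node_id: str) -> KefedNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise UnknownNodeError(f"no node with id {node_id!r} in model {self.id!r}")

    def has_node(self, node_id: str) -> bool:
        return any(n.id == node_id for n in self.nodes)

    def nodes_of_kind(self, *kinds: str) -> tuple[KefedNode, ...]:
        return tuple(n for n in self.nodes if n.kind in kinds)

    @property
    def measurements(self) -> tuple[KefedNode, ...]:
        return self.nodes_of_kind("measurement")

    def edges_of_kind(self, kind: str) -> tuple[KefedEdge, ...]:
        return tuple(e for e in self.edges if e.kind == kind)

    # -- graph views -----------------------------------------------------
    def flow_graph(self) -> nx.DiGraph:
        """The workflow subgraph (materials/activities/branches/forks)."""
        g = nx.DiGraph()
        for n in self.nodes:
            if n.kind in FLOW_KINDS:
                g.add_node(n.id, kind=n.kind)
        for e in self.edges_of_kind("flow"):
            if g.has_node(e.source) and g.has_node(e.target):
                g.add_edge(e.source, e.target)
        return g

    def attachments(self, variable_id: str) -> tuple[str, ...]:
        """Activity ids a parameter/constant is attached to."""
        return tuple(sorted(e.target for e in self.edges_of_kind("parameter_of") if e.source == variable_id))

    def measuring_activities(self, measurement_id: str) -> tuple[str, ...]:
        return tuple(sorted(e.source for e in self.edges_of_kind("measurement_of") if e.target == measurement_id))


@dataclass(frozen=True)
class MeasurementContext:
    """The parameters/constants that index one measurement."""

    measurement_id: str
    context_ids: tuple[str, ...]


@dataclass(frozen=True)
class FormColumn:
    node_id: str
    role: str  # constant | parameter | measurement
    domain: Optional[ValueDomain]
    label: str
    fixed: bool = False  # constants are fixed per experiment


@dataclass(frozen=True)
class FormSpec:
    """Column schema of the data-entry table derived from a model."""

    model_id: str
    columns: tuple[FormColumn, ...]

    def column(self, node_id: str) -> FormColumn:
        for c in self.columns:
            if c.node_id == node_id:
                return c
        raise UnknownNodeError(f"no form column for node {node_id!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.columns)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    subjects: tuple[str, ...] = ()


class ValidationReport:
    """A list of invariant violations; empty means valid."""

    def __init__(self, violations: Iterable[Violation] = ()):
        self._violations = list(violations)

    @property
    def ok(self) -> bool:
        return not self._violations

    def __bool__(self) -> bool:  # truthy when *valid*, matching `if report:`
        return self.ok

    def __iter__(self) -> Iterator[Violation]:
        return iter(self._violations)

    def __len__(self) -> int:
        return len(self._violations)

    def codes(self) -> list[str]:
        return [v.code for v in self._violations]

    def render(self) -> str:
        if self.ok:
            return "valid: no violations"
        lines = []
        for v in self._violations:
            subj = f" [{', '.join(v.subjects)}]" if v.subjects else ""
            lines.append(f"{v.code}: {v.message}{subj}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"ValidationReport({len(self._violations)} violations)"


def _effective_flow_neighbours(model_nodes: dict, g: nx.DiGraph, start: str, forward: bool) -> set:
    """Nearest non-control flow nodes reachable through branch/fork chains."""
    seen, out, stack = set(), set(), [start]
    while stack:
        cur = stack.pop()
        neigh = g.successors(cur) if forward else g.predecessors(cur)
        for n in neigh:
            if n in seen:
                continue
            seen.add(n)
            if model_nodes[n].kind in CONTROL_KINDS:
                stack.append(n)
            else:
                out.add(n)
    return out


def validate_model(model: KefedModel) -> ValidationReport:
    """Check every structural invariant; violations are data, not errors."""
    v: list[Violation] = []
    ids = [n.id for n in model.nodes]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        v.append(Violation("duplicate-node-id", "node ids must be unique", tuple(dup)))
    by_id = {n.id: n for n in model.nodes}

    for n in model.nodes:
        if n.kind not in NODE_KINDS:
            v.append(Violation("unknown-node-kind", f"unknown node kind {n.kind!r}", (n.id,)))
            continue
        if n.is_variable and n.domain is None:
            v.append(Violation("missing-domain", "variables must declare a value domain", (n.id,)))
        if not n.is_variable and n.domain is not None:
            v.append(Violation("spurious-domain", f"{n.kind} nodes carry no value domain", (n.id,)))
        if n.ontology_term is not None and not _CURIE_RE.match(n.ontology_term):
            v.append(Violation("bad-curie", f"ontology term {n.ontology_term!r} is not prefix:identifier", (n.id,)))
        if n.domain is not None:
            d = n.domain
            if d.kind not in DOMAIN_KINDS:
                v.append(Violation("unknown-domain-kind", f"unknown domain kind {d.kind!r}", (n.id,)))
            if d.kind in ("nominal", "ordinal") and len(set(d.levels)) != len(d.levels):
                v.append(Violation("duplicate-levels", "category levels must be unique", (n.id,)))
            if d.kind == "ordinal" and len(set(d.levels)) < 2:
                v.append(Violation("degenerate-ordinal", "ordinal domains need >=2 ordered levels", (n.id,)))
            if d.kind not in ("nominal", "ordinal") and d.levels:
                v.append(Violation("spurious-levels", f"{d.kind} domains carry no levels", (n.id,)))

    for e in model.edges:
        missing = [x for x in (e.source, e.target) if x not in by_id]
        if missing:
            v.append(Violation("dangling-edge", f"edge endpoints undeclared: {missing}", (e.source, e.target)))
            continue
        if e.kind not in EDGE_KINDS:
            v.append(Violation("unknown-edge-kind", f"unknown edge kind {e.kind!r}", (e.source, e.target)))
            continue
        s, t = by_id[e.source], by_id[e.target]
        if e.kind == "flow":
            bad = [n.id for n in (s, t) if n.kind not in FLOW_KINDS]
            if bad:
                v.append(Violation("flow-endpoint-kind", "flow edges connect materials/activities/branches/forks only", tuple(bad)))
        elif e.kind == "parameter_of":
            if s.kind not in ("parameter", "constant") or t.kind != "activity":
                v.append(Violation("parameter-of-shape", "parameter_of must run parameter/constant -> activity", (e.source, e.target)))
        elif e.kind == "measurement_of":
            if s.kind != "activity" or t.kind != "measurement":
                v.append(Violation("measurement-of-shape", "measurement_of must run activity -> measurement", (e.source, e.target)))

    if not dup and not any(x not in by_id for e in model.edges for x in (e.source, e.target)):
        g = model.flow_graph()
        if g.number_of_nodes() == 0:
            v.append(Violation("no-start", "the workflow has no material/activity nodes"))
        else:
            try:
                cycle = nx.find_cycle(g)
                v.append(Violation("flow-cycle", "the workflow must be acyclic", tuple(n for n, _ in cycle)))
            except nx.NetworkXNoCycle:
                pass
            # alternation: materials and activities must interleave, with
            # branch/fork nodes transparent
            for a, b in g.edges:
                ka, kb = by_id[a].kind, by_id[b].kind
                if ka in CONTROL_KINDS or kb in CONTROL_KINDS:
                    continue
                if ka == kb:
                    v.append(Violation("flow-alternation", f"flow edge joins two {ka} nodes", (a, b)))
            if not any(c.code == "flow-cycle" for c in v):
                for n in model.nodes:
                    if n.kind in CONTROL_KINDS:
                        ups = _effective_flow_neighbours(by_id, g, n.id, forward=False)
                        downs = _effective_flow_neighbours(by_id, g, n.id, forward=True)
                        clash = {by_id[u].kind for u in ups} & {by_id[d].kind for d in downs}
                        if clash:
                            v.append(Violation("flow-alternation", f"{n.kind} {n.id!r} joins two {clash.pop()} nodes", (n.id,)))

        for m in model.measurements:
            k = len(model.measuring_activities(m.id))
            if k != 1:
                v.append(Violation("measurement-cardinality", f"measurement must attach to exactly one activity (found {k})", (m.id,)))
        for p in model.nodes_of_kind("parameter", "constant"):
            if not model.attachments(p.id):
                v.append(Violation("unattached-variable", "parameter/constant must attach to >=1 activity", (p.id,)))
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# context derivation


def _topo_positions(g: nx.DiGraph) -> dict:
    # lexicographic topological order gives a canonical position that is
    # independent of how the document listed nodes and edges
    return {n: i for i, n in enumerate(nx.lexicographical_topological_sort(g))}


def derive_context(model: KefedModel, measurement_id: str) -> MeasurementContext:
    """Parameters/constants indexing ``measurement_id``.

    The context is the union, over every workflow path from a start node to
    the measuring activity, of the parameters and constants attached to
    activities on the path.  In an acyclic workflow this equals the
    attachments of the measuring activity and all its workflow ancestors.

    Ordering is canonical: by topological position of the earliest
    attachment activity, ties broken by node id.
    """
    node = model.node(measurement_id)
    if node.kind != "measurement":
        raise NodeKindError(f"{measurement_id!r} is a {node.kind}, not a measurement")
    g = model.flow_graph()
    if not nx.is_directed_acyclic_graph(g):
        raise ModelValidationError(validate_model(model))
    pos = _topo_positions(g)

    upstream: set[str] = set()
    for act in model.measuring_activities(measurement_id):
        if act in g:
            upstream |= {act} | nx.ancestors(g, act)
    upstream = {a for a in upstream if model.node(a).kind == "activity"}

    keyed = []
    for var in model.nodes_of_kind("parameter", "constant"):
        hits = [a for a in model.attachments(var.id) if a in upstream]
        if hits:
            keyed.append((min(pos[a] for a in hits), var.id))
    ordered = tuple(vid for _, vid in sorted(keyed))
    return MeasurementContext(measurement_id=measurement_id, context_ids=ordered)


def derive_form(model: KefedModel) -> FormSpec:
    """Derive the data-entry column schema by tracing data dependencies.

    Columns are the union of all measurement contexts (each context
    variable once, in canonical order) followed by the measurements.
    Constants are flagged ``fixed``: they hold a single value per
    experiment.
    """
    report = validate_model(model)
    if not report.ok:
        raise ModelValidationError(report)
    g = model.flow_graph()
    pos = _topo_positions(g)

    contexts = [derive_context(model, m.id) for m in model.measurements]
    in_context = {vid for ctx in contexts for vid in ctx.context_ids}

    keyed = []
    for var in model.nodes_of_kind("parameter", "constant"):
        if var.id in in_context:
            keyed.append((min(pos[a] for a in model.attachments(var.id)), var.id))
    columns = [
        FormColumn(node_id=vid, role=model.node(vid).kind, domain=model.node(vid).domain,
                   label=model.node(vid).label or vid, fixed=model.node(vid).kind == "constant")
        for _, vid in sorted(keyed)
    ]
    meas_keyed = sorted((min(pos[a] for a in model.measuring_activities(m.id)), m.id) for m in model.measurements)
    columns += [
        FormColumn(node_id=mid, role="measurement", domain=model.node(mid).domain,
                   label=model.node(mid).label or mid)
        for _, mid in meas_keyed
    ]
    return FormSpec(model_id=model.id, columns=tuple(columns))


# ---------------------------------------------------------------------------
# serialization

_SCHEMA_PATH = Path(__file__).parent / "schemas" / "model.schema.json"


def model_schema() -> dict:
    """The JSON Schema for model documents (shipped with the package)."""
    return json.loads(_SCHEMA_PATH.read_text())


def _expect(cond: bool, message: str, pointer: str):
    if not cond:
        raise DocumentParseError(message, pointer)


def model_from_dict(doc: object) -> KefedModel:
    """Build a model from a parsed JSON document, checking its structure.

    Structural problems raise :class:`DocumentParseError` with a
    JSON-pointer location; semantic invariants are left to
    :func:`validate_model`.
    """
    _expect(isinstance(doc, dict), "model document must be a JSON object", "/")
    for key in ("id", "nodes", "edges"):
        _expect(key in doc, f"missing required key {key!r}", f"/{key}")
    _expect(isinstance(doc["id"], str) and doc["id"], "id must be a non-empty string", "/id")
    for key in ("name", "description"):
        if key in doc:
            _expect(isinstance(doc[key], str), f"{key} must be a string", f"/{key}")
    _expect(isinstance(doc["nodes"], list), "nodes must be an array", "/nodes")
    _expect(isinstance(doc["edges"], list), "edges must be an array", "/edges")

    nodes = []
    for i, nd in enumerate(doc["nodes"]):
        ptr = f"/nodes/{i}"
        _expect(isinstance(nd, dict), "node must be an object", ptr)
        for key in ("id", "kind"):
            _expect(key in nd, f"missing required key {key!r}", f"{ptr}/{key}")
            _expect(isinstance(nd[key], str) and nd[key], f"{key} must be a non-empty string", f"{ptr}/{key}")
        domain = None
        if nd.get("domain") is not None:
            dd = nd["domain"]
            _expect(isinstance(dd, dict), "domain must be an object", f"{ptr}/domain")
            _expect(isinstance(dd.get("kind"), str), "domain.kind must be a string", f"{ptr}/domain/kind")
            levels = dd.get("levels", [])
            _expect(isinstance(levels, list) and all(isinstance(x, str) for x in levels),
                    "domain.levels must be an array of strings", f"{ptr}/domain/levels")
            units = dd.get("units")
            _expect(units is None or isinstance(units, str), "domain.units must be a string", f"{ptr}/domain/units")
            domain = ValueDomain(kind=dd["kind"], levels=tuple(levels), units=units)
        term = nd.get("ontology_term")
        _expect(term is None or isinstance(term, str), "ontology_term must be a string", f"{ptr}/ontology_term")
        nodes.append(KefedNode(id=nd["id"], kind=nd["kind"], label=nd.get("label", ""),
                               ontology_term=term, domain=domain))

    edges = []
    for i, ed in enumerate(doc["edges"]):
        ptr = f"/edges/{i}"
        _expect(isinstance(ed, dict), "edge must be an object", ptr)
        for key in ("source", "target", "kind"):
            _expect(key in ed, f"missing required key {key!r}", f"{ptr}/{key}")
            _expect(isinstance(ed[key], str) and ed[key], f"{key} must be a non-empty string", f"{ptr}/{key}")
        edges.append(KefedEdge(source=ed["source"], target=ed["target"], kind=ed["kind"]))

    return KefedModel(id=doc["id"], name=doc.get("name", ""), description=doc.get("description", ""),
                      nodes=tuple(nodes), edges=tuple(edges))


def model_to_dict(model: KefedModel) -> dict:
    doc: dict = {"id": model.id, "name": model.name, "description": model.description,
                 "nodes": [], "edges": []}
    for n in model.nodes:
        nd: dict = {"id": n.id, "kind": n.kind, "label": n.label}
        if n.ontology_term is not None:
            nd["ontology_term"] = n.ontology_term
        if n.domain is not None:
            dd: dict = {"kind": n.domain.kind}
            if n.domain.levels:
                dd["levels"] = list(n.domain.levels)
            if n.domain.units is not None:
                dd["units"] = n.domain.units
            nd["domain"] = dd
        doc["nodes"].append(nd)
    for e in model.edges:
        doc["edges"].append({"source": e.source, "target": e.target, "kind": e.kind})
    return doc


def read_model(path: Union[str, Path]) -> KefedModel:
    """Read a model document (JSON) from ``path``."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentParseError(f"not valid JSON: {exc}", "/") from exc
    return model_from_dict(doc)


def write_model(model: KefedModel, path: Union[str, Path]) -> None:
    """Write a *valid* model document to ``path`` (deterministic JSON)."""
    report = validate_model(model)
    if not report.ok:
        raise ModelValidationError(report)
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=False) + "\n",
                          encoding="utf-8")
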