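"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid networkx and the package's own graph code: plain
dictionaries, explicit path enumeration and fixpoint closures.
"""

from __future__ import annotations


def oracle_context(model, measurement_id: str) -> set:
    """Context by exhaustive start->activity path enumeration + union."""
    flow_kinds = {"material", "activity", "branch", "fork"}
    kind = {n.id: n.kind for n in model.nodes}
    succ: dict[str, list[str]] = {}
    has_pred: set[str] = set()
    for e in model.edges:
        if e.kind == "flow":
            succ.setdefault(e.source, []).append(e.target)
            has_pred.add(e.target)
    flow_nodes = [n for n, k in kind.items() if k in flow_kinds]
    starts = [n for n in flow_nodes if n not in has_pred]
    attached: dict[str, set[str]] = {}
    for e in model.edges:
        if e.kind == "parameter_of":
            attached.setdefault(e.target, set()).add(e.source)
    targets = [e.source for e in model.edges
               if e.kind == "measurement_of" and e.target == measurement_id]

    context: set[str] = set()

    def walk(node: str, path: list[str], goal: str):
        path.append(node)
        if node == goal:
            for n in path:
                if kind[n] == "activity":
                    context.update(attached.get(n, ()))
        else:
            for nxt in succ.get(node, ()):
                walk(nxt, path, goal)
        path.pop()

    for goal in targets:
        for s in starts:
            walk(s, [], goal)
    return context


def _transitive_closure(pairs) -> set:
    closure = set(pairs)
    changed = True
    while changed:
        changed = False
        for a, b in list(closure):
            for c, d in list(closure):
                if b == c and (a, d) not in closure:
                    closure.add((a, d))
                    changed = True
    return closure


def oracle_is_part_of(atlas, sub: str, super_: str) -> bool:
    return (sub, super_) in _transitive_closure(atlas.proper_part_pairs())


def oracle_part_of_or_overlaps(atlas, sub: str, super_: str) -> bool:
    """Direct evaluation of the four disjuncts of the defined relation."""
    closure = _transitive_closure(atlas.proper_part_pairs())
    ov = set()
    for a, b in atlas.overlap_pairs():
        ov.add((a, b))
        ov.add((b, a))
    regions = [r.abbrev for r in atlas.regions]
    return (
        sub == super_
        or (sub, super_) in closure
        or (sub, super_) in ov
        or any((r, super_) in closure and (sub, r) in ov for r in regions)
    )
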