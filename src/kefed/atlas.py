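"""Qualitative spatial reasoning over a brain parcellation.

An atlas is a set of named regions with two primitive relations:

* ``proper_part_of`` — irreflexive, transitively-closed containment
  (``RSPv-a`` is a proper part of ``RSPv``, which is a proper part of
  ``RSP``);
* ``overlaps`` — symmetric, irreflexive: one region covers part of
  another while also covering territory outside it.

On top of these the defined relation :func:`part_of_or_overlaps` holds
between ``sub`` and ``super`` when any of four disjuncts fires:

1. the two regions are identical;
2. ``sub`` is (transitively) a proper part of ``super``;
3. ``sub`` overlaps ``super``;
4. some region is a proper part of ``super`` and ``sub`` overlaps it.

This is exactly the admissibility test used when matching injection sites
and labeling locations against the row/column regions of a connection
matrix.  Every positive answer carries a :class:`GeoTrail` recording which
disjunct fired and the primitive relation steps used, so downstream
evidence can report *how* a region matched.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
from lxml import etree

from .errors import AtlasIntegrityError, DocumentParseError, UnknownRegionError

__all__ = [
    "Region",
    "Atlas",
    "GeoTrail",
    "VERDICT_ORDER",
    "load_atlas",
    "write_atlas",
    "is_part_of",
    "part_of_or_overlaps",
    "resolve_extent",
]

#: verdict vocabulary, strongest first
VERDICT_ORDER = {"identical": 4, "contained": 3, "overlap": 2, "overlap_of_part": 1, "none": 0}

#: placeholder endpoint for steps asserted by a drawn extent rather than the atlas
EXTENT = "<extent>"


@dataclass(frozen=True)
class Region:
    abbrev: str
    name: str = ""
    atlas_source: str = ""


@dataclass(frozen=True)
class GeoTrail:
    """Reasoning trail behind a spatial verdict.

    ``steps`` are ``(relation, from, to)`` triples using only the
    primitive relations (``identical``, ``proper_part_of``, ``overlaps``)
    plus ``asserted_*`` steps contributed by a drawn region extent.
    """

    verdict: str
    steps: tuple[tuple[str, str, str], ...] = ()

    def replay(self, atlas: "Atlas", extent=None) -> str:
        """Re-derive the verdict from the recorded steps.

        Raises :class:`AtlasIntegrityError` if any step is unsupported by
        the atlas (or, for ``asserted_*`` steps, by ``extent``).
        """
        if self.verdict == "none":
            if self.steps:
                raise AtlasIntegrityError("a 'none' verdict carries no steps")
            return "none"
        asserted = None
        chain_start: Optional[str] = None
        saw_overlap = False
        contained_hops = 0
        prev_to: Optional[str] = None
        for rel, a, b in self.steps:
            if rel.startswith("asserted_"):
                if extent is None or (rel[len("asserted_"):], b) not in tuple(extent.assertions):
                    raise AtlasIntegrityError(f"extent does not assert {rel} -> {b}")
                asserted = rel[len("asserted_"):]
                prev_to = b
                continue
            if rel == "identical":
                if a != b or not atlas.has_region(a):
                    raise AtlasIntegrityError(f"bad identity step {a!r}/{b!r}")
                prev_to = b
            elif rel == "proper_part_of":
                if b not in atlas.parents(a):
                    raise AtlasIntegrityError(f"{a!r} is not declared a proper part of {b!r}")
                if chain_start is None:
                    chain_start = a
                contained_hops += 1
                prev_to = b
            elif rel == "overlaps":
                if frozenset((a, b)) not in atlas._overlap_pairs:
                    raise AtlasIntegrityError(f"{a!r}/{b!r} is not a declared overlap")
                saw_overlap = True
                prev_to = b
            else:
                raise AtlasIntegrityError(f"unknown trail relation {rel!r}")
        # reconstruct the verdict class from the step mix
        if saw_overlap and contained_hops:
            base = "overlap_of_part"
        elif saw_overlap:
            base = "overlap"
        elif contained_hops:
            base = "contained"
        else:
            base = "identical"
        if asserted == "proper_part_of" and base in ("identical", "contained"):
            base = "contained"
        if asserted == "overlaps":
            base = "overlap" if base == "identical" else "overlap_of_part"
        return base


class Atlas:
    """Named regions with containment and overlap relations."""

    def __init__(self, regions: Iterable[Region],
                 proper_part_of: Iterable[tuple[str, str]] = (),
                 overlaps: Iterable[tuple[str, str]] = ()):
        self._regions: dict[str, Region] = {}
        for r in regions:
            if not r.abbrev:
                raise AtlasIntegrityError("region abbreviation must be non-empty")
            if r.abbrev in self._regions:
                raise AtlasIntegrityError(f"duplicate region abbreviation {r.abbrev!r}")
            self._regions[r.abbrev] = r

        self._containment = nx.DiGraph()  # edge child -> parent
        self._containment.add_nodes_from(self._regions)
        for child, parent in proper_part_of:
            self._check_declared(child)
            self._check_declared(parent)
            if child == parent:
                raise AtlasIntegrityError(f"proper parthood is irreflexive: {child!r}")
            self._containment.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(self._containment)
            raise AtlasIntegrityError(
                "containment cycle: " + " -> ".join(a for a, _ in cycle) + f" -> {cycle[0][0]}")
        except nx.NetworkXNoCycle:
            pass

        self._overlap_pairs: set[frozenset] = set()
        for a, b in overlaps:
            self._check_declared(a)
            self._check_declared(b)
            if a == b:
                raise AtlasIntegrityError(f"overlap is irreflexive: {a!r}")
            self._overlap_pairs.add(frozenset((a, b)))

    # -- basic access ----------------------------------------------------
    def _check_declared(self, abbrev: str):
        if abbrev not in self._regions:
            raise UnknownRegionError(f"region {abbrev!r} is not declared in the atlas")

    def has_region(self, abbrev: str) -> bool:
        return abbrev in self._regions

    def region(self, abbrev: str) -> Region:
        self._check_declared(abbrev)
        return self._regions[abbrev]

    @property
    def regions(self) -> tuple[Region, ...]:
        return tuple(self._regions[a] for a in sorted(self._regions))

    def proper_part_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._containment.edges))

    def overlap_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(p)) for p in self._overlap_pairs))

    def parents(self, abbrev: str) -> set:
        self._check_declared(abbrev)
        return set(self._containment.successors(abbrev))

    def children(self, abbrev: str) -> set:
        self._check_declared(abbrev)
        return set(self._containment.predecessors(abbrev))

    def ancestors(self, abbrev: str) -> set:
        """All regions this one is transitively a proper part of."""
        self._check_declared(abbrev)
        return nx.descendants(self._containment, abbrev)

    def descendants(self, abbrev: str) -> set:
        """All transitive proper parts of this region."""
        self._check_declared(abbrev)
        return nx.ancestors(self._containment, abbrev)

    def overlapping(self, abbrev: str) -> set:
        self._check_declared(abbrev)
        return {next(iter(p - {abbrev})) for p in self._overlap_pairs if abbrev in p}

    def top_level(self, abbrev: str) -> set:
        """Root region(s) of the containment hierarchy above ``abbrev``."""
        self._check_declared(abbrev)
        ups = {abbrev} | self.ancestors(abbrev)
        return {a for a in ups if not self.parents(a)}

    # -- reasoning -------------------------------------------------------
    def is_part_of(self, sub: str, super_: str) -> bool:
        """Transitive proper parthood (irreflexive)."""
        self._check_declared(sub)
        self._check_declared(super_)
        return super_ in self.ancestors(sub)

    def _containment_chain(self, sub: str, super_: str) -> tuple[tuple[str, str, str], ...]:
        path = nx.shortest_path(self._containment, sub, super_)
        return tuple(("proper_part_of", a, b) for a, b in zip(path, path[1:]))

    def part_of_or_overlaps(self, sub: str, super_: str) -> tuple[bool, GeoTrail]:
        """The four-disjunct admissibility relation, with its trail.

        Disjuncts are tried in a fixed order (identity, containment,
        direct overlap, overlap-with-a-part) so trails are deterministic;
        for disjunct 4 the lexicographically smallest witnessing part is
        recorded.
        """
        self._check_declared(sub)
        self._check_declared(super_)
        if sub == super_:
            return True, GeoTrail("identical", (("identical", sub, super_),))
        if self.is_part_of(sub, super_):
            return True, GeoTrail("contained", self._containment_chain(sub, super_))
        if frozenset((sub, super_)) in self._overlap_pairs:
            return True, GeoTrail("overlap", (("overlaps", sub, super_),))
        witnesses = sorted(self.descendants(super_) & self.overlapping(sub))
        if witnesses:
            r = witnesses[0]
            steps = (("overlaps", sub, r),) + self._containment_chain(r, super_)
            return True, GeoTrail("overlap_of_part", steps)
        return False, GeoTrail("none")

    def resolve_extent(self, extent, target: str) -> tuple[bool, GeoTrail]:
        """Match an arbitrarily drawn extent against a named target region.

        The extent is a bundle of qualified assertions relating the drawn
        territory to named regions.  Each assertion is tested through
        :meth:`part_of_or_overlaps` on its named region; the verdict class
        is then adjusted for what the assertion itself says:

        * ``coextensive_with N`` — the extent *is* N, so the verdict of
          N-vs-target carries over unchanged;
        * ``proper_part_of N`` — the extent lies strictly inside N, so
          identity of N with the target still only warrants ``contained``;
        * ``overlaps N`` — the extent merely overlaps N, so any match is
          overlap-class (``overlap`` when N is the target itself,
          ``overlap_of_part`` otherwise).

        The strongest verdict over all assertions wins (ties: first
        assertion).  Unresolvable abbreviations raise
        :class:`UnknownRegionError` listing them.
        """
        self._check_declared(target)
        missing = sorted({ab for _, ab in extent.assertions if not self.has_region(ab)})
        if missing:
            raise UnknownRegionError("extent names undeclared regions: " + ", ".join(missing))
        best: Optional[GeoTrail] = None
        for rel, named in extent.assertions:
            ok, base = self.part_of_or_overlaps(named, target)
            if not ok:
                continue
            verdict = base.verdict
            if rel == "proper_part_of" and verdict in ("identical", "contained"):
                verdict = "contained"
            elif rel == "overlaps":
                verdict = "overlap" if verdict == "identical" else "overlap_of_part"
            trail = GeoTrail(verdict, ((f"asserted_{rel}", EXTENT, named),) + base.steps)
            if best is None or VERDICT_ORDER[verdict] > VERDICT_ORDER[best.verdict]:
                best = trail
        if best is None:
            return False, GeoTrail("none")
        return True, best

    def extent_top_level(self, extent) -> set:
        """Top-level regions touched by an extent (for spread detection)."""
        out: set = set()
        for _, named in extent.assertions:
            out |= self.top_level(named)
        return out

    def __repr__(self) -> str:
        return (f"Atlas({len(self._regions)} regions, "
                f"{self._containment.number_of_edges()} containments, "
                f"{len(self._overlap_pairs)} overlaps)")


# ---------------------------------------------------------------------------
# functional wrappers


def is_part_of(atlas: Atlas, sub: str, super_: str) -> bool:
    return atlas.is_part_of(sub, super_)


def part_of_or_overlaps(atlas: Atlas, sub: str, super_: str) -> tuple[bool, GeoTrail]:
    return atlas.part_of_or_overlaps(sub, super_)


def resolve_extent(atlas: Atlas, extent, target: str) -> tuple[bool, GeoTrail]:
    return atlas.resolve_extent(extent, target)


# ---------------------------------------------------------------------------
# I/O

_SECTIONS = ("#regions", "#part_of", "#overlaps")


def _atlas_from_csv_text(text: str, source: str = "") -> Atlas:
    regions: list[Region] = []
    ppo: list[tuple[str, str]] = []
    ov: list[tuple[str, str]] = []
    section = None
    for lineno, row in enumerate(csv.reader(io.StringIO(text)), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        head = row[0].strip()
        if head.startswith("#"):
            if head not in _SECTIONS:
                raise DocumentParseError(f"unknown section {head!r}", f"line {lineno}")
            section = head
            continue
        if section == "#regions":
            name = row[1].strip() if len(row) > 1 else ""
            src = row[2].strip() if len(row) > 2 else source
            regions.append(Region(abbrev=head, name=name, atlas_source=src))
        elif section == "#part_of":
            if len(row) < 2:
                raise DocumentParseError("part_of rows need child,parent", f"line {lineno}")
            ppo.append((head, row[1].strip()))
        elif section == "#overlaps":
            if len(row) < 2:
                raise DocumentParseError("overlaps rows need two regions", f"line {lineno}")
            ov.append((head, row[1].strip()))
        else:
            raise DocumentParseError("data before any section header", f"line {lineno}")
    return Atlas(regions, proper_part_of=ppo, overlaps=ov)


def _atlas_from_bams_xml(data: bytes, source: str) -> Atlas:
    """Import a BAMS-style nomenclature export.

    Accepts region elements (tag ``region`` or ``BrainRegion``, any
    namespace/case) with ``abbreviation``/``abbrev``, ``name`` and
    optional ``parent`` children; ``parent`` holds the abbreviation of the
    containing region and is mapped onto ``proper_part_of``.
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise DocumentParseError(f"not well-formed XML: {exc}", "/") from exc

    def local(tag) -> str:
        return etree.QName(tag).localname.lower() if isinstance(tag, str) else ""

    regions, ppo = [], []
    for el in root.iter():
        if local(el.tag) not in ("region", "brainregion"):
            continue
        fields = {local(c.tag): (c.text or "").strip() for c in el}
        abbrev = fields.get("abbreviation") or fields.get("abbrev")
        if not abbrev:
            raise DocumentParseError("region element lacks an abbreviation",
                                     root.getroottree().getpath(el))
        regions.append(Region(abbrev=abbrev, name=fields.get("name", ""), atlas_source=source))
        if fields.get("parent"):
            ppo.append((abbrev, fields["parent"]))
    return Atlas(regions, proper_part_of=ppo)


def load_atlas(path: Union[str, Path], format: str = "csv") -> Atlas:
    """Load an atlas from a sectioned CSV file or a BAMS-style XML export."""
    p = Path(path)
    if format == "csv":
        return _atlas_from_csv_text(p.read_text(encoding="utf-8"), source=p.stem)
    if format == "bams_xml":
        return _atlas_from_bams_xml(p.read_bytes(), source=p.stem)
    raise DocumentParseError(f"unknown atlas format {format!r}")


def write_atlas(atlas: Atlas, path: Union[str, Path]) -> None:
    """Write the sectioned-CSV serialization (deterministic order)."""
    Path(path).write_text(atlas_to_csv_text(atlas), encoding="utf-8")


def atlas_to_csv_text(atlas: Atlas) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["#regions"])
    for r in atlas.regions:
        w.writerow([r.abbrev, r.name, r.atlas_source])
    w.writerow(["#part_of"])
    for child, parent in atlas.proper_part_pairs():
        w.writerow([child, parent])
    w.writerow(["#overlaps"])
    for a, b in atlas.overlap_pairs():
        w.writerow([a, b])
    return buf.getvalue()
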