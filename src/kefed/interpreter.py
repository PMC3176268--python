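"""Interpretation of tract-tracing observations as connection evidence.

Observations are raw: an injection extent, a tracer chemical, a labeling
extent, a labeling type and an ordinal labeling density.  Turning them into
claims about projections requires background knowledge of tracer transport:

* **anterograde** tracers travel from cell bodies at the injection site to
  axon terminals — so an anterograde injection matching the *origin* with
  axonal label (``fibers``/``terminals``) matching the *termination*
  supports origin → termination;
* **retrograde** tracers travel from axon fibers back to cell bodies — so
  a retrograde injection matching the *termination* with ``cellular``
  label matching the *origin* supports the same projection.

Extent matching goes through the atlas's qualitative reasoning, so
injections into subregions, or extents that merely overlap a region of
interest, still contribute — flagged by ``directness`` and carrying the
full reasoning trail.  Evidence strength comes from a configurable
monotone map of the seven-point density scale onto the four-point
connection-strength scale; rows reporting ``no label`` are negative
reports and contribute no evidence.  Per region pair, the connection
matrix shows the strongest strength over the pair's evidence together
with the evidence count.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .atlas import Atlas, GeoTrail
from .data import ObservationTable, RegionExtent
from .errors import DomainError, TracerConfigError, UnknownRegionError

__all__ = [
    "Strength",
    "DENSITY_LEVELS",
    "PRESENT_UNKNOWN",
    "StrengthScale",
    "TracerRegistry",
    "TractTracingBinding",
    "ConnectionEvidence",
    "ConnectionMatrix",
    "density_to_strength",
    "evidence_for_connection",
    "build_matrix",
    "evidence_report",
    "load_config",
    "default_config",
]

#: the seven-point ordinal labeling-density scale, in scale order
DENSITY_LEVELS = (
    "no label",
    "very sparse label",
    "sparse label",
    "sparse/moderate label",
    "moderate label",
    "moderate/dense label",
    "dense label",
)
#: extra category: labeling present, density not reported
PRESENT_UNKNOWN = "present-unknown"

DIRECTIONS = ("anterograde", "retrograde")
#: labeling types satisfying the anterograde rule (axonal label)
AXONAL_TYPES = frozenset({"fibers", "terminals"})
CELLULAR = "cellular"


class Strength(enum.IntEnum):
    """Ordinal connection strength."""

    NONE = 0
    WEAK = 1
    MODERATE = 2
    STRONG = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Strength":
        try:
            return cls[label.upper()]
        except KeyError:
            raise DomainError(f"unknown strength label {label!r}") from None


@dataclass(frozen=True)
class StrengthScale:
    """Monotone map from labeling density to connection strength.

    ``density_map`` must cover every density level plus the
    ``present-unknown`` category, send ``no label`` to ``none``, and be
    non-decreasing along the density order.
    """

    density_map: Mapping[str, Strength]
    density_order: tuple[str, ...] = DENSITY_LEVELS

    def __post_init__(self):
        dm = {k: (v if isinstance(v, Strength) else Strength.from_label(str(v)))
              for k, v in dict(self.density_map).items()}
        object.__setattr__(self, "density_map", dm)
        missing = [lv for lv in (*self.density_order, PRESENT_UNKNOWN) if lv not in dm]
        if missing:
            raise DomainError(f"density map does not cover {missing}")
        if dm[self.density_order[0]] != Strength.NONE:
            raise DomainError(f"{self.density_order[0]!r} must map to 'none'")
        seq = [dm[lv] for lv in self.density_order]
        if any(a > b for a, b in zip(seq, seq[1:])):
            raise DomainError("density map must be monotone non-decreasing along the density order")

    def strength_of(self, density_label: str) -> Strength:
        if density_label not in self.density_map:
            raise DomainError(
                f"{density_label!r} is not on the density scale "
                f"({', '.join((*self.density_order, PRESENT_UNKNOWN))})")
        return self.density_map[density_label]


def density_to_strength(density_label: str, scale: StrengthScale) -> Strength:
    """Map one density label to its configured connection strength."""
    return scale.strength_of(density_label)


class TracerRegistry:
    """Registered transport directions of tracer chemicals."""

    def __init__(self, directions: Mapping[str, str] = ()):
        self._dir: dict[str, str] = {}
        self.update(dict(directions))

    def update(self, directions: Mapping[str, str]) -> "TracerRegistry":
        for name, direction in directions.items():
            if direction not in DIRECTIONS:
                raise TracerConfigError(
                    f"tracer {name!r}: direction must be one of {DIRECTIONS}, got {direction!r}")
            self._dir[name] = direction
        return self

    def direction(self, chemical: str) -> str:
        try:
            return self._dir[chemical]
        except KeyError:
            raise TracerConfigError(
                f"tracer chemical {chemical!r} is not registered with a transport direction"
            ) from None

    def __contains__(self, chemical: str) -> bool:
        return chemical in self._dir

    def as_dict(self) -> dict:
        return dict(sorted(self._dir.items()))


@dataclass(frozen=True)
class TractTracingBinding:
    """Node ids binding the interpreter to a tract-tracing form."""

    injection_location: str = "injection-location"
    injection_chemical: str = "injection-chemical"
    labeling_location: str = "mapped-location"
    labeling_type: str = "labeling-type"
    labeling_density: str = "labeling-density"


DEFAULT_BINDING = TractTracingBinding()

_OVERLAP_VERDICTS = frozenset({"overlap", "overlap_of_part"})


@dataclass(frozen=True)
class ConnectionEvidence:
    """One observation row interpreted as support for origin → termination."""

    origin: str
    termination: str
    strength: Strength
    direction_used: str
    directness: str  # direct | via_part | via_overlap
    injection_spread: bool
    experiment_id: str
    row_index: int
    publication: str
    injection_trail: GeoTrail
    labeling_trail: GeoTrail


def _directness(injection_trail: GeoTrail, labeling_trail: GeoTrail) -> str:
    verdicts = (injection_trail.verdict, labeling_trail.verdict)
    if any(v in _OVERLAP_VERDICTS for v in verdicts):
        return "via_overlap"
    if all(v == "identical" for v in verdicts):
        return "direct"
    return "via_part"


def evidence_for_connection(origin: str, termination: str, table: ObservationTable,
                            atlas: Atlas, registry: TracerRegistry, scale: StrengthScale,
                            binding: TractTracingBinding = DEFAULT_BINDING,
                            direct_only: bool = False) -> list[ConnectionEvidence]:
    """All rows of ``table`` supporting a projection origin → termination.

    A row matches under the anterograde rule (anterograde tracer, injection
    resolves against the origin, axonal label resolves against the
    termination) or the retrograde rule (retrograde tracer, injection
    resolves against the termination, cellular label resolves against the
    origin).  Rows with density ``no label`` are negative reports and never
    yield evidence.  With ``direct_only`` evidence whose geometric match is
    overlap-class is dropped.
    """
    for r in (origin, termination):
        if not atlas.has_region(r):
            raise UnknownRegionError(f"region {r!r} is not declared in the atlas")
    out: list[ConnectionEvidence] = []
    for i, row in enumerate(table.rows):
        direction = registry.direction(row.values[binding.injection_chemical])
        density = row.values[binding.labeling_density]
        strength = scale.strength_of(density)
        if strength == Strength.NONE:
            continue
        ltype = row.values[binding.labeling_type]
        if direction == "anterograde":
            if ltype not in AXONAL_TYPES:
                continue
            injection_target, labeling_target = origin, termination
        else:
            if ltype != CELLULAR:
                continue
            injection_target, labeling_target = termination, origin
        inj_extent: RegionExtent = row.values[binding.injection_location]
        lab_extent: RegionExtent = row.values[binding.labeling_location]
        inj_ok, inj_trail = atlas.resolve_extent(inj_extent, injection_target)
        if not inj_ok:
            continue
        lab_ok, lab_trail = atlas.resolve_extent(lab_extent, labeling_target)
        if not lab_ok:
            continue
        directness = _directness(inj_trail, lab_trail)
        if direct_only and directness == "via_overlap":
            continue
        out.append(ConnectionEvidence(
            origin=origin, termination=termination, strength=strength,
            direction_used=direction, directness=directness,
            injection_spread=len(atlas.extent_top_level(inj_extent)) > 1,
            experiment_id=row.experiment_id, row_index=i,
            publication=row.publication,
            injection_trail=inj_trail, labeling_trail=lab_trail))
    return out


@dataclass(frozen=True)
class ConnectionMatrix:
    """Strongest evidenced strength (and evidence count) per region pair."""

    regions: tuple[str, ...]
    cells: Mapping[tuple[str, str], tuple[Strength, int]]

    def cell(self, origin: str, termination: str) -> tuple[Strength, int]:
        return self.cells.get((origin, termination), (Strength.NONE, 0))

    def to_frame(self) -> pd.DataFrame:
        """Rows = origins, columns = terminations, cells ``strength:count``."""
        data = {}
        for t in self.regions:
            col = []
            for o in self.regions:
                if o == t:
                    col.append("-")
                else:
                    s, n = self.cell(o, t)
                    col.append(f"{s.label}:{n}")
            data[t] = col
        return pd.DataFrame(data, index=list(self.regions))

    def to_csv_text(self) -> str:
        frame = self.to_frame()
        return frame.to_csv(index_label="origin", lineterminator="\n")


def build_matrix(regions: Sequence[str], table: ObservationTable, atlas: Atlas,
                 registry: TracerRegistry, scale: StrengthScale,
                 binding: TractTracingBinding = DEFAULT_BINDING,
                 direct_only: bool = False) -> ConnectionMatrix:
    """Fill every ordered pair of ``regions`` by max-aggregating evidence."""
    for r in regions:
        if not atlas.has_region(r):
            raise UnknownRegionError(f"region {r!r} is not declared in the atlas")
    cells: dict[tuple[str, str], tuple[Strength, int]] = {}
    for o in regions:
        for t in regions:
            if o == t:
                continue
            ev = evidence_for_connection(o, t, table, atlas, registry, scale,
                                         binding=binding, direct_only=direct_only)
            if ev:
                cells[(o, t)] = (max(e.strength for e in ev), len(ev))
            else:
                cells[(o, t)] = (Strength.NONE, 0)
    return ConnectionMatrix(regions=tuple(regions), cells=cells)


def _trail_summary(e: ConnectionEvidence) -> str:
    return f"injection:{e.injection_trail.verdict}; labeling:{e.labeling_trail.verdict}"


def evidence_report(evidence: Iterable[ConnectionEvidence]) -> pd.DataFrame:
    """Drill-down provenance table, one row per evidence item.

    Sorted by (publication, experiment_id, row index) so evidence groups
    by study.
    """
    cols = ["publication", "experiment_id", "row_index", "origin", "termination",
            "strength", "direction", "directness", "injection_spread", "trail"]
    rows = [
        {"publication": e.publication, "experiment_id": e.experiment_id,
         "row_index": e.row_index, "origin": e.origin, "termination": e.termination,
         "strength": e.strength.label, "direction": e.direction_used,
         "directness": e.directness, "injection_spread": e.injection_spread,
         "trail": _trail_summary(e)}
        for e in evidence
    ]
    frame = pd.DataFrame(rows, columns=cols)
    if len(frame):
        frame = frame.sort_values(["publication", "experiment_id", "row_index"],
                                  kind="stable").reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# configuration

_DEFAULT_CONFIG_PATH = Path(__file__).parent / "config" / "default_config.json"


def _config_from_doc(doc: dict) -> tuple[TracerRegistry, StrengthScale]:
    registry = TracerRegistry(doc.get("tracers", {}))
    scale = StrengthScale(density_map=doc.get("density_map", {}))
    return registry, scale


def load_config(path: Union[str, Path]) -> tuple[TracerRegistry, StrengthScale]:
    """Load a ``{"tracers": ..., "density_map": ...}`` JSON config file."""
    return _config_from_doc(json.loads(Path(path).read_text(encoding="utf-8")))


def default_config() -> tuple[TracerRegistry, StrengthScale]:
    """The packaged default tracer registry and density→strength map."""
    return _config_from_doc(json.loads(_DEFAULT_CONFIG_PATH.read_text(encoding="utf-8")))
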