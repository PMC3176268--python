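"""Observation tables conforming to a model's derived form.

One row is one data point: a single labeling report tied to a single
injection, carrying the full parameter context derived from the model plus
experiment and publication provenance.  Findings in several labeled
locations become several rows sharing an ``experiment_id``.

Region extents — arbitrarily drawn injection sites or labeling territories
— are flat-encoded for CSV cells with a mini-grammar of ``relation(ABBREV)``
segments joined by ``|``::

    part_of(ENTl)|overlaps(PRC)

with relations ``coextensive_with``, ``part_of`` (alias ``proper_part_of``)
and ``overlaps``, plus an optional trailing ``note(...)`` free label.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .errors import (
    DocumentParseError,
    ExtentParseError,
    ModelMismatchError,
    ModelValidationError,
)
from .model import (
    KefedModel,
    ValidationReport,
    Violation,
    derive_form,
    validate_model,
)

__all__ = [
    "RegionExtent",
    "ObservationRow",
    "ObservationTable",
    "parse_extent",
    "format_extent",
    "validate_table",
    "read_table",
    "write_table",
]

EXTENT_RELATIONS = ("coextensive_with", "proper_part_of", "overlaps")

_REL_TOKENS = {
    "coextensive_with": "coextensive_with",
    "proper_part_of": "part_of",
    "overlaps": "overlaps",
}
_TOKEN_RELS = {
    "coextensive_with": "coextensive_with",
    "coextensive": "coextensive_with",
    "part_of": "proper_part_of",
    "proper_part_of": "proper_part_of",
    "overlaps": "overlaps",
}

_SEGMENT_RE = re.compile(r"^\s*([A-Za-z_]+)\(([^()|]*)\)\s*$")


@dataclass(frozen=True)
class RegionExtent:
    """A drawn region expressed by qualified relations to named regions."""

    assertions: tuple[tuple[str, str], ...]
    free_label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "assertions", tuple((r, a) for r, a in self.assertions))

    def abbrevs(self) -> tuple[str, ...]:
        return tuple(a for _, a in self.assertions)


def parse_extent(text: str, where: str = "") -> RegionExtent:
    """Parse the ``rel(ABBREV)|...`` mini-expression."""
    if not text or not text.strip():
        raise ExtentParseError("empty region-extent expression", where)
    assertions: list[tuple[str, str]] = []
    note: Optional[str] = None
    for seg in text.split("|"):
        m = _SEGMENT_RE.match(seg)
        if not m:
            raise ExtentParseError(f"cannot parse extent segment {seg!r}", where)
        token, arg = m.group(1), m.group(2).strip()
        if token == "note":
            note = arg
            continue
        if token not in _TOKEN_RELS:
            raise ExtentParseError(f"unknown extent relation {token!r}", where)
        if not arg:
            raise ExtentParseError(f"empty region abbreviation in {seg!r}", where)
        assertions.append((_TOKEN_RELS[token], arg))
    if not assertions:
        raise ExtentParseError("extent needs at least one region assertion", where)
    return RegionExtent(assertions=tuple(assertions), free_label=note)


def format_extent(extent: RegionExtent) -> str:
    parts = [f"{_REL_TOKENS[rel]}({ab})" for rel, ab in extent.assertions]
    if extent.free_label:
        parts.append(f"note({extent.free_label})")
    return "|".join(parts)


@dataclass(frozen=True)
class ObservationRow:
    experiment_id: str
    publication: str
    values: dict

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __eq__(self, other):
        if not isinstance(other, ObservationRow):
            return NotImplemented
        return (self.experiment_id, self.publication, self.values) == \
               (other.experiment_id, other.publication, other.values)

    def __hash__(self):
        return hash((self.experiment_id, self.publication,
                     tuple(sorted((k, repr(v)) for k, v in self.values.items()))))


@dataclass
class ObservationTable:
    model_id: str
    rows: list = field(default_factory=list)

    def __post_init__(self):
        self.rows = list(self.rows)

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other):
        if not isinstance(other, ObservationTable):
            return NotImplemented
        return self.model_id == other.model_id and self.rows == other.rows


# ---------------------------------------------------------------------------
# validation


def validate_table(table: ObservationTable, model: KefedModel) -> ValidationReport:
    """Check rows against the model's derived form.

    Reports missing/extra columns, out-of-domain values, empty provenance
    and within-experiment inconsistencies of constant-role columns — each
    with the offending row index.
    """
    model_report = validate_model(model)
    if not model_report.ok:
        raise ModelValidationError(model_report)
    if table.model_id != model.id:
        raise ModelMismatchError(
            f"table references model {table.model_id!r}, got model {model.id!r}")
    form = derive_form(model)
    expected = {c.node_id: c for c in form.columns}

    v: list[Violation] = []
    for i, row in enumerate(table.rows):
        if not row.experiment_id:
            v.append(Violation("missing-experiment", f"row {i}: empty experiment_id", (str(i),)))
        if not row.publication:
            v.append(Violation("missing-publication", f"row {i}: empty publication", (str(i),)))
        missing = sorted(set(expected) - set(row.values))
        extra = sorted(set(row.values) - set(expected))
        if missing:
            v.append(Violation("missing-column", f"row {i}: missing values for {missing}", (str(i),)))
        if extra:
            v.append(Violation("extra-column", f"row {i}: values for undeclared columns {extra}", (str(i),)))
        for nid, col in expected.items():
            if nid not in row.values:
                continue
            value = row.values[nid]
            if col.domain is None or col.domain.contains(value):
                continue
            if col.domain.kind in ("nominal", "ordinal"):
                v.append(Violation(
                    "domain-violation",
                    f"row {i}: {value!r} is not a level of the "
                    f"{len(col.domain.levels)}-level {col.domain.kind} scale "
                    f"for {col.label!r} ({', '.join(col.domain.levels)})",
                    (str(i), nid)))
            else:
                v.append(Violation(
                    "domain-violation",
                    f"row {i}: {value!r} does not fit the {col.domain.kind} "
                    f"domain of {col.label!r}", (str(i), nid)))

    constants = [c.node_id for c in form.columns if c.fixed]
    by_exp: dict[str, list[int]] = {}
    for i, row in enumerate(table.rows):
        by_exp.setdefault(row.experiment_id, []).append(i)
    for exp, idxs in sorted(by_exp.items()):
        for nid in constants:
            seen = {repr(table.rows[i].values.get(nid)) for i in idxs
                    if nid in table.rows[i].values}
            if len(seen) > 1:
                v.append(Violation(
                    "constant-inconsistency",
                    f"experiment {exp!r}: constant column {expected[nid].label!r} "
                    f"takes {len(seen)} different values across rows {idxs}",
                    tuple(str(i) for i in idxs)))
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# serialization

_PROVENANCE_COLS = ("experiment_id", "publication")


def _value_to_text(value, col) -> str:
    if isinstance(value, RegionExtent):
        return format_extent(value)
    if col.domain is not None and col.domain.kind == "numeric":
        return repr(value)
    return str(value)


def _value_from_text(text: str, col, where: str):
    if col.domain is not None and col.domain.kind == "region_extent":
        return parse_extent(text, where)
    if col.domain is not None and col.domain.kind == "numeric":
        try:
            return int(text)
        except ValueError:
            try:
                return float(text)
            except ValueError as exc:
                raise DocumentParseError(f"expected a number, got {text!r}", where) from exc
    return text


def write_table(table: ObservationTable, path: Union[str, Path],
                model: KefedModel, format: Optional[str] = None) -> None:
    """Write a table as CSV (columns = form labels) or JSON lines."""
    fmt = format or _infer_format(path)
    form = derive_form(model)
    p = Path(path)
    if fmt == "csv":
        labels = form.labels
        if len(set(labels)) != len(labels):
            raise DocumentParseError("form column labels are not unique; cannot write CSV")
        with p.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(list(_PROVENANCE_COLS) + list(labels))
            for row in table.rows:
                w.writerow([row.experiment_id, row.publication] +
                           [_value_to_text(row.values[c.node_id], c) for c in form.columns])
    elif fmt == "json":
        with p.open("w", encoding="utf-8") as fh:
            for row in table.rows:
                doc = {"model_id": table.model_id,
                       "experiment_id": row.experiment_id,
                       "publication": row.publication,
                       "values": {c.node_id: _value_to_text(row.values[c.node_id], c)
                                  for c in form.columns if c.node_id in row.values}}
                fh.write(json.dumps(doc, sort_keys=True) + "\n")
    else:
        raise DocumentParseError(f"unknown table format {fmt!r}")


def read_table(path: Union[str, Path], model: KefedModel,
               format: Optional[str] = None) -> ObservationTable:
    """Read a CSV or JSON-lines table whose columns match the derived form."""
    fmt = format or _infer_format(path)
    form = derive_form(model)
    p = Path(path)
    rows: list[ObservationRow] = []
    if fmt == "csv":
        by_label = {c.label: c for c in form.columns}
        with p.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise DocumentParseError("empty CSV file", str(path)) from None
            if header[:2] != list(_PROVENANCE_COLS):
                raise DocumentParseError(
                    f"first columns must be {_PROVENANCE_COLS}", "header")
            unknown = [h for h in header[2:] if h not in by_label]
            if unknown:
                raise DocumentParseError(f"unknown columns {unknown}", "header")
            cols = [by_label[h] for h in header[2:]]
            for lineno, rec in enumerate(reader, start=2):
                if not rec:
                    continue
                if len(rec) != len(cols) + 2:
                    raise DocumentParseError(
                        f"expected {len(cols) + 2} cells, got {len(rec)}", f"line {lineno}")
                values = {}
                for col, cell in zip(cols, rec[2:]):
                    values[col.node_id] = _value_from_text(
                        cell, col, f"line {lineno}, column {col.label!r}")
                rows.append(ObservationRow(experiment_id=rec[0], publication=rec[1],
                                           values=values))
        return ObservationTable(model_id=model.id, rows=rows)
    if fmt == "json":
        model_id = model.id
        with p.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    doc = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise DocumentParseError(f"bad JSON: {exc}", f"line {lineno}") from exc
                if not isinstance(doc, dict) or "values" not in doc:
                    raise DocumentParseError("each line must be an object with 'values'",
                                             f"line {lineno}")
                if doc.get("model_id", model.id) != model.id:
                    raise ModelMismatchError(
                        f"line {lineno} references model {doc.get('model_id')!r}")
                values = {}
                for nid, raw in doc["values"].items():
                    try:
                        col = form.column(nid)
                    except Exception:
                        raise DocumentParseError(f"unknown column {nid!r}",
                                                 f"line {lineno}") from None
                    values[nid] = _value_from_text(str(raw), col,
                                                   f"line {lineno}, column {nid!r}")
                rows.append(ObservationRow(experiment_id=str(doc.get("experiment_id", "")),
                                           publication=str(doc.get("publication", "")),
                                           values=values))
        return ObservationTable(model_id=model_id, rows=rows)
    raise DocumentParseError(f"unknown table format {fmt!r}")


def _infer_format(path: Union[str, Path]) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".json", ".jsonl", ".ndjson"):
        return "json"
    return "csv"
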