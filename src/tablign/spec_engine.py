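"""Declarative harmonization specifications: build, merge, serialize, apply.

A :class:`HarmonizationSpec` is the reusable artifact of a harmonization
session: an ordered list of mapping entries, each naming a source attribute,
a target attribute, and a *mapper* describing how cell values transform
(identity, dictionary substitution, affine numeric transform, or a named
custom routine).  Specs serialize to JSON, merge with user overrides (user
entries take precedence), and materialize any table sharing the source
schema into the harmonized form.

One source attribute may feed several targets (one-to-many); two sources
feeding one target (many-to-one) is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .core import (AttributeMatch, Cell, Column, Table, TargetSchema,
                   is_missing, parse_number)
from .errors import (ManyToOneError, MissingSourceAttributeError,
                     SpecFormatError, UnresolvedRoutineError)
from .value_matching import NumericTransform, ValueMatchSet

SPEC_VERSION = "1"

MAPPER_TYPES = ("identity", "dictionary", "affine", "custom")

# registry of custom cell-wise routines, referenced by name in specs
_ROUTINES: dict[str, Callable[[Cell], Cell]] = {}


def register_routine(name: str, fn: Callable[[Cell], Cell]) -> None:
    """Register a custom mapper routine under a stable name."""
    _ROUTINES[name] = fn


def unregister_routine(name: str) -> None:
    _ROUTINES.pop(name, None)


@dataclass
class Mapper:
    """How one source column's values become the target column's values."""

    type: str = "identity"
    map: dict[str, str] = field(default_factory=dict)          # dictionary only
    transform: Optional[NumericTransform] = None               # affine only
    routine_name: str = ""                                     # custom only
    unmatched_policy: str = "null"                             # null | passthrough

    def __post_init__(self) -> None:
        if self.type not in MAPPER_TYPES:
            raise ValueError(f"unknown mapper type {self.type!r}")
        if self.unmatched_policy not in {"null", "passthrough"}:
            raise ValueError(f"unknown unmatched_policy {self.unmatched_policy!r}")
        if self.type == "affine" and self.transform is None:
            raise ValueError("affine mapper requires a transform")
        if self.type == "custom" and not self.routine_name:
            raise ValueError("custom mapper requires a routine_name")


@dataclass
class MappingEntry:
    source_attribute: str
    target_attribute: str
    mapper: Mapper = field(default_factory=Mapper)
    similarity: Optional[float] = None
    provenance: str = "user"


@dataclass
class HarmonizationSpec:
    """Ordered list of mapping entries; the serializable artifact."""

    version: str = SPEC_VERSION
    entries: list[MappingEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(e.source_attribute, e.target_attribute) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (source, target) mapping entries")

    @property
    def source_attributes(self) -> list[str]:
        return list(dict.fromkeys(e.source_attribute for e in self.entries))


def _check_many_to_one(entries: Sequence[MappingEntry]) -> None:
    by_target: dict[str, str] = {}
    for e in entries:
        prev = by_target.get(e.target_attribute)
        if prev is not None and prev != e.source_attribute:
            raise ManyToOneError(
                f"target attribute {e.target_attribute!r} is fed by both "
                f"{prev!r} and {e.source_attribute!r}; many-to-one mappings "
                "are not supported"
            )
        by_target[e.target_attribute] = e.source_attribute


def build_spec(matches: Sequence[AttributeMatch],
               value_sets: Sequence[ValueMatchSet] = (),
               method: str = "tfidf") -> HarmonizationSpec:
    """Compose a spec from schema matches and their value-match sets.

    Each attribute pair gets a dictionary mapper from its value matches; the
    mapper collapses to identity when every matched value maps to itself, or
    when no value matches exist at all.
    """
    by_pair = {(v.source_attribute, v.target_attribute): v for v in value_sets}
    entries = []
    for m in matches:
        vset = by_pair.get((m.source_attribute, m.target_attribute))
        if vset is not None and vset.matches:
            mapping = {v.source_value: v.target_value for v in vset.matches}
            if all(k == v for k, v in mapping.items()):
                mapper = Mapper(type="identity")
            else:
                mapper = Mapper(type="dictionary", map=mapping)
        else:
            mapper = Mapper(type="identity")
        entries.append(
            MappingEntry(m.source_attribute, m.target_attribute, mapper,
                         similarity=m.similarity, provenance=f"auto:{method}")
        )
    _check_many_to_one(entries)
    return HarmonizationSpec(entries=entries)


def merge_mappings(auto: HarmonizationSpec, user: HarmonizationSpec) -> HarmonizationSpec:
    """Merge with user precedence.

    A user entry for a source attribute replaces *all* auto entries for that
    source; user-only entries are appended after the surviving auto entries.
    """
    overridden = {e.source_attribute for e in user.entries}
    merged = [e for e in auto.entries if e.source_attribute not in overridden]
    merged.extend(user.entries)
    _check_many_to_one(merged)
    return HarmonizationSpec(entries=merged)


# ---------------------------------------------------------------------------
# materialization


def _apply_mapper(mapper: Mapper, cells: Sequence[Cell]) -> list[Cell]:
    if mapper.type == "identity":
        return list(cells)
    if mapper.type == "dictionary":
        out: list[Cell] = []
        for c in cells:
            if is_missing(c):
                out.append(None)
                continue
            key = str(c)
            if key in mapper.map:
                out.append(mapper.map[key])
            else:
                out.append(c if mapper.unmatched_policy == "passthrough" else None)
        return out
    if mapper.type == "affine":
        t = mapper.transform
        out = []
        for c in cells:
            v = None if is_missing(c) else parse_number(c)
            if v is None:
                out.append(None)
            else:
                y = t.apply(v)
                out.append(y if t.rounding == "none" else int(y))
        return out
    # custom
    fn = _ROUTINES.get(mapper.routine_name)
    if fn is None:
        raise UnresolvedRoutineError(
            f"custom routine {mapper.routine_name!r} is not registered; "
            "call register_routine() before materializing"
        )
    return [None if is_missing(c) else fn(c) for c in cells]


def materialize(source: Table, spec: HarmonizationSpec) -> Table:
    """Apply a spec to a source table, producing the harmonized table.

    The output has exactly the spec's target attributes, in entry order;
    row count is preserved; source columns not mentioned by the spec are
    dropped.
    """
    _check_many_to_one(spec.entries)
    missing = [e.source_attribute for e in spec.entries
               if e.source_attribute not in source.column_names]
    if missing:
        raise MissingSourceAttributeError(
            f"source table lacks attributes referenced by the spec: {sorted(set(missing))}"
        )
    columns = []
    for e in spec.entries:
        src = source.column(e.source_attribute)
        columns.append(Column(e.target_attribute, _apply_mapper(e.mapper, src.cells)))
    return Table(name=f"{source.name}__harmonized", columns=columns)


# ---------------------------------------------------------------------------
# serialization


def _mapper_to_doc(m: Mapper) -> dict:
    doc: dict = {"type": m.type, "unmatched_policy": m.unmatched_policy}
    if m.type == "dictionary":
        doc["map"] = dict(m.map)
    elif m.type == "affine":
        doc["transform"] = {
            "scale": m.transform.scale,
            "offset": m.transform.offset,
            "rounding": m.transform.rounding,
            "provenance": m.transform.provenance,
        }
    elif m.type == "custom":
        doc["routine_name"] = m.routine_name  # names only, never code
    return doc


def _mapper_from_doc(doc: dict, where: str) -> Mapper:
    if not isinstance(doc, dict) or "type" not in doc:
        raise SpecFormatError(f"{where}: mapper must be an object with a 'type' key")
    mtype = doc["type"]
    if mtype not in MAPPER_TYPES:
        raise SpecFormatError(f"{where}: unknown mapper type {mtype!r}")
    try:
        transform = None
        if mtype == "affine":
            t = doc["transform"]
            transform = NumericTransform(
                scale=float(t["scale"]), offset=float(t.get("offset", 0.0)),
                rounding=str(t.get("rounding", "none")),
                provenance=str(t.get("provenance", "")),
            )
        return Mapper(
            type=mtype,
            map={str(k): str(v) for k, v in doc.get("map", {}).items()},
            transform=transform,
            routine_name=str(doc.get("routine_name", "")),
            unmatched_policy=str(doc.get("unmatched_policy", "null")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SpecFormatError(f"{where}: malformed mapper ({exc})") from None


def spec_to_doc(spec: HarmonizationSpec) -> dict:
    return {
        "version": spec.version,
        "mappings": [
            {
                "source_attribute": e.source_attribute,
                "target_attribute": e.target_attribute,
                "mapper": _mapper_to_doc(e.mapper),
                "similarity": e.similarity,
                "provenance": e.provenance,
            }
            for e in spec.entries
        ],
    }


def spec_from_doc(doc: dict) -> HarmonizationSpec:
    if not isinstance(doc, dict):
        raise SpecFormatError("specification document must be a JSON object")
    if "mappings" not in doc:
        raise SpecFormatError("specification document is missing the 'mappings' key")
    entries = []
    for i, entry in enumerate(doc["mappings"]):
        where = f"mappings[{i}]"
        if not isinstance(entry, dict):
            raise SpecFormatError(f"{where}: entry must be an object")
        for key in ("source_attribute", "target_attribute"):
            if key not in entry:
                raise SpecFormatError(f"{where}: missing field {key!r}")
        sim = entry.get("similarity")
        entries.append(
            MappingEntry(
                source_attribute=str(entry["source_attribute"]),
                target_attribute=str(entry["target_attribute"]),
                mapper=_mapper_from_doc(entry.get("mapper", {"type": "identity"}), where),
                similarity=None if sim is None else float(sim),
                provenance=str(entry.get("provenance", "user")),
            )
        )
    _check_many_to_one(entries)
    return HarmonizationSpec(version=str(doc.get("version", SPEC_VERSION)), entries=entries)


def write_spec(spec: HarmonizationSpec, path) -> None:
    """Write a spec as JSON (UTF-8, 2-space indent, sorted keys)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(spec_to_doc(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_spec(path) -> HarmonizationSpec:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SpecFormatError(f"invalid JSON at line {exc.lineno}: {exc.msg}") from None
    return spec_from_doc(doc)


# ---------------------------------------------------------------------------
# validation


@dataclass
class Finding:
    code: str
    message: str
    source_attribute: str = ""
    target_attribute: str = ""


def validate_spec(spec: HarmonizationSpec, source: Optional[Table] = None,
                  target: Optional[TargetSchema] = None) -> list[Finding]:
    """Consistency findings (never exceptions) for a spec against its context."""
    findings: list[Finding] = []
    by_target: dict[str, str] = {}
    for e in spec.entries:
        prev = by_target.get(e.target_attribute)
        if prev is not None and prev != e.source_attribute:
            findings.append(Finding(
                "many-to-one",
                f"target {e.target_attribute!r} fed by both {prev!r} and {e.source_attribute!r}",
                e.source_attribute, e.target_attribute))
        by_target[e.target_attribute] = e.source_attribute
        if source is not None and e.source_attribute not in source.column_names:
            findings.append(Finding(
                "unknown-source-attribute",
                f"source table has no column {e.source_attribute!r}",
                e.source_attribute, e.target_attribute))
        if target is not None:
            if e.target_attribute not in target.attribute_names:
                findings.append(Finding(
                    "unknown-target-attribute",
                    f"target schema has no attribute {e.target_attribute!r}",
                    e.source_attribute, e.target_attribute))
            elif e.mapper.type == "dictionary":
                attr = target.attribute(e.target_attribute)
                if attr.permissible_values:
                    allowed = set(attr.permissible_values)
                    for v in e.mapper.map.values():
                        if v not in allowed:
                            findings.append(Finding(
                                "value-out-of-domain",
                                f"dictionary value {v!r} is outside the permissible "
                                f"values of {e.target_attribute!r}",
                                e.source_attribute, e.target_attribute))
    return findings
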