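"""Pluggable data-model standards.

A *standard* (common data model) is a named catalogue of target attributes
with permissible values and metadata.  Every standard — bundled or
user-supplied — is reached exclusively through four accessors:
``get_attributes``, ``get_attribute_values``, ``get_attribute_metadata`` and
``get_table_representation``; the rest of the library never touches the
storage format.  Bundled standards are YAML files shipped with the package;
users can register additional directories or load a file directly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .core import TargetAttribute, TargetSchema
from .errors import UnknownAttributeError, UnknownStandardError

_EXTRA_DIRS: list[Path] = []


def register_standards_dir(path) -> None:
    """Add a directory of ``*.yaml`` standard files to the registry."""
    _EXTRA_DIRS.append(Path(path))


@dataclass
class StandardModel:
    """A data-model standard exposing the four-accessor interface."""

    name: str
    attributes: list[TargetAttribute]
    provenance: str = "builtin"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {a.name: a for a in self.attributes}
        if len(self._index) != len(self.attributes):
            raise ValueError(f"standard {self.name!r} has duplicate attribute names")

    def _attr(self, name: str) -> TargetAttribute:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownAttributeError(
                f"standard {self.name!r} has no attribute {name!r}; "
                f"available: {self.get_attributes()}"
            ) from None

    def get_attributes(self) -> list[str]:
        return [a.name for a in self.attributes]

    def get_attribute_values(self, attr: str) -> list[str]:
        """Permissible values for ``attr``; empty for free (e.g. numeric) attributes."""
        return list(self._attr(attr).permissible_values or [])

    def get_attribute_metadata(self, attr: str) -> dict[str, str]:
        a = self._attr(attr)
        meta = {"description": a.description or ""}
        meta.update(a.metadata)
        return meta

    def get_table_representation(self) -> TargetSchema:
        attrs = [
            TargetAttribute(
                name=a.name,
                description=a.description,
                permissible_values=list(a.permissible_values or []),
                metadata=dict(a.metadata),
            )
            for a in self.attributes
        ]
        return TargetSchema(attributes=attrs, origin=f"standard:{self.name}")


def _parse_standard(doc: dict, provenance: str) -> StandardModel:
    if not isinstance(doc, dict) or "name" not in doc or "attributes" not in doc:
        raise UnknownStandardError(
            f"standard document at {provenance!r} must have 'name' and 'attributes' keys"
        )
    attrs = []
    for entry in doc["attributes"]:
        values = entry.get("values")
        attrs.append(
            TargetAttribute(
                name=str(entry["name"]),
                description=str(entry.get("description", "")),
                permissible_values=[str(v) for v in values] if values is not None else None,
                metadata={str(k): str(v) for k, v in (entry.get("metadata") or {}).items()},
            )
        )
    return StandardModel(name=str(doc["name"]), attributes=attrs, provenance=provenance)


def _builtin_files() -> dict[str, object]:
    root = importlib.resources.files("tablign") / "standards_data"
    return {p.name.removesuffix(".yaml"): p for p in root.iterdir() if p.name.endswith(".yaml")}


def available_standards() -> list[str]:
    names = set(_builtin_files())
    for d in _EXTRA_DIRS:
        names.update(p.stem for p in d.glob("*.yaml"))
    return sorted(names)


def load_standard(name: str) -> StandardModel:
    """Load a registered standard by name, or any YAML standard by file path."""
    path = Path(name)
    if path.suffix in {".yaml", ".yml", ".json"} and path.exists():
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        return _parse_standard(doc, provenance=str(path))
    for d in _EXTRA_DIRS:
        candidate = d / f"{name}.yaml"
        if candidate.exists():
            doc = yaml.safe_load(candidate.read_text(encoding="utf-8"))
            return _parse_standard(doc, provenance=str(candidate))
    builtins = _builtin_files()
    if name in builtins:
        doc = yaml.safe_load(builtins[name].read_text(encoding="utf-8"))
        return _parse_standard(doc, provenance="builtin")
    raise UnknownStandardError(
        f"unknown standard {name!r}; available standards: {available_standards()}"
    )
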