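"""Core domain model: tables, columns, target schemas, and match records.

Everything downstream (schema matchers, value matchers, the spec engine)
operates on these types.  A :class:`Table` is a rectangular collection of
named :class:`Column` objects whose cells are either text, a number, or
missing (``None``).  A :class:`TargetSchema` is the uniform view over either
a plain table or a data-model standard: a list of attributes, each with
optional permissible values and metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import DuplicateColumnError, EmptyTableError

Cell = Union[str, float, None]

#: Case-insensitive sentinels parsed to missing; common biomedical CSV dialects.
MISSING_SENTINELS = frozenset({"", "na", "nan", "null"})

# Integer, decimal or scientific notation; thousands separators rejected.
_NUMBER_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")

TEXT = "text"
NUMERIC = "numeric"
UNKNOWN = "unknown"


def is_missing(cell: Cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, str):
        return cell.strip().lower() in MISSING_SENTINELS
    return False


def parse_number(cell: Cell) -> Optional[float]:
    """Parse a cell as a finite number, or return None."""
    if isinstance(cell, (int, float)):
        return float(cell)
    if isinstance(cell, str) and _NUMBER_RE.match(cell.strip()):
        return float(cell)
    return None


@dataclass
class Column:
    """A named, ordered list of cells with an inferred kind."""

    name: str
    cells: list = field(default_factory=list)

    def non_missing(self) -> list:
        return [c for c in self.cells if not is_missing(c)]

    def distinct_values(self) -> list[str]:
        """Each non-missing value at most once, first-occurrence order."""
        seen: dict[str, None] = {}
        for c in self.non_missing():
            seen.setdefault(_as_text(c), None)
        return list(seen)

    def numeric_values(self) -> list[float]:
        out = []
        for c in self.non_missing():
            v = parse_number(c)
            if v is not None:
                out.append(v)
        return out

    @property
    def kind(self) -> str:
        return infer_column_kind(self)


def _as_text(cell: Cell) -> str:
    if isinstance(cell, float) and cell.is_integer():
        return str(int(cell))
    return str(cell)


def infer_column_kind(column: Column) -> str:
    """Classify a column as numeric, text, or unknown.

    Numeric iff at least one non-missing cell exists and >= 95% of the
    non-missing cells parse as finite numbers; unknown iff every cell is
    missing; text otherwise.
    """
    present = column.non_missing()
    if not present:
        return UNKNOWN
    parsed = sum(1 for c in present if parse_number(c) is not None)
    if parsed / len(present) >= 0.95:
        return NUMERIC
    return TEXT


@dataclass
class Table:
    """A rectangular, uniquely-named collection of columns."""

    name: str
    columns: list[Column] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if any(not n for n in names):
            raise DuplicateColumnError("column names must be non-empty")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateColumnError(f"duplicate column names: {sorted(dupes)}")
        lengths = {len(c.cells) for c in self.columns}
        if len(lengths) > 1:
            raise ValueError(f"ragged table: column lengths {sorted(lengths)}")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def n_rows(self) -> int:
        return len(self.columns[0].cells) if self.columns else 0

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c.name: [None if is_missing(x) else x for x in c.cells] for c in self.columns}
        )


@dataclass
class TargetAttribute:
    """One attribute of a target schema: name, optional enumerated values."""

    name: str
    description: str = ""
    permissible_values: Optional[list[str]] = None
    metadata: dict[str, str] = field(default_factory=dict)
    # Full non-missing cell list when the target is a table; lets
    # distribution-based matching see value frequencies, not just the
    # distinct values.  Not part of equality/serialization.
    raw_cells: Optional[list] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.permissible_values is not None:
            if len(set(self.permissible_values)) != len(self.permissible_values):
                raise ValueError(f"duplicate permissible values for {self.name!r}")

    @property
    def values(self) -> list[str]:
        return list(self.permissible_values or [])


@dataclass
class TargetSchema:
    """Uniform matching target: a table's columns or a standard's attributes."""

    attributes: list[TargetAttribute]
    origin: str = "table"

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise DuplicateColumnError("target attribute names must be unique")

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def attribute(self, name: str) -> TargetAttribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass
class AttributeMatch:
    """A (source attribute, target attribute) correspondence with a score."""

    source_attribute: str
    target_attribute: str
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0 + 1e-12:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")
        self.similarity = min(float(self.similarity), 1.0)


@dataclass
class RankedMatchList:
    """Top-k target candidates for one source attribute.

    Candidates are ordered by descending similarity; exact ties are broken
    lexicographically by target attribute name so output is reproducible.
    """

    source_attribute: str
    candidates: list[tuple[str, float]]

    def __post_init__(self) -> None:
        sims = [s for _, s in self.candidates]
        if any(sims[i] < sims[i + 1] for i in range(len(sims) - 1)):
            raise ValueError("candidates must be in non-increasing similarity order")

    @property
    def top(self) -> Optional[AttributeMatch]:
        if not self.candidates:
            return None
        name, sim = self.candidates[0]
        return AttributeMatch(self.source_attribute, name, sim)


def rank_candidates(scores: Mapping[str, float], top_k: Optional[int] = None) -> list[tuple[str, float]]:
    """Sort candidate scores descending with a lexicographic tie-break."""
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ordered = ordered[: max(top_k, 0)]
    return [(name, float(min(max(s, 0.0), 1.0))) for name, s in ordered]


def validate_table(raw, name: str = "table") -> Table:
    """Build a Table from parsed tabular content (header row + cell rows).

    ``raw`` may be a pandas DataFrame or a mapping of column name to cell
    sequence.  Missing-value sentinels ("", "NA", "NaN", "null", any case)
    become None.  Raises DuplicateColumnError / EmptyTableError.
    """
    if isinstance(raw, pd.DataFrame):
        headers = [str(h) for h in raw.columns]
        data = {h: raw.iloc[:, i].tolist() for i, h in enumerate(headers)}
        if len(set(headers)) != len(headers):
            raise DuplicateColumnError(f"duplicate column names: {headers}")
    elif isinstance(raw, Mapping):
        data = {str(k): list(v) for k, v in raw.items()}
        headers = list(data)
    else:
        raise TypeError(f"cannot build a Table from {type(raw).__name__}")
    if not headers:
        raise EmptyTableError("table has no columns")
    columns = [
        Column(h, [None if is_missing(c) else c for c in data[h]]) for h in headers
    ]
    return Table(name, columns)


def read_table(path, delimiter: str = ",", name: Optional[str] = None) -> Table:
    """Read a delimited text file (RFC 4180 dialect, UTF-8) into a Table."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8")
    return validate_table(df, name=name or str(path))


def write_table(table: Table, path, delimiter: str = ",") -> None:
    df = pd.DataFrame({c.name: ["" if is_missing(x) else _as_text(x) for x in c.cells] for c in table.columns})
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def as_target_schema(table: Table) -> TargetSchema:
    """View a table as a matching target.

    Each column becomes an attribute whose permissible values are the
    column's distinct non-missing values (first-occurrence order).
    """
    attrs = [
        TargetAttribute(
            name=c.name,
            permissible_values=c.distinct_values(),
            metadata={"kind": c.kind},
            raw_cells=c.non_missing(),
        )
        for c in table.columns
    ]
    return TargetSchema(attributes=attrs, origin="table")


def coerce_target(target, name: str = "target") -> TargetSchema:
    """Accept a TargetSchema, a Table, or a standard name and normalize it."""
    if isinstance(target, TargetSchema):
        return target
    if isinstance(target, Table):
        return as_target_schema(target)
    if isinstance(target, str):
        from .standards import load_standard

        return load_standard(target).get_table_representation()
    raise TypeError(f"cannot interpret {type(target).__name__} as a target schema")
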