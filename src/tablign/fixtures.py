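"""Synthetic fixture generator with known ground truth.

Emulates the situation the toolkit is built for: a clinical/omics study
table (the *source*) that drifted away from a curated table or data model
(the *target*) through renamed headers, re-coded categorical values, unit
changes, and extra bookkeeping columns.  Because the generator starts from
the target and applies known perturbations, it emits the exact ground-truth
attribute map, value maps, and numeric transforms — which is what lets the
test suite measure matcher accuracy without any external data.

Regenerating with the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import AttributeMatch, Column, Table
from .value_matching import NumericTransform, ValueMatchSet

PERTURBATIONS = (
    "case_change", "snake_camel", "abbreviation", "typo",
    "value_recode", "unit_scale", "distractor_column",
)

#: Days per year used for age conversions throughout the package.
DAYS_PER_YEAR = 365.25

# (name, categorical values or numeric spec, recode variants)
_POOL: list[tuple[str, object, dict[str, str]]] = [
    ("gender", ["female", "male", "unknown"],
     {"female": "FEMALE", "male": "MALE", "unknown": "UNK"}),
    ("race", ["white", "black or african american", "asian", "other"],
     {"white": "WHITE", "black or african american": "BLACK_OR_AFRICAN_AMERICAN",
      "asian": "ASIAN", "other": "OTHER"}),
    ("bmi", ("float", 17.0, 42.0, 1), {}),
    ("tumor_focality", ["unifocal", "multifocal"],
     {"unifocal": "UNIFOCAL", "multifocal": "MULTIFOCAL"}),
    ("age_at_diagnosis", ("int", 30, 85), {}),
    ("cnv_status", ["CNV_L", "CNV_H", "CNV_N"],
     {"CNV_L": "CNV_LOW", "CNV_H": "CNV_HIGH", "CNV_N": "CNV_NEUTRAL"}),
    ("assay", ["RNA-seq", "ATAC-seq"],
     {"RNA-seq": "RNA-Seq", "ATAC-seq": "ATAC-Seq"}),
    ("species", ["Homo sapiens", "Mus musculus"],
     {"Homo sapiens": "HOMO_SAPIENS", "Mus musculus": "MUS_MUSCULUS"}),
    ("vital_status", ["alive", "dead"], {"alive": "ALIVE", "dead": "DECEASED"}),
    ("tumor_grade", ["g1", "g2", "g3", "g4"],
     {"g1": "G1", "g2": "G2", "g3": "G3", "g4": "G4"}),
    ("primary_site", ["kidney", "lung", "breast", "colon"],
     {"kidney": "KIDNEY", "lung": "LUNG", "breast": "BREAST", "colon": "COLON"}),
    ("aliquot_id", ("id", "CPT", 7), {}),
]

# fixed, versioned abbreviation table (truncation-style header renames)
ABBREVIATIONS = {
    "aliquot_id": "aliq_id",
    "age_at_diagnosis": "age_diag",
    "tumor_focality": "tumor_foc",
    "primary_site": "site",
    "vital_status": "status",
    "cnv_status": "cnv_class",
}


@dataclass
class GroundTruth:
    """What the perturbations did, for scoring recovered mappings."""

    attribute_map: dict[str, str] = field(default_factory=dict)   # source -> target
    value_maps: dict[str, dict[str, str]] = field(default_factory=dict)  # per source attr
    transforms: dict[str, NumericTransform] = field(default_factory=dict)
    distractor_columns: list[str] = field(default_factory=list)


@dataclass
class FixtureSpec:
    seed: int = 0
    n_rows: int = 50
    n_columns: int = 10
    perturbations: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        unknown = set(self.perturbations) - set(PERTURBATIONS)
        if unknown:
            raise ValueError(f"unknown perturbations: {sorted(unknown)}")
        self.perturbations = frozenset(self.perturbations)


def _sample_cell(spec, rng: random.Random) -> str:
    if isinstance(spec, list):
        return rng.choice(spec)
    kind = spec[0]
    if kind == "float":
        _, lo, hi, digits = spec
        return f"{rng.uniform(lo, hi):.{digits}f}"
    if kind == "int":
        _, lo, hi = spec
        return str(rng.randint(lo, hi))
    _, prefix, width = spec
    return prefix + "".join(rng.choice("0123456789") for _ in range(width))


def _perturb_header(name: str, perturbations: frozenset, rng: random.Random) -> str:
    out = name
    if "abbreviation" in perturbations and out in ABBREVIATIONS:
        out = ABBREVIATIONS[out]
    if "snake_camel" in perturbations:
        out = "".join(tok.capitalize() for tok in out.split("_"))
    if "case_change" in perturbations:
        style = rng.choice(["upper", "title", "lower"])
        if style == "upper":
            out = out.upper()
        elif style == "title":
            out = "_".join(tok.capitalize() for tok in out.split("_"))
        else:
            out = out.lower()
    if "typo" in perturbations and len(out) > 3:
        i = rng.randrange(1, len(out) - 1)
        if rng.random() < 0.5:
            out = out[:i] + out[i + 1 :]  # deletion
        else:
            out = out[: i] + out[i + 1] + out[i] + out[i + 2 :]  # transposition
    return out


def generate_fixture(fs: FixtureSpec) -> tuple[Table, Table, GroundTruth]:
    """Generate (source, target, ground_truth) under the requested perturbations."""
    rng = random.Random(fs.seed)
    pool = _POOL[: max(1, min(fs.n_columns, len(_POOL)))]
    truth = GroundTruth()

    target_cols: list[Column] = []
    source_cols: list[Column] = []
    for name, spec, variants in pool:
        base_cells = [_sample_cell(spec, rng) for _ in range(fs.n_rows)]
        src_name = _perturb_header(name, fs.perturbations, rng)
        tgt_cells = list(base_cells)
        src_cells = list(base_cells)

        if "unit_scale" in fs.perturbations and name == "age_at_diagnosis":
            # source reports age in years; the target standardizes on days
            transform = NumericTransform(DAYS_PER_YEAR, 0.0, "floor",
                                         "unit-hint:years->days")
            tgt_cells = [str(int(transform.apply(float(c)))) for c in base_cells]
            truth.transforms[src_name] = transform
        elif "value_recode" in fs.perturbations and variants:
            src_cells = [variants.get(c, c) for c in base_cells]
            truth.value_maps[src_name] = {v: k for k, v in variants.items()}

        target_cols.append(Column(name, tgt_cells))
        source_cols.append(Column(src_name, src_cells))
        truth.attribute_map[src_name] = name

    if "distractor_column" in fs.perturbations:
        cells = ["note-" + "".join(rng.choice("abcdefgh") for _ in range(6))
                 for _ in range(fs.n_rows)]
        source_cols.append(Column("internal_comment", cells))
        truth.distractor_columns.append("internal_comment")

    source = Table(f"fixture_source_{fs.seed}", source_cols)
    target = Table(f"fixture_target_{fs.seed}", target_cols)
    return source, target, truth


# ---------------------------------------------------------------------------
# scoring helpers


def schema_accuracy(matches: Sequence[AttributeMatch], truth: GroundTruth) -> float:
    """accuracy@1 of recovered attribute matches over the ground-truth map."""
    relevant = [m for m in matches if m.source_attribute in truth.attribute_map]
    if not relevant:
        return 0.0
    hits = sum(m.target_attribute == truth.attribute_map[m.source_attribute]
               for m in relevant)
    return hits / len(relevant)


def value_recovery(value_sets: Sequence[ValueMatchSet], truth: GroundTruth,
                   source: Table) -> float:
    """Fraction of ground-truth value pairs recovered as top-1 matches.

    For every correctly matched categorical source column, the expected pair
    for a source value is its ground-truth recode target (identity when the
    value was not recoded).
    """
    total = hits = 0
    by_src = {v.source_attribute: v for v in value_sets}
    for src_attr, tgt_attr in truth.attribute_map.items():
        vset = by_src.get(src_attr)
        if vset is None or vset.target_attribute != tgt_attr:
            continue
        vmap = truth.value_maps.get(src_attr, {})
        recovered = {m.source_value: m.target_value for m in vset.matches}
        for sval in source.column(src_attr).distinct_values():
            expected = vmap.get(sval, sval)
            total += 1
            if recovered.get(sval) == expected:
                hits += 1
    return hits / total if total else 0.0
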