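"""Value matchers: align source column values to target permissible values.

Given a matched attribute pair (e.g. ``CNV_class -> cnv_status``), these
routines find which source values correspond to which target values
(``CNV_LOW -> CNV_L``), producing per-pair :class:`ValueMatchSet` objects.
Methods: Levenshtein edit distance with an optional custom scorer,
character-3-gram TF-IDF cosine, embedding cosine behind a
:class:`~tablign.backends.TextEncoder`, and an LLM route behind a
:class:`~tablign.backends.ChatAdapter`.  A separate routine infers affine
numeric transforms (e.g. age in years -> age in days) from unit hints.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import linear_kernel

from .backends import Candidate, ChatAdapter, HashEncoder, TextEncoder
from .core import (AttributeMatch, Column, Table, TargetSchema, coerce_target,
                   rank_candidates)
from .errors import (AdapterError, MissingValuesError, NotNumericError,
                     ScorerContractError, UnknownMethodError)
from .textutils import char_ngrams, normalized_levenshtein_distance

logger = logging.getLogger(__name__)

#: Minimum similarity for a top-1 value match to be emitted.
DEFAULT_TAU = 0.3

VALUE_METHODS = ("edit_distance", "tfidf", "embedding", "llm")


@dataclass
class ValueMatch:
    source_value: str
    target_value: str
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0 + 1e-12:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")
        self.similarity = min(float(self.similarity), 1.0)


@dataclass
class ValueMatchSet:
    """All value matches for one attribute pair, plus the leftovers."""

    source_attribute: str
    target_attribute: str
    matches: list[ValueMatch] = field(default_factory=list)
    unmatched_source_values: list[str] = field(default_factory=list)


@dataclass
class RankedValueMatches:
    """Per source value, the ranked target-value candidates for one pair."""

    source_attribute: str
    target_attribute: str
    rankings: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# similarity primitives


def value_edit_distance(s: str, t: str,
                        scorer: Optional[Callable[[str, str], float]] = None) -> float:
    """Edit-distance similarity between two strings.

    Default scorer: ``1 - levenshtein(s, t) / max(|s|, |t|)`` on case-folded
    strings; two empty strings score 1.0.  A custom scorer must be symmetric
    with range [0, 1].
    """
    if scorer is not None:
        sim = float(scorer(s, t))
        if not 0.0 <= sim <= 1.0 or math.isnan(sim):
            raise ScorerContractError(f"scorer returned {sim!r}, outside [0, 1]")
        return sim
    return 1.0 - normalized_levenshtein_distance(s.casefold(), t.casefold())


def value_tfidf(sources: Sequence[str], targets: Sequence[str]) -> np.ndarray:
    """TF-IDF / cosine similarity matrix over character 3-grams.

    Strings are case-folded and boundary-padded with "#"; the vectorizer is
    fitted over the union of both lists (smoothed IDF); exact
    case-insensitive equality forces similarity 1.0.
    """
    if not targets:
        raise ValueError("at least one target value is required")
    sources = [str(s) for s in sources]
    targets = [str(t) for t in targets]
    corpus = list(dict.fromkeys(sources + targets))
    vec = TfidfVectorizer(analyzer=char_ngrams)
    vec.fit(corpus)
    sim = linear_kernel(vec.transform(sources), vec.transform(targets))
    sim = np.clip(sim, 0.0, 1.0)
    for i, s in enumerate(sources):
        for j, t in enumerate(targets):
            if s.casefold() == t.casefold():
                sim[i, j] = 1.0
    return sim


def value_embedding(sources: Sequence[str], targets: Sequence[str],
                    encoder: Optional[TextEncoder] = None) -> np.ndarray:
    """Cosine similarity of value embeddings, mapped from [-1, 1] to [0, 1]."""
    enc = encoder or HashEncoder()
    vs = enc.encode([str(s) for s in sources])
    vt = enc.encode([str(t) for t in targets])
    cos = np.clip(vs @ vt.T, -1.0, 1.0)
    return (cos + 1.0) / 2.0


def value_llm(sources: Sequence[str], targets: Sequence[str], adapter: ChatAdapter,
              source_attribute: str = "", target_attribute: str = "") -> ValueMatchSet:
    """Adapter-driven value matching.

    The adapter selects a target value per source value or abstains;
    abstentions land in ``unmatched_source_values``.  Out-of-set answers are
    rejected and the adapter is re-asked without the bogus option.  Adapter
    failure falls back to TF-IDF with a logged warning.
    """
    result = ValueMatchSet(source_attribute, target_attribute)
    try:
        for s in sources:
            candidates = [Candidate(name=str(t)) for t in targets]
            selection = None
            for _ in range(len(candidates)):
                selection = adapter.select(str(s), candidates)
                if selection is None or selection.choice in {c.name for c in candidates}:
                    break
                # out-of-set answer: reject it and ask again
                candidates = [c for c in candidates if c.name != selection.choice]
                selection = None
            if selection is None:
                result.unmatched_source_values.append(str(s))
            else:
                result.matches.append(
                    ValueMatch(str(s), selection.choice, min(selection.confidence, 1.0))
                )
        return result
    except AdapterError as exc:
        logger.warning("value_llm adapter failed (%s); falling back to tfidf", exc)
        sim = value_tfidf(sources, targets)
        return _matrix_to_set(sources, targets, sim, DEFAULT_TAU,
                              source_attribute, target_attribute)


# ---------------------------------------------------------------------------
# dispatch


def _similarity_matrix(method: str, sources: Sequence[str], targets: Sequence[str],
                       method_args: dict) -> np.ndarray:
    if method == "tfidf":
        return value_tfidf(sources, targets)
    if method == "edit_distance":
        scorer = method_args.get("scorer")
        return np.array(
            [[value_edit_distance(str(s), str(t), scorer) for t in targets] for s in sources]
        )
    if method == "embedding":
        return value_embedding(sources, targets, method_args.get("encoder"))
    raise UnknownMethodError(
        f"unknown value-matching method {method!r}; available: {VALUE_METHODS}"
    )


def _matrix_to_set(sources, targets, sim, tau, src_attr, tgt_attr) -> ValueMatchSet:
    out = ValueMatchSet(src_attr, tgt_attr)
    for i, s in enumerate(sources):
        ranked = rank_candidates({str(t): float(sim[i, j]) for j, t in enumerate(targets)})
        if ranked and ranked[0][1] >= tau:
            out.matches.append(ValueMatch(str(s), ranked[0][0], ranked[0][1]))
        else:
            out.unmatched_source_values.append(str(s))
    return out


def _pair_values(source: Table, target: TargetSchema, pair: AttributeMatch,
                 method: str) -> tuple[list[str], list[str]]:
    col = source.column(pair.source_attribute)
    attr = target.attribute(pair.target_attribute)
    targets = attr.values
    if not targets:
        raise MissingValuesError(
            f"target attribute {attr.name!r} has no permissible values, "
            f"required by method {method!r}"
        )
    return col.distinct_values(), targets


def match_values(source: Table, target, pairs: Sequence[AttributeMatch],
                 method: str = "tfidf", method_args: Optional[dict] = None,
                 tau: float = DEFAULT_TAU) -> list[ValueMatchSet]:
    """Top-1 value matching for each attribute pair.

    Emits a match for a source value only when its best similarity reaches
    ``tau``; otherwise the value is reported unmatched.
    """
    target = coerce_target(target)
    method_args = dict(method_args or {})
    out = []
    for pair in pairs:
        svals, tvals = _pair_values(source, target, pair, method)
        if method == "llm":
            adapter = method_args.get("adapter")
            if adapter is None:
                raise UnknownMethodError("method 'llm' requires method_args['adapter']")
            out.append(value_llm(svals, tvals, adapter,
                                 pair.source_attribute, pair.target_attribute))
        else:
            sim = _similarity_matrix(method, svals, tvals, method_args)
            out.append(_matrix_to_set(svals, tvals, sim, tau,
                                      pair.source_attribute, pair.target_attribute))
    return out


def rank_value_matches(source: Table, target, pairs: Sequence[AttributeMatch],
                       method: str = "tfidf", method_args: Optional[dict] = None,
                       top_k: int = 10) -> list[RankedValueMatches]:
    """Top-k ranked target-value candidates per source value, per pair."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    target = coerce_target(target)
    method_args = dict(method_args or {})
    out = []
    for pair in pairs:
        svals, tvals = _pair_values(source, target, pair, method)
        sim = _similarity_matrix(method if method != "llm" else "tfidf",
                                 svals, tvals, method_args)
        rankings = {
            str(s): rank_candidates(
                {str(t): float(sim[i, j]) for j, t in enumerate(tvals)}, top_k
            )
            for i, s in enumerate(svals)
        }
        out.append(RankedValueMatches(pair.source_attribute, pair.target_attribute, rankings))
    return out


# ---------------------------------------------------------------------------
# numeric transforms


@dataclass
class NumericTransform:
    """Affine transform ``y = x * scale + offset`` with optional rounding."""

    scale: float
    offset: float = 0.0
    rounding: str = "none"  # none | floor | nearest
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError("scale must be non-zero")
        if self.rounding not in {"none", "floor", "nearest"}:
            raise ValueError(f"unknown rounding {self.rounding!r}")

    def apply(self, x: float, rounded: bool = True) -> float:
        y = x * self.scale + self.offset
        if not rounded or self.rounding == "none":
            return y
        if self.rounding == "floor":
            return float(math.floor(y))
        return float(round(y))

    def inverse(self) -> "NumericTransform":
        """Algebraic inverse (rounding dropped)."""
        return NumericTransform(1.0 / self.scale, -self.offset / self.scale,
                                "none", f"inverse({self.provenance})")


#: Scales considered when inferring a numeric transform.
CANDIDATE_SCALES = (12.0, 365.25, 1 / 12.0, 1 / 365.25, 1000.0, 1 / 1000.0, 1.0)

_UNIT_ALIASES = {
    "year": "years", "years": "years", "yr": "years", "yrs": "years",
    "month": "months", "months": "months", "mo": "months",
    "day": "days", "days": "days",
    "kg": "kg", "kilograms": "kg", "g": "g", "grams": "g",
    "mg": "mg", "milligrams": "mg",
    "l": "l", "liters": "l", "ml": "ml", "milliliters": "ml",
}

_UNIT_SCALES = {
    ("years", "days"): 365.25,
    ("years", "months"): 12.0,
    ("days", "years"): 1 / 365.25,
    ("months", "years"): 1 / 12.0,
    ("kg", "g"): 1000.0,
    ("g", "mg"): 1000.0,
    ("l", "ml"): 1000.0,
    ("g", "kg"): 1 / 1000.0,
    ("mg", "g"): 1 / 1000.0,
    ("ml", "l"): 1 / 1000.0,
}


def _canonical_unit(text: Optional[str]) -> Optional[str]:
    if not text:
        return None
    return _UNIT_ALIASES.get(str(text).strip().casefold())


def infer_numeric_transform(source_col: Column, target_meta: dict,
                            source_unit: Optional[str] = None,
                            adapter: Optional[ChatAdapter] = None) -> NumericTransform:
    """Infer an affine transform from a numeric source column to a target unit.

    Deterministic path: when source and target unit hints resolve to a known
    unit pair (e.g. years -> days), pick the corresponding scale from
    :data:`CANDIDATE_SCALES`; upscaling conversions round with floor (ages in
    completed days/months).  Without unit hints, an adapter may propose one
    of the candidate scales; otherwise the identity transform is returned
    with provenance "no-evidence".
    """
    if source_col.kind != "numeric":
        raise NotNumericError(f"column {source_col.name!r} is not numeric")
    if len(source_col.numeric_values()) < 3:
        raise NotNumericError(
            f"column {source_col.name!r} has fewer than 3 non-missing numeric values"
        )
    src = _canonical_unit(source_unit)
    if src is None:
        # fall back to a unit word embedded in the column name, e.g. "age_years"
        from .textutils import tokenize

        for tok in tokenize(source_col.name):
            if _canonical_unit(tok):
                src = _canonical_unit(tok)
                break
    tgt = _canonical_unit(target_meta.get("unit"))
    if src and tgt:
        if src == tgt:
            return NumericTransform(1.0, 0.0, "none", f"same-unit:{src}")
        scale = _UNIT_SCALES.get((src, tgt))
        if scale is not None:
            rounding = "floor" if scale > 1.0 else "none"
            return NumericTransform(scale, 0.0, rounding, f"unit-hint:{src}->{tgt}")
    if adapter is not None:
        candidates = [Candidate(name=repr(float(s))) for s in CANDIDATE_SCALES]
        query = f"scale converting {source_col.name} ({src or 'unknown unit'}) to {tgt or 'unknown unit'}"
        selection = adapter.select(query, candidates)
        if selection is not None and selection.choice in {c.name for c in candidates}:
            scale = float(selection.choice)
            rounding = "floor" if scale > 1.0 else "none"
            return NumericTransform(scale, 0.0, rounding, f"adapter:{adapter.name}")
    return NumericTransform(1.0, 0.0, "none", "no-evidence")
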