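"""Deterministic triage of proposed matches: accept / needs_review / reject.

Each proposed schema or value match is run through an ordered rule list;
the first rule that fires assigns the label and a templated explanation
naming the evidence.  An optional chat adapter may refine *only* the
``needs_review`` outcomes — it can never flip an accept or a reject, so the
offline rule core stays authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .backends import Candidate, ChatAdapter
from .core import AttributeMatch, Table, TargetAttribute, coerce_target
from .schema_matching import fuzzy_jaccard
from .textutils import normalize_name, tokenize
from .value_matching import ValueMatch, ValueMatchSet

ACCEPT = "accept"
NEEDS_REVIEW = "needs_review"
REJECT = "reject"

# repo-defined score bands
SCHEMA_ACCEPT_SIM = 0.9
SCHEMA_REJECT_SIM = 0.4
VALUE_ACCEPT_SIM = 0.8
VALUE_REJECT_SIM = 0.4
FUZZY_OVERLAP_THETA = 0.2


@dataclass
class MatchEvaluation:
    match: Union[AttributeMatch, ValueMatch]
    label: str
    explanation: str
    rule_id: str

    def __post_init__(self) -> None:
        if self.label not in {ACCEPT, NEEDS_REVIEW, REJECT}:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.explanation:
            raise ValueError("explanation must be non-empty")


def _norm_values(values: Sequence[str]) -> set[str]:
    return {normalize_name(str(v)) for v in values}


def evaluate_schema_matches(source: Table, target, matches: Sequence[AttributeMatch],
                            adapter: Optional[ChatAdapter] = None) -> list[MatchEvaluation]:
    """Label each schema match; rules applied in order, first hit wins.

    R1  normalized names equal and (no enumerable values, or value sets
        equal case-insensitively)            -> accept
    R2  value sets equal after case/punctuation normalization -> accept
    R3  similarity >= 0.9 and fuzzy value overlap >= 0.5      -> accept
    R4  similarity < 0.4, or zero value overlap and zero
        name-token overlap                                     -> reject
    R5  otherwise                                              -> needs_review
    """
    target = coerce_target(target)
    out = []
    for m in matches:
        col = source.column(m.source_attribute)
        attr = target.attribute(m.target_attribute)
        src_vals = col.distinct_values()
        tgt_vals = attr.values
        name_eq = normalize_name(m.source_attribute) == normalize_name(m.target_attribute)
        vals_eq = bool(src_vals or tgt_vals) and _norm_values(src_vals) == _norm_values(tgt_vals)
        overlap = fuzzy_jaccard(
            [normalize_name(v) for v in src_vals],
            [normalize_name(v) for v in tgt_vals],
            FUZZY_OVERLAP_THETA,
        ) if src_vals and tgt_vals else 0.0
        token_overlap = len(set(tokenize(m.source_attribute)) & set(tokenize(m.target_attribute)))

        if name_eq and (not (src_vals and tgt_vals) or vals_eq):
            label, rule = ACCEPT, "R1"
            expl = (f"attribute names {m.source_attribute!r} and {m.target_attribute!r} "
                    "are identical after normalization"
                    + (" and their value sets coincide" if vals_eq else ""))
        elif vals_eq:
            label, rule = ACCEPT, "R2"
            expl = (f"the value sets of {m.source_attribute!r} and {m.target_attribute!r} "
                    "are identical after case and punctuation normalization "
                    f"({len(src_vals)} source values)")
        elif m.similarity >= SCHEMA_ACCEPT_SIM and overlap >= 0.5:
            label, rule = ACCEPT, "R3"
            expl = (f"similarity {m.similarity:.2f} is high and {overlap:.0%} of the "
                    "values overlap between the two attributes")
        elif m.similarity < SCHEMA_REJECT_SIM or (overlap == 0.0 and token_overlap == 0):
            label, rule = REJECT, "R4"
            reason = (f"similarity {m.similarity:.2f} is below {SCHEMA_REJECT_SIM}"
                      if m.similarity < SCHEMA_REJECT_SIM else
                      "the attributes share no values and no name tokens")
            expl = (f"{m.source_attribute!r} -> {m.target_attribute!r} rejected: {reason}")
        else:
            label, rule = NEEDS_REVIEW, "R5"
            expl = (f"similarity {m.similarity:.2f} and value overlap {overlap:.0%} are "
                    "inconclusive; a human should review this match")

        if adapter is not None and label == NEEDS_REVIEW:
            sel = adapter.select(
                f"{m.source_attribute} -> {m.target_attribute}",
                [Candidate(name=ACCEPT), Candidate(name=REJECT), Candidate(name=NEEDS_REVIEW)],
            )
            if sel is not None and sel.choice in {ACCEPT, REJECT, NEEDS_REVIEW}:
                label = sel.choice
                rule = "R5+adapter"
                expl += f"; adapter escalated to {label}"
        out.append(MatchEvaluation(m, label, expl, rule))
    return out


def evaluate_value_matches(value_set: ValueMatchSet,
                           target_attr: TargetAttribute) -> list[MatchEvaluation]:
    """Label each value match in a set against the target's permissible values."""
    permissible = set(target_attr.permissible_values or [])
    out = []
    for vm in value_set.matches:
        if permissible and vm.target_value not in permissible:
            out.append(MatchEvaluation(
                vm, REJECT,
                f"proposed target value {vm.target_value!r} is not a permissible "
                f"value of {target_attr.name!r}",
                "out-of-domain"))
        elif normalize_name(vm.source_value) == normalize_name(vm.target_value):
            out.append(MatchEvaluation(
                vm, ACCEPT,
                f"{vm.source_value!r} equals {vm.target_value!r} after normalization",
                "V1"))
        elif vm.similarity >= VALUE_ACCEPT_SIM:
            out.append(MatchEvaluation(
                vm, ACCEPT,
                f"similarity {vm.similarity:.2f} is at or above {VALUE_ACCEPT_SIM}",
                "V2"))
        elif vm.similarity < VALUE_REJECT_SIM:
            out.append(MatchEvaluation(
                vm, REJECT,
                f"similarity {vm.similarity:.2f} is below {VALUE_REJECT_SIM}",
                "V3"))
        else:
            out.append(MatchEvaluation(
                vm, NEEDS_REVIEW,
                f"similarity {vm.similarity:.2f} sits between the reject and accept "
                "bands; a human should confirm this value mapping",
                "V4"))
    return out
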