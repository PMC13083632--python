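"""Schema matchers: find which source columns correspond to which target attributes.

All matchers share one dispatch contract (:func:`match_schema` for top-1,
:func:`rank_schema_matches` for top-k) and produce similarities in [0, 1]:

* ``composite_name`` — mean of four string/set similarity metrics on the
  attribute names (normalized Levenshtein, Jaro–Winkler, token-set Jaccard,
  character-3-gram cosine).
* ``similarity_flooding`` — graph propagation: schemas become graphs, name
  similarities seed a pairwise-connectivity graph and are iteratively
  propagated to neighbouring pairs until a fixpoint.
* ``distribution_based`` — compares column *values*: 1-D Earth mover's
  distance for numeric pairs, total-variation distance for categorical pairs.
* ``jaccard_distance`` — fuzzy Jaccard of distinct-value sets, where two
  values count as identical when their normalized Levenshtein distance is
  below a threshold.
* ``magneto_zs_bp`` / ``magneto_zs_llm`` — embedding-based candidate
  retrieval (zero-shot encoder) followed by maximum-weight bipartite
  reranking (bp) or adapter reranking (llm).
* ``two_phase`` — one matcher prunes the search space, a second one picks
  the winner among the survivors.
* ``max_val_sim`` — a name matcher prunes, then candidates are reranked by
  how well their permissible values match the source column's values.
* ``llm`` — a chat adapter picks matches from candidate descriptions.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import wasserstein_distance

from .backends import Candidate, ChatAdapter, HashEncoder, MockChatAdapter, TextEncoder
from .core import (AttributeMatch, Column, RankedMatchList, Table,
                   TargetAttribute, TargetSchema, coerce_target, parse_number,
                   rank_candidates)
from .errors import (AdapterError, EmptySchemaError, EmptyTableError,
                     InsufficientDataWarning, NonConvergenceWarning,
                     UnknownMethodError)
from .textutils import (char_ngrams, jaro_winkler, levenshtein_similarity,
                        normalized_levenshtein_distance, tokenize)

logger = logging.getLogger(__name__)

SCHEMA_METHODS = (
    "composite_name", "similarity_flooding", "distribution_based",
    "jaccard_distance", "magneto_zs_bp", "magneto_zs_llm", "two_phase",
    "max_val_sim", "llm",
)

#: Distinct values serialized per column for embedding.
EMBED_VALUE_CAP = 15


@dataclass
class MatcherConfig:
    """Method selection plus per-method arguments."""

    method: str = "composite_name"
    top_k: int = 10
    method_args: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in SCHEMA_METHODS:
            raise UnknownMethodError(
                f"unknown schema-matching method {self.method!r}; "
                f"available: {SCHEMA_METHODS}"
            )
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


# ---------------------------------------------------------------------------
# composite name similarity


def _trigram_cosine(a: str, b: str) -> float:
    ca, cb = Counter(char_ngrams(a)), Counter(char_ngrams(b))
    dot = sum(ca[g] * cb[g] for g in ca.keys() & cb.keys())
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb) if na and nb else 0.0


def _token_jaccard(a: str, b: str) -> float:
    ta, tb = set(tokenize(a)), set(tokenize(b))
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def composite_name_score(a: str, b: str) -> float:
    """Mean of four symmetric name-similarity components, each in [0, 1]."""
    fa, fb = a.casefold(), b.casefold()
    components = (
        levenshtein_similarity(fa, fb),
        jaro_winkler(fa, fb),
        _token_jaccard(a, b),
        _trigram_cosine(a, b),
    )
    return sum(components) / len(components)


# ---------------------------------------------------------------------------
# helpers


def _attr_kind(attr: TargetAttribute) -> str:
    meta_kind = attr.metadata.get("kind") or attr.metadata.get("type")
    if meta_kind in {"text", "numeric", "unknown"}:
        return meta_kind
    values = attr.values
    if not values:
        return "unknown"
    parsed = sum(1 for v in values if parse_number(v) is not None)
    return "numeric" if parsed / len(values) >= 0.95 else "text"


def _attr_numeric_sample(attr: TargetAttribute) -> list[float]:
    cells = attr.raw_cells if attr.raw_cells is not None else attr.values
    out = []
    for c in cells:
        v = parse_number(c)
        if v is not None:
            out.append(v)
    return out


def _attr_text_sample(attr: TargetAttribute) -> list[str]:
    cells = attr.raw_cells if attr.raw_cells is not None else attr.values
    return [str(c) for c in cells]


ScoreDict = dict[str, dict[str, float]]  # source attr -> target attr -> sim


def _check_inputs(source: Table, target: TargetSchema) -> None:
    if not source.columns:
        raise EmptyTableError("source table has no columns")
    if not target.attributes:
        raise EmptySchemaError("target schema has no attributes")


# ---------------------------------------------------------------------------
# individual matchers (each returns a ScoreDict)


def _composite_name_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    return {
        c.name: {a.name: composite_name_score(c.name, a.name) for a in target.attributes}
        for c in source.columns
    }


# --- similarity flooding ----------------------------------------------------

_SCHEMA_NODE = ("schema", "")


def _schema_graph(names_kinds: list[tuple[str, str]]) -> dict:
    """Flat schema graph: schema --column--> col --kind--> kind node."""
    edges = []
    for name, kind in names_kinds:
        edges.append((_SCHEMA_NODE, ("col", name), "column"))
        edges.append((("col", name), ("kind", kind), "kind"))
    return {"edges": edges}


def similarity_flooding_scores(source: Table, target: TargetSchema,
                               eps: float = 1e-4, max_iter: int = 100) -> ScoreDict:
    """Basic similarity-flooding fixpoint over the pairwise-connectivity graph.

    sigma^{i+1}(p) = sigma^i(p) + sum_{q in nbr(p)} sigma^i(q) * w(q, p),
    then normalized by the maximum; stops when the largest per-pair change
    drops below ``eps`` or after ``max_iter`` iterations (with a
    NonConvergenceWarning).  ``eps = inf`` returns the initial name scores.
    """
    g1 = _schema_graph([(c.name, c.kind) for c in source.columns])
    g2 = _schema_graph([(a.name, _attr_kind(a)) for a in target.attributes])

    # pairwise-connectivity graph: nodes are same-category node pairs
    pair_edges: list[tuple[tuple, tuple]] = []
    for (a1, a2, l1) in g1["edges"]:
        for (b1, b2, l2) in g2["edges"]:
            if l1 == l2:
                pair_edges.append(((a1, b1), (a2, b2)))
    nodes = sorted({p for e in pair_edges for p in e})
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)

    # propagation coefficients: 1 / out-degree per direction
    T = np.zeros((n, n))
    out_deg = Counter(e[0] for e in pair_edges)
    in_deg = Counter(e[1] for e in pair_edges)
    for p, q in pair_edges:
        T[index[q], index[p]] += 1.0 / out_deg[p]   # forward p -> q
        T[index[p], index[q]] += 1.0 / in_deg[q]    # backward q -> p

    def seed(pair: tuple) -> float:
        (cat_a, name_a), (cat_b, name_b) = pair
        if cat_a != cat_b:
            return 0.0
        if cat_a == "kind":
            return 1.0 if name_a == name_b else 0.0
        if cat_a == "schema":
            return 1.0
        return composite_name_score(name_a, name_b)

    sigma = np.array([seed(p) for p in nodes])
    if not math.isinf(eps):
        converged = False
        for _ in range(max_iter):
            nxt = sigma + T @ sigma
            peak = nxt.max()
            if peak > 0:
                nxt = nxt / peak
            delta = np.abs(nxt - sigma).max()
            sigma = nxt
            if delta < eps:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"similarity flooding did not converge in {max_iter} iterations",
                NonConvergenceWarning,
            )

    scores: ScoreDict = {c.name: {} for c in source.columns}
    for c in source.columns:
        for a in target.attributes:
            pair = (("col", c.name), ("col", a.name))
            scores[c.name][a.name] = float(min(max(sigma[index[pair]], 0.0), 1.0)) if pair in index else 0.0
    return scores


def _similarity_flooding_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    return similarity_flooding_scores(
        source, target,
        eps=float(cfg.method_args.get("eps", 1e-4)),
        max_iter=int(cfg.method_args.get("max_iter", 100)),
    )


# --- distribution based -----------------------------------------------------


def emd_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """1 - EMD between two numeric samples min-max scaled over the pooled range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:  # both samples constant and equal
        return 1.0
    a = (a - lo) / (hi - lo)
    b = (b - lo) / (hi - lo)
    return 1.0 - float(wasserstein_distance(a, b))


def total_variation_similarity(a: Sequence[str], b: Sequence[str]) -> float:
    """1 - total-variation distance between value-frequency vectors."""
    ca, cb = Counter(a), Counter(b)
    na, nb = sum(ca.values()), sum(cb.values())
    tv = 0.5 * sum(abs(ca[v] / na - cb[v] / nb) for v in set(ca) | set(cb))
    return 1.0 - tv


def _distribution_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    scores: ScoreDict = {}
    for c in source.columns:
        row: dict[str, float] = {}
        src_kind = c.kind
        for a in target.attributes:
            tgt_kind = _attr_kind(a)
            if src_kind != tgt_kind or src_kind == "unknown":
                row[a.name] = 0.0
                continue
            if src_kind == "numeric":
                sv, tv = c.numeric_values(), _attr_numeric_sample(a)
            else:
                sv, tv = [str(x) for x in c.non_missing()], _attr_text_sample(a)
            if len(sv) < 2 or len(tv) < 2:
                warnings.warn(
                    f"column pair ({c.name!r}, {a.name!r}) has <2 non-missing "
                    "values; scored 0", InsufficientDataWarning)
                row[a.name] = 0.0
                continue
            if src_kind == "numeric":
                row[a.name] = emd_similarity(sv, tv)
            else:
                row[a.name] = total_variation_similarity(sv, tv)
        scores[c.name] = row
    return scores


# --- fuzzy Jaccard ----------------------------------------------------------


def fuzzy_jaccard(values_a: Sequence[str], values_b: Sequence[str],
                  theta: float = 0.2) -> float:
    """Jaccard similarity with a fuzzy intersection.

    Distinct values are paired one-to-one greedily in ascending normalized
    Levenshtein distance, keeping only pairs with distance <= theta;
    similarity = |I| / (|A| + |B| - |I|).  At theta = 0 this is exact
    Jaccard on the two sets.
    """
    sa = list(dict.fromkeys(str(v) for v in values_a))
    sb = list(dict.fromkeys(str(v) for v in values_b))
    if not sa and not sb:
        return 0.0
    pairs = sorted(
        (normalized_levenshtein_distance(x, y), x, y)
        for x in sa for y in sb
        if normalized_levenshtein_distance(x, y) <= theta
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    intersection = 0
    for _, x, y in pairs:
        if x not in used_a and y not in used_b:
            used_a.add(x)
            used_b.add(y)
            intersection += 1
    return intersection / (len(sa) + len(sb) - intersection)


def _jaccard_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    theta = float(cfg.method_args.get("theta", 0.2))
    return {
        c.name: {
            a.name: fuzzy_jaccard(c.distinct_values(), a.values, theta)
            for a in target.attributes
        }
        for c in source.columns
    }


# --- magneto: embedding retrieval + bipartite / adapter reranking -----------


def serialize_column(item) -> str:
    """Flat text form of a column or attribute for embedding."""
    if isinstance(item, Column):
        name, values = item.name, item.distinct_values()
    elif isinstance(item, TargetAttribute):
        name, values = item.name, item.values
    else:
        raise TypeError(f"cannot serialize {type(item).__name__}")
    joined = ", ".join(str(v) for v in values[:EMBED_VALUE_CAP])
    return f"name: {name}. values: {joined}"


def embed_column(item, encoder: Optional[TextEncoder] = None) -> np.ndarray:
    """Unit-norm embedding of a column's serialized name + values."""
    enc = encoder or HashEncoder()
    return enc.encode([serialize_column(item)])[0]


def bipartite_rerank(score_matrix: np.ndarray) -> list[Optional[int]]:
    """Maximum-total-similarity one-to-one assignment.

    The matrix is square-padded with zeros; rows assigned to a padding
    column come back as None.  Among equal-cost optima a tiny deterministic
    bias prefers earlier rows taking lower-index columns.
    """
    m = np.asarray(score_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("score matrix must be 2-D")
    n_rows, n_cols = m.shape
    n = max(n_rows, n_cols)
    padded = np.zeros((n, n))
    padded[:n_rows, :n_cols] = m
    # deterministic tie-break bias, far below any meaningful score difference
    eps = 1e-9
    bias = np.zeros_like(padded)
    for i in range(min(n, 200)):
        bias[i, :] = eps * (n - np.arange(n)) / float(n) / (n + 1.0) ** (i + 1)
    rows, cols = linear_sum_assignment(padded + bias, maximize=True)
    assignment: list[Optional[int]] = [None] * n_rows
    for r, c in zip(rows, cols):
        if r < n_rows:
            assignment[r] = int(c) if c < n_cols else None
    return assignment


def _cosine_matrix(source: Table, target: TargetSchema, encoder: TextEncoder) -> np.ndarray:
    enc_src = np.stack([embed_column(c, encoder) for c in source.columns])
    enc_tgt = np.stack([embed_column(a, encoder) for a in target.attributes])
    return np.clip(enc_src @ enc_tgt.T, 0.0, 1.0)


def _magneto_scores(source: Table, target: TargetSchema, cfg: MatcherConfig,
                    rerank: str) -> ScoreDict:
    encoder = cfg.method_args.get("encoder") or HashEncoder()
    retrieval_k = int(cfg.method_args.get("retrieval_k", max(cfg.top_k, 10)))
    cos = _cosine_matrix(source, target, encoder)
    tgt_names = target.attribute_names

    # per-source candidate retrieval by cosine
    candidates: list[list[int]] = []
    for i in range(cos.shape[0]):
        ranked = rank_candidates(
            {name: float(cos[i, j]) for j, name in enumerate(tgt_names)}, retrieval_k
        )
        candidates.append([tgt_names.index(name) for name, _ in ranked])

    union = sorted({j for cand in candidates for j in cand})
    sub = cos[:, union]

    winners: dict[int, int] = {}
    if rerank == "bp":
        assignment = bipartite_rerank(sub)
        for i, col in enumerate(assignment):
            if col is not None:
                winners[i] = union[col]
    else:  # adapter reranking
        adapter: ChatAdapter = cfg.method_args.get("adapter") or MockChatAdapter()
        try:
            for i, src_col in enumerate(source.columns):
                offered = [
                    Candidate(
                        name=tgt_names[j],
                        description=target.attributes[j].description,
                        values=tuple(target.attributes[j].values[:8]),
                    )
                    for j in candidates[i]
                ]
                sel = adapter.select(
                    serialize_column(src_col), offered
                ) if offered else None
                if sel is not None and sel.choice in {c.name for c in offered}:
                    winners[i] = tgt_names.index(sel.choice)
        except AdapterError as exc:
            logger.warning("magneto adapter failed (%s); using bipartite rerank", exc)
            assignment = bipartite_rerank(sub)
            winners = {i: union[c] for i, c in enumerate(assignment) if c is not None}

    # winner first (keeps its cosine); the rest keep cosine capped at the
    # winner's score so the ranked list stays non-increasing
    scores: ScoreDict = {}
    for i, src_col in enumerate(source.columns):
        row: dict[str, float] = {}
        win = winners.get(i)
        win_score = float(cos[i, win]) if win is not None else None
        for j in candidates[i]:
            s = float(cos[i, j])
            if win is not None and j != win:
                s = min(s, win_score) * (1.0 - 1e-9)  # strictly below the winner
            row[tgt_names[j]] = s
        scores[src_col.name] = row
    return scores


def _magneto_bp_scores(source, target, cfg) -> ScoreDict:
    return _magneto_scores(source, target, cfg, rerank="bp")


def _magneto_llm_scores(source, target, cfg) -> ScoreDict:
    return _magneto_scores(source, target, cfg, rerank="llm")


# --- two phase --------------------------------------------------------------


def _two_phase_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    args = cfg.method_args
    phase1 = str(args.get("phase1", "composite_name"))
    phase2 = str(args.get("phase2", "jaccard_distance"))
    prune_k = int(args.get("prune_k", max(cfg.top_k, 10)))
    cfg1 = MatcherConfig(phase1, top_k=prune_k, method_args=dict(args.get("phase1_args", {})))
    cfg2 = MatcherConfig(phase2, top_k=prune_k, method_args=dict(args.get("phase2_args", {})))
    s1 = _SCORERS[phase1](source, target, cfg1)
    s2 = _SCORERS[phase2](source, target, cfg2)
    scores: ScoreDict = {}
    for src, row1 in s1.items():
        kept = [name for name, _ in rank_candidates(row1, prune_k)]
        # rank by phase2 score with phase1 as tie-break (folded in far below
        # the phase2 resolution)
        scores[src] = {
            name: min(s2[src].get(name, 0.0) + 1e-9 * row1[name], 1.0) for name in kept
        }
    return scores


# --- max_val_sim ------------------------------------------------------------


def _max_val_sim_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    from .value_matching import _similarity_matrix  # late import, avoids a cycle

    args = cfg.method_args
    phase1 = str(args.get("phase1", "composite_name"))
    value_method = str(args.get("value_method", "tfidf"))
    prune_k = int(args.get("prune_k", max(cfg.top_k, 10)))
    cfg1 = MatcherConfig(phase1, top_k=prune_k, method_args=dict(args.get("phase1_args", {})))
    s1 = _SCORERS[phase1](source, target, cfg1)
    scores: ScoreDict = {}
    for c in source.columns:
        row1 = s1[c.name]
        kept = [name for name, _ in rank_candidates(row1, prune_k)]
        svals = c.distinct_values()
        row: dict[str, float] = {}
        for name in kept:
            attr = target.attribute(name)
            if not attr.values or not svals:
                # no values to compare: keep the name score, scaled down
                row[name] = 0.5 * row1[name]
                continue
            sim = _similarity_matrix(value_method, svals, attr.values, dict(args.get("value_args", {})))
            value_score = float(np.mean(sim.max(axis=1)))
            row[name] = min(value_score + 1e-9 * row1[name], 1.0)
        scores[c.name] = row
    return scores


# --- llm --------------------------------------------------------------------


def _llm_scores(source: Table, target: TargetSchema, cfg: MatcherConfig) -> ScoreDict:
    adapter: ChatAdapter = cfg.method_args.get("adapter") or MockChatAdapter()
    tgt_names = target.attribute_names
    scores: ScoreDict = {}
    try:
        for c in source.columns:
            offered = [
                Candidate(name=a.name, description=a.description,
                          values=tuple(a.values[:8]))
                for a in target.attributes
            ]
            query = serialize_column(c)
            row: dict[str, float] = {}
            prev_conf = 1.0
            remaining = list(offered)
            for _ in range(min(cfg.top_k, len(offered))):
                if not remaining:
                    break
                sel = adapter.select(query, remaining)
                if sel is None:
                    break
                if sel.choice not in {x.name for x in remaining}:
                    # out-of-candidate-set answer: reject, drop it if it is a
                    # stale earlier pick, and move on
                    remaining = [x for x in remaining if x.name != sel.choice]
                    continue
                conf = min(min(sel.confidence, 1.0), prev_conf)
                row[sel.choice] = conf
                prev_conf = conf
                remaining = [x for x in remaining if x.name != sel.choice]
            # fill the rest with composite-name scores capped below the last
            # adapter confidence
            floor = prev_conf * (1.0 - 1e-9)
            for a in target.attributes:
                if a.name not in row:
                    row[a.name] = min(composite_name_score(c.name, a.name), floor)
            scores[c.name] = row
        return scores
    except AdapterError as exc:
        logger.warning("llm adapter failed (%s); falling back to composite_name", exc)
        return _composite_name_scores(source, target, cfg)


# ---------------------------------------------------------------------------
# dispatch

_SCORERS = {
    "composite_name": _composite_name_scores,
    "similarity_flooding": _similarity_flooding_scores,
    "distribution_based": _distribution_scores,
    "jaccard_distance": _jaccard_scores,
    "magneto_zs_bp": _magneto_bp_scores,
    "magneto_zs_llm": _magneto_llm_scores,
    "two_phase": _two_phase_scores,
    "max_val_sim": _max_val_sim_scores,
    "llm": _llm_scores,
}


def rank_schema_matches(source: Table, target, cfg: Optional[MatcherConfig] = None,
                        method: Optional[str] = None, top_k: Optional[int] = None,
                        **method_args) -> list[RankedMatchList]:
    """Top-k ranked target candidates per source column.

    Candidates are sorted by descending similarity with lexicographic
    tie-breaks; at most min(top_k, |target|) candidates are returned.
    """
    if cfg is None:
        cfg = MatcherConfig(method or "composite_name", top_k=top_k or 10,
                            method_args=method_args)
    target = coerce_target(target)
    _check_inputs(source, target)
    scores = _SCORERS[cfg.method](source, target, cfg)
    out = []
    for c in source.columns:
        out.append(RankedMatchList(c.name, rank_candidates(scores[c.name], cfg.top_k)))
    return out


def match_schema(source: Table, target, cfg: Optional[MatcherConfig] = None,
                 method: Optional[str] = None, **method_args) -> list[AttributeMatch]:
    """Top-1 schema matching: exactly one AttributeMatch per source column."""
    if cfg is None:
        cfg = MatcherConfig(method or "composite_name", method_args=method_args)
    ranked = rank_schema_matches(source, target, cfg)
    matches = []
    for r in ranked:
        top = r.top
        if top is None:  # no candidates survived pruning; force the best name match
            target_schema = coerce_target(target)
            fallback = rank_candidates(
                {a.name: composite_name_score(r.source_attribute, a.name)
                 for a in target_schema.attributes}, 1)
            top = AttributeMatch(r.source_attribute, fallback[0][0], fallback[0][1])
        matches.append(top)
    return matches
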