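"""Shared low-level string routines used by the matchers and the reviewer."""

from __future__ import annotations

import re

import edlib

_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")
_SPLIT_RE = re.compile(r"[^0-9A-Za-z]+")


def tokenize(text: str) -> list[str]:
    """Split on snake/camel/space boundaries and case-fold.

    "Tumor_Focality" -> ["tumor", "focality"]; "AgeAtIndex" -> ["age", "at", "index"].
    """
    parts = []
    for chunk in _SPLIT_RE.split(text):
        if chunk:
            parts.extend(p for p in _CAMEL_RE.split(chunk) if p)
    return [p.casefold() for p in parts]


def normalize_name(text: str) -> str:
    """Case-fold and strip every non-alphanumeric character."""
    return re.sub(r"[^0-9a-z]+", "", text.casefold())


def char_ngrams(text: str, n: int = 3, pad: str = "#") -> list[str]:
    """Case-folded character n-grams with one boundary pad on each side."""
    padded = pad + text.casefold() + pad
    if len(padded) < n:
        return [padded]
    return [padded[i : i + n] for i in range(len(padded) - n + 1)]


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit costs)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def normalized_levenshtein_distance(a: str, b: str) -> float:
    """levenshtein(a, b) / max(|a|, |b|); 0.0 for two empty strings."""
    m = max(len(a), len(b))
    return levenshtein(a, b) / m if m else 0.0


def levenshtein_similarity(a: str, b: str) -> float:
    return 1.0 - normalized_levenshtein_distance(a, b)


def jaro(a: str, b: str) -> float:
    """Jaro similarity."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    sa = [c for c, m in zip(a, match_a) if m]
    sb = [c for c, m in zip(b, match_b) if m]
    transpositions = sum(ca != cb for ca, cb in zip(sa, sb)) // 2
    return (matches / la + matches / lb + (matches - transpositions) / matches) / 3.0


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro–Winkler similarity: Jaro with a bonus for a shared prefix."""
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)
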