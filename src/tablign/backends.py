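"""Pluggable model backends: text encoders and chat-style adapters.

Two contracts, each with a deterministic offline implementation:

* :class:`TextEncoder` — maps a batch of strings to fixed-dimension
  unit-norm vectors.  :class:`HashEncoder` is the offline implementation:
  signed feature hashing of character 3-grams.  A pretrained sentence
  encoder is a drop-in replacement behind the same contract.
* :class:`ChatAdapter` — given a query context and a candidate list,
  selects one candidate with a confidence, or abstains.
  :class:`MockChatAdapter` is the offline implementation: a deterministic
  token-overlap rule.  A hosted or local LLM is a drop-in replacement.

The whole test suite runs with only the offline backends — no network and
no model downloads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .textutils import char_ngrams, tokenize


@runtime_checkable
class TextEncoder(Protocol):
    name: str
    dimension: int

    def encode(self, texts: Sequence[str]) -> np.ndarray:  # (len(texts), dimension)
        ...


def _bucket_and_sign(ngram: str, dimension: int) -> tuple[int, float]:
    # Seedless, version-pinned hash so vectors are reproducible artifacts
    # across runs and platforms.
    digest = hashlib.blake2b(ngram.encode("utf-8"), digest_size=9).digest()
    bucket = int.from_bytes(digest[:8], "big") % dimension
    sign = 1.0 if digest[8] % 2 == 0 else -1.0
    return bucket, sign


def hash_encode(texts: Sequence[str], dimension: int = 512) -> np.ndarray:
    """Signed feature hashing of case-folded character 3-grams.

    Each text becomes the L2-normalized sum of signed one-hot buckets, one
    per 3-gram occurrence.  The sign (from a second hash byte) reduces
    collision bias.  All-empty texts map to the zero vector.
    """
    if dimension < 16:
        raise ValueError("dimension must be >= 16")
    out = np.zeros((len(texts), dimension), dtype=np.float64)
    for row, text in enumerate(texts):
        for gram in char_ngrams(text):
            bucket, sign = _bucket_and_sign(gram, dimension)
            out[row, bucket] += sign
        norm = np.linalg.norm(out[row])
        if norm > 0:
            out[row] /= norm
    return out


@dataclass
class HashEncoder:
    """Deterministic offline TextEncoder based on :func:`hash_encode`."""

    dimension: int = 512
    name: str = "hash-3gram"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        return hash_encode(list(texts), self.dimension)


@dataclass
class Candidate:
    """One option offered to a chat adapter."""

    name: str
    description: str = ""
    values: tuple[str, ...] = ()


@dataclass
class Selection:
    choice: str
    confidence: float


@runtime_checkable
class ChatAdapter(Protocol):
    name: str
    model_id: str

    def select(self, query: str, candidates: Sequence[Candidate]) -> Optional[Selection]:
        """Pick one candidate for the query, or return None to abstain."""
        ...


def _context_tokens(name: str, description: str = "", values: Sequence[str] = ()) -> frozenset[str]:
    # word tokens plus character 3-grams of the name, so near-identical
    # spellings (CNV_L vs CNV_LOW) outrank same-prefix alternatives
    toks = set(tokenize(name))
    toks.update(char_ngrams(name))
    toks.update(tokenize(description))
    for v in values:
        toks.update(tokenize(str(v)))
    return frozenset(toks)


def mock_select(candidates: Sequence[Candidate], query: str,
                query_values: Sequence[str] = ()) -> Optional[Selection]:
    """Deterministic selection rule: maximum token overlap with the query.

    Confidence is the overlap fraction (Jaccard of token sets).  Zero overlap
    for every candidate means abstain.  Ties go to the lexicographically
    smallest candidate name.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    q = _context_tokens(query, values=query_values)
    best: Optional[tuple[float, str]] = None
    for cand in candidates:
        c = _context_tokens(cand.name, cand.description, cand.values)
        union = q | c
        overlap = len(q & c) / len(union) if union else 0.0
        key = (-overlap, cand.name)
        if best is None or key < (-best[0], best[1]):
            best = (overlap, cand.name)
    if best is None or best[0] == 0.0:
        return None
    return Selection(choice=best[1], confidence=best[0])


@dataclass
class MockChatAdapter:
    """Offline ChatAdapter applying :func:`mock_select`."""

    name: str = "mock"
    model_id: str = "token-overlap-v1"
    query_values: tuple[str, ...] = ()

    def select(self, query: str, candidates: Sequence[Candidate]) -> Optional[Selection]:
        return mock_select(candidates, query, query_values=self.query_values)
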