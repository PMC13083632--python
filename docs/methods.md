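# Methods

This note documents the models and procedures implemented in `tablign`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test data does and does not show.

## Problem setting

A *source* table (named columns of text/numeric/missing cells) is to be
aligned with a *target*, which is either a second table or a data-model
standard — a catalogue of attributes with optional permissible values and
metadata.  Both are viewed uniformly as a `TargetSchema`.  Harmonization
proceeds in three stages: schema matching (column ↔ attribute), value
matching (cell value ↔ permissible value), and materialization through a
declarative specification.  One source attribute may feed several targets;
two sources feeding one target (a many-to-one mapping, e.g. deriving BMI from
weight and height) is out of scope and rejected with an error.

## Table model

Cells are text, numbers, or missing.  The missing-value sentinels are the
empty string, `NA`, `NaN` and `null` (case-insensitive), matching common
biomedical CSV dialects.  Numeric parsing accepts integer, decimal and
scientific notation and rejects thousands separators and the textual
`inf`/`nan` forms, so classification is unambiguous.  A column is *numeric*
when at least 95% of its non-missing cells parse as numbers (tolerating stray
annotations like `"n/a (lost)"` in an otherwise numeric column), *unknown*
when all cells are missing, *text* otherwise.  Distinct values are extracted
in first-occurrence order, which makes every downstream tie-break
reproducible.  Date-times are treated as text.

## Schema matchers

All matchers emit similarities in [0, 1] by construction — no post-hoc
rescaling — so meta-matchers can compare scores across methods.  Exact score
ties are always broken lexicographically by target attribute name.

**composite_name.**  The mean of four symmetric components on case-folded
names: normalized Levenshtein similarity, Jaro–Winkler, token-set Jaccard
after snake/camel/space tokenization, and character-3-gram cosine.  Edit
distances are computed with `edlib`; Jaro–Winkler is implemented in
`textutils` (standard prefix bonus 0.1, max prefix 4) and verified against
published example values.

**similarity_flooding.**  Each schema becomes a flat graph (schema node →
column nodes → kind nodes; no nesting, since the inputs are single flat
tables).  The pairwise-connectivity graph pairs same-category nodes whose
parents are connected by same-labelled edges.  Propagation coefficients are
the inverse out-degree per direction ("basic" variant); the fixpoint is

    sigma_{i+1}(p) = sigma_i(p) + sum_{q in nbr(p)} sigma_i(q) * w(q,p)

followed by max-normalization, seeded with `composite_name` scores for column
pairs (1 for schema and equal-kind pairs).  Defaults: tolerance `eps = 1e-4`,
`max_iter = 100`; hitting the cap raises `NonConvergenceWarning` and returns
the last iterate.  `eps = inf` short-circuits to the seed scores.

**distribution_based.**  Numeric pairs: both samples are min–max scaled over
the pooled range and compared with the 1-D Earth mover's distance (equal to
the integral of |ΔCDF|, bounded by 1 after scaling); similarity is 1 − EMD.
Text pairs: 1 − total-variation distance between value-frequency vectors over
the union of exact values.  Kind-mismatched pairs score 0.  Columns with
fewer than two non-missing values cannot define a distribution; the pair
scores 0 with `InsufficientDataWarning`.  When the target is a table, full
cell frequencies are used; a standard's permissible values are treated as a
uniform sample.

**jaccard_distance.**  Distinct values are paired one-to-one greedily in
ascending normalized Levenshtein distance, keeping pairs at distance ≤ θ
(default 0.2); similarity is |I|/(|A|+|B|−|I|).  θ = 0 reduces to exact
Jaccard.  Greedy pairing can in principle fall short of the optimal
bipartite pairing; the test suite bounds it by a brute-force oracle and
observes agreement on almost all small random instances.  Values are
compared without case folding here so the θ = 0 degenerate case is exactly
set-theoretic Jaccard.

**magneto_zs_bp / magneto_zs_llm.**  Each column is serialized as
`name: <name>. values: v1, …, v15` (15 caps the embedding payload; beyond
that additional values add little discriminative signal) and embedded with
the configured encoder.  Cosine retrieval keeps the top `retrieval_k`
(default 10) candidates per source column; a maximum-weight bipartite
assignment (Hungarian algorithm on the square-zero-padded candidate matrix)
rewrites the top-1 choices one-to-one.  Sources assigned to padding fall
back to their top cosine candidate.  In the ranked output the assignment
winner comes first with its cosine score and the remaining candidates keep
their cosine capped just below the winner, so ranked lists stay
non-increasing.  The `llm` variant replaces the bipartite step with a chat
adapter choosing among the retrieved candidates; on adapter failure it falls
back to the bipartite path.  Equal-cost assignment optima are disambiguated
by an infinitesimal bias (1e-9 scale) favouring earlier rows and lower
column indices; the bias is orders of magnitude below meaningful score
differences and only makes ties deterministic.

**two_phase / max_val_sim.**  `two_phase` prunes with one matcher
(`prune_k`, default 10) and rescores survivors with a second; ranking is by
the phase-2 score with the phase-1 score folded in at 1e-9 scale as a pure
tie-break.  `max_val_sim` prunes by name and reranks candidates by their
*value score*: the mean over source distinct values of the best value-match
similarity against the candidate's permissible values (default value matcher
tfidf).  Candidates without permissible values keep half their name score —
value evidence is absent, so the name-only score is discounted rather than
trusted outright.

**llm.**  The adapter receives, per source column, all target attributes with
names, descriptions and up to 8 sample values, and repeatedly selects a
candidate with a confidence; out-of-candidate-set answers are rejected.
Unselected candidates are filled in with composite-name scores capped below
the last adapter confidence.  Adapter errors fall back to `composite_name`
with a logged warning.

## Value matchers

The default edit-distance scorer is `1 − lev(s,t)/max(|s|,|t|)` on
case-folded strings (two empty strings score 1).  A user-supplied scorer
must return values in [0, 1] or `ScorerContractError` is raised.  TF-IDF uses
case-folded character 3-grams padded with one `#` on each boundary, fitted
over the deduplicated union of both value lists with smoothed IDF
`ln((1+N)/(1+df)) + 1`, cosine similarity, and a forced 1.0 for exact
case-insensitive equality — capitalization-only variants must never depend
on a model.  Embedding similarity is the encoder cosine mapped from [−1, 1]
to [0, 1] via (x+1)/2.  A top-1 value match is emitted only when its
similarity reaches τ = 0.3 (low enough to keep abbreviation-style matches
like `UNK → unknown`, high enough to drop unrelated strings); everything
else is reported unmatched for human review.

**Numeric transforms.**  Affine transforms `y = x·scale + offset` with
rounding ∈ {none, floor, nearest} and non-zero scale.  Inference considers
the candidate scales {12, 365.25, 1/12, 1/365.25, 1000, 1/1000, 1} and picks
by unit hints: the target unit from attribute metadata, the source unit from
an explicit argument or a unit word in the column name.  Years → days uses
365.25 (Julian-year convention) with floor rounding, i.e. age in *completed*
days, matching how clinical CDMs store ages; years → months uses 12.
Without hints an adapter may propose a candidate scale; otherwise the
identity transform is returned with provenance `no-evidence` rather than
guessing.  Applying a transform and then its algebraic inverse (rounding
dropped) recovers inputs to 1e-9 relative error.

## Harmonization specification

The JSON grammar is this package's own documented contract:

```json
{"version": "1", "mappings": [
  {"source_attribute": "...", "target_attribute": "...",
   "mapper": {"type": "dictionary", "map": {"...": "..."}, "unmatched_policy": "null"},
   "similarity": 0.9, "provenance": "auto:tfidf"}]}
```

Mapper types: `identity`, `dictionary`, `affine` (serialized scale / offset /
rounding), `custom` (routine *name* only — specs never carry executable
content; routines are re-registered at runtime).  Dictionary values not
covered by the map become null by default (`unmatched_policy: "null"`);
passthrough is available per entry but can silently emit values outside the
target domain, so it is opt-in.  `merge_mappings` keys user precedence by
source attribute: a user entry replaces *all* auto entries for that source,
and the merge is idempotent in the user argument.  `validate_spec` reports
findings (unknown attributes, out-of-domain dictionary values, many-to-one
collisions) instead of raising, so a UI can display them; the constructors
and I/O paths raise `ManyToOneError` eagerly.

## Match triage

Schema rules, first hit wins: R1 normalized-name equality with compatible
value sets → accept; R2 value-set equality after case/punctuation
normalization → accept; R3 similarity ≥ 0.9 with fuzzy value overlap ≥ 0.5 →
accept; R4 similarity < 0.4 or zero value and name-token overlap → reject;
R5 otherwise → needs_review.  Value rules: normalized equality → accept,
similarity ≥ 0.8 → accept, < 0.4 → reject, else needs_review; a proposed
target outside the permissible set rejects with rule `out-of-domain`.  The
band thresholds are this package's own calibration of the three-way triage;
explanations are rendered from per-rule templates naming the evidence.  An
optional adapter may refine only needs_review outcomes — it can never flip
an accept or a reject, keeping the offline rule core authoritative.

## Offline backends

`HashEncoder` feature-hashes case-folded character 3-grams into 512 signed
buckets (bucket and sign from a seedless BLAKE2b digest, so vectors are
stable across runs and platforms) and L2-normalizes.  `MockChatAdapter`
selects the candidate with maximal token overlap with the query (word tokens
plus name 3-grams; confidence is the Jaccard overlap; zero overlap abstains;
ties go to the lexicographically smallest name).  The entire test suite runs
with only these two backends.  Pretrained sentence encoders or hosted LLMs
plug in behind the same `TextEncoder` / `ChatAdapter` contracts as
configuration.

## Synthetic fixtures

`generate_fixture` draws a target table from a pool of twelve
clinical/assay-style attributes (gender, race, bmi, tumor_focality,
age_at_diagnosis, cnv_status, assay, species, vital_status, tumor_grade,
primary_site, aliquot_id) and derives the source by applying requested
perturbations: header case changes, snake→camel renames, a fixed
abbreviation table, single-character typos, categorical value recodes from a
fixed variant map, a years→days unit change on age, and distractor columns.
Defaults are 50 rows and 10 columns — enough rows for stable value
distributions while keeping the full 20-seed recovery benchmark under a few
seconds.  All randomness flows from one `random.Random(seed)`, so
regeneration is byte-identical.

What the fixtures do *not* emulate: the scale of real CDMs (hundreds of
attributes, thousands of permissible values), semantically unrelated
synonym pairs (e.g. `sex` vs `gender` spelled completely differently),
free-text fields, and messy real-world missingness.  Passing the recovery
benchmark therefore demonstrates correctness of the machinery and robustness
to surface variation, not state-of-the-art matching accuracy on hard
biomedical corpora.

## Known limitations

Many-to-one mappings and multi-file inputs are unsupported by design.  The
greedy fuzzy-Jaccard intersection is not guaranteed optimal.  The triage
rule core is a deterministic surrogate for LLM-based match evaluation; its
labels come from score bands, not semantic reasoning, and borderline matches
should still be reviewed.  The bipartite tie-break bias guarantees
determinism but not exact lexicographic minimality for assignments deeper
than ~200 rows.
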