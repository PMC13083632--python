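# tablign

Schema matching, value matching, and declarative harmonization of biomedical
tabular data.

Biomedical studies rarely agree on how to spell a column name, encode a
categorical value, or express a unit.  One cohort reports `CNV_class` with
values `CNV_LOW`/`CNV_HIGH`; another reports `cnv_status` with `CNV_L`/`CNV_H`;
a common data model (CDM) wants ages in days while the source table records
years.  Before any joint analysis, someone has to discover these
correspondences and apply them — by hand, column by column, value by value.

`tablign` automates that work for anyone integrating clinical or omics tables:
it matches a source table's columns to a target table or data-model standard
(*schema matching*), aligns the values of each matched pair (*value matching*),
composes the result into a declarative, reusable JSON *harmonization
specification* with user overrides taking precedence, and materializes the
harmonized dataset.  Every proposed match can be triaged automatically into
`accept` / `needs_review` / `reject` with a plain-language explanation, keeping
a human in the loop where it matters.

## Methods at a glance

**Schema matchers** (all produce similarities in [0, 1], top-1 or ranked top-k):

| method | idea |
|---|---|
| `composite_name` | mean of normalized Levenshtein, Jaro–Winkler, token-set Jaccard, and character-3-gram cosine on the names |
| `similarity_flooding` | schemas become graphs; name similarities seed a pairwise-connectivity graph and flood to neighbours until a fixpoint: σ⁽ⁱ⁺¹⁾(p) = σ⁽ⁱ⁾(p) + Σ_q σ⁽ⁱ⁾(q)·w(q,p), max-normalized |
| `distribution_based` | 1-D Earth mover's distance between min–max-scaled numeric columns (EMD = ∫\|F₁−F₂\|), total-variation distance between categorical frequency vectors |
| `jaccard_distance` | fuzzy Jaccard \|I\|/(\|A\|+\|B\|−\|I\|), where the intersection pairs values greedily at normalized Levenshtein distance ≤ θ |
| `magneto_zs_bp` / `magneto_zs_llm` | zero-shot embedding retrieval over serialized columns (`name: …. values: …`), reranked by maximum-weight bipartite assignment (Hungarian) or by a chat adapter |
| `two_phase` | one matcher prunes to top-k, a second picks among the survivors |
| `max_val_sim` | name matcher prunes; candidates reranked by mean best value-match similarity |
| `llm` | chat adapter chooses among candidates with names, descriptions, sample values |

**Value matchers**: Levenshtein edit-distance similarity 1 − d(s,t)/max(|s|,|t|);
TF-IDF cosine over boundary-padded character 3-grams (smoothed IDF
ln((1+N)/(1+df))+1); embedding cosine mapped to [0, 1]; an adapter-driven LLM
route; and affine numeric-transform inference from unit hints (years → days
uses 365.25 with floor rounding).

All embedding/LLM functionality runs offline by default behind two contracts:
a deterministic signed feature-hashing text encoder and a deterministic
token-overlap mock adapter.  Real encoders or hosted models are drop-in
configuration, not code changes.

## Worked example

```python
import tablign as tl

source = tl.validate_table({
    "CNV_class": ["CNV_LOW", "CNV_HIGH", "CNV_LOW"],
    "Tumor_Focality": ["Unifocal", "Multifocal", "Unifocal"],
    "Age": ["65", "54", "71"],
}, name="cohort")

matches = tl.match_schema(source, "toy_cdm", method="magneto_zs_bp")
for m in matches:
    print(f"{m.source_attribute:15s} -> {m.target_attribute:16s} similarity={m.similarity:.3f}")
```

```
CNV_class       -> cnv_status       similarity=0.803
Tumor_Focality  -> tumor_focality   similarity=0.933
Age             -> age_at_index     similarity=0.583
```

Each source column is matched to its best attribute in the bundled `toy_cdm`
data model; the similarity is the embedding cosine of the serialized columns
after one-to-one bipartite reranking.  Value matching then aligns the
categorical codes:

```python
pairs = [m for m in matches
         if tl.load_standard("toy_cdm").get_attribute_values(m.target_attribute)]
value_sets = tl.match_values(source, "toy_cdm", pairs, method="tfidf")
```

```
CNV_class: 'CNV_LOW' -> 'CNV_L' (0.419)
CNV_class: 'CNV_HIGH' -> 'CNV_H' (0.378)
Tumor_Focality: 'Unifocal' -> 'unifocal' (1.000)
Tumor_Focality: 'Multifocal' -> 'multifocal' (1.000)
```

`CNV_LOW → CNV_L` is found despite the spelling difference (shared character
3-grams); case-only differences score exactly 1.0 without any model call.
Building and applying the specification produces the harmonized table:

```python
spec = tl.build_spec(matches, value_sets, method="tfidf")
harmonized = tl.materialize(source, spec)
print(harmonized.to_dataframe())
```

```
  cnv_status tumor_focality age_at_index
0      CNV_L       unifocal           65
1      CNV_H     multifocal           54
2      CNV_L       unifocal           71
```

The spec serializes to JSON (`tl.write_spec`), merges with hand-written
overrides (`tl.merge_mappings`, user entries win), and can be reapplied to any
future table with the same source schema.

The same pipeline is available from the shell:

```bash
tablign match-schema cohort.csv --target-standard toy_cdm --method magneto_zs_bp
tablign build-spec cohort.csv target.csv -o spec.json
tablign materialize cohort.csv spec.json -o harmonized.csv
```

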