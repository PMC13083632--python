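"""Schema matchers: unit tests per matcher plus independent numerical oracles."""

import itertools
import math
import random
import warnings

import numpy as np
import pytest

from tablign import (MatcherConfig, as_target_schema, bipartite_rerank,
                     composite_name_score, embed_column, fuzzy_jaccard,
                     match_schema, rank_schema_matches, validate_table)
from tablign.backends import Candidate, HashEncoder, Selection
from tablign.core import TargetSchema
from tablign.errors import (AdapterError, EmptySchemaError,
                            InsufficientDataWarning, UnknownMethodError)
from tablign.schema_matching import (SCHEMA_METHODS, emd_similarity,
                                     serialize_column,
                                     similarity_flooding_scores,
                                     total_variation_similarity)
from tablign.textutils import jaro_winkler, levenshtein

# ---------------------------------------------------------------------------
# oracles


def dp_levenshtein(a, b):
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def emd_oracle(a, b):
    """Closed-form 1-D EMD: integral of |F_a - F_b| over the pooled support."""
    a, b = np.sort(np.asarray(a, float)), np.sort(np.asarray(b, float))
    grid = np.sort(np.unique(np.concatenate([a, b])))
    total = 0.0
    for lo, hi in zip(grid[:-1], grid[1:]):
        fa = np.searchsorted(a, lo, side="right") / len(a)
        fb = np.searchsorted(b, lo, side="right") / len(b)
        total += abs(fa - fb) * (hi - lo)
    return total


def brute_force_assignment_value(matrix):
    """Maximum assignment total over all row->column injections."""
    n_rows, n_cols = matrix.shape
    n = max(n_rows, n_cols)
    padded = np.zeros((n, n))
    padded[:n_rows, :n_cols] = matrix
    return max(
        sum(padded[i, p[i]] for i in range(n))
        for p in itertools.permutations(range(n))
    )


def brute_force_fuzzy_intersection(sa, sb, theta):
    """Largest one-to-one pairing with normalized distance <= theta."""
    def norm_dist(x, y):
        m = max(len(x), len(y))
        return dp_levenshtein(x, y) / m if m else 0.0

    best = 0
    for k in range(min(len(sa), len(sb)), 0, -1):
        for subset in itertools.permutations(sb, k):
            for chosen in itertools.combinations(sa, k):
                if all(norm_dist(x, y) <= theta for x, y in zip(chosen, subset)):
                    return k
    return best


# ---------------------------------------------------------------------------
# composite name matcher


class TestCompositeName:
    def test_identity(self):
        assert composite_name_score("gender", "gender") == 1.0

    def test_underscore_case_variants_score_high(self):
        assert composite_name_score("Tumor_Focality", "tumor_focality") >= 0.9

    def test_disjoint_strings_score_zero(self):
        # every component is zero: no shared characters, tokens, or grams
        assert composite_name_score("abc", "xyz") == 0.0

    def test_equals_mean_of_components(self):
        a, b = "age_at_index", "age_index"
        fa, fb = a.casefold(), b.casefold()
        lev_sim = 1 - dp_levenshtein(fa, fb) / max(len(fa), len(fb))
        jw = jaro_winkler(fa, fb)
        ta, tb = {"age", "at", "index"}, {"age", "index"}
        jac = len(ta & tb) / len(ta | tb)

        def grams(s):
            p = "#" + s.casefold() + "#"
            return [p[i:i + 3] for i in range(len(p) - 2)]

        from collections import Counter
        ca, cb = Counter(grams(a)), Counter(grams(b))
        dot = sum(ca[g] * cb[g] for g in ca)
        cos = dot / math.sqrt(sum(v * v for v in ca.values())) / math.sqrt(
            sum(v * v for v in cb.values()))
        expected = (lev_sim + jw + jac + cos) / 4
        assert composite_name_score(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        assert composite_name_score("BMI", "bmi_index") == composite_name_score(
            "bmi_index", "BMI")


class TestJaroWinkler:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("martha", "marhta", 0.9611),
            ("dixon", "dicksonx", 0.8133),
            ("dwayne", "duane", 0.84),
            ("abc", "abc", 1.0),
            ("", "abc", 0.0),
        ],
    )
    def test_published_values(self, a, b, expected):
        assert jaro_winkler(a, b) == pytest.approx(expected, abs=1e-3)


# ---------------------------------------------------------------------------
# similarity flooding


class TestSimilarityFlooding:
    def test_identical_schemas_match_namesakes(self):
        t = validate_table({"gender": ["f", "m"], "age": ["1", "2"]})
        ranked = rank_schema_matches(t, as_target_schema(t), method="similarity_flooding")
        for r in ranked:
            assert r.candidates[0][0] == r.source_attribute

    def test_matches_independent_fixpoint_oracle(self):
        src = validate_table({"gender": ["f"], "age": ["1"], "site": ["kidney"]})
        tgt = validate_table({"gendre": ["f"], "age_years": ["2"], "location": ["lung"]})
        eps, max_iter = 1e-4, 100

        # independent PCG construction + power iteration
        def graph(cols):
            edges = []
            for name, kind in cols:
                edges.append((("schema", ""), ("col", name), "column"))
                edges.append((("col", name), ("kind", kind), "kind"))
            return edges

        g1 = graph([(c.name, c.kind) for c in src.columns])
        g2 = graph([(c.name, c.kind) for c in tgt.columns])
        pcg = [((a1, b1), (a2, b2))
               for a1, a2, l1 in g1 for b1, b2, l2 in g2 if l1 == l2]
        nodes = sorted({p for e in pcg for p in e})
        idx = {p: i for i, p in enumerate(nodes)}
        out_deg, in_deg = {}, {}
        for p, q in pcg:
            out_deg[p] = out_deg.get(p, 0) + 1
            in_deg[q] = in_deg.get(q, 0) + 1
        T = np.zeros((len(nodes), len(nodes)))
        for p, q in pcg:
            T[idx[q], idx[p]] += 1 / out_deg[p]
            T[idx[p], idx[q]] += 1 / in_deg[q]
        sigma = np.zeros(len(nodes))
        for p in nodes:
            (ca, na), (cb, nb) = p
            if ca == "kind":
                sigma[idx[p]] = 1.0 if na == nb else 0.0
            elif ca == "schema":
                sigma[idx[p]] = 1.0
            else:
                sigma[idx[p]] = composite_name_score(na, nb)
        for _ in range(max_iter):
            nxt = sigma + T @ sigma
            nxt /= nxt.max()
            if np.abs(nxt - sigma).max() < eps:
                sigma = nxt
                break
            sigma = nxt

        scores = similarity_flooding_scores(src, as_target_schema(tgt), eps=eps,
                                            max_iter=max_iter)
        for s in src.column_names:
            for t in tgt.column_names:
                assert scores[s][t] == pytest.approx(
                    sigma[idx[(("col", s), ("col", t))]], abs=1e-8)

    def test_infinite_eps_returns_name_ranking(self):
        src = validate_table({"gender": ["f"], "age": ["1"]})
        tgt = validate_table({"age": ["2"], "gender": ["m"]})
        flooded = rank_schema_matches(src, as_target_schema(tgt),
                                      MatcherConfig("similarity_flooding",
                                                    method_args={"eps": math.inf}))
        named = rank_schema_matches(src, as_target_schema(tgt), method="composite_name")
        assert [[c for c, _ in r.candidates] for r in flooded] == [
            [c for c, _ in r.candidates] for r in named]

    def test_nonconvergence_warns(self):
        src = validate_table({"a": ["1"], "b": ["2"]})
        tgt = validate_table({"c": ["1"], "d": ["2"]})
        with pytest.warns(UserWarning):
            similarity_flooding_scores(src, as_target_schema(tgt), eps=0.0, max_iter=2)


# ---------------------------------------------------------------------------
# distribution based


class TestDistributionBased:
    def test_identical_numeric_columns_score_one(self):
        src = validate_table({"x": ["1", "2", "3"]})
        tgt = validate_table({"y": ["1", "2", "3"]})
        ranked = rank_schema_matches(src, as_target_schema(tgt), method="distribution_based")
        assert ranked[0].candidates[0] == ("y", 1.0)

    def test_matches_cumulative_difference_oracle(self):
        a, b = [0, 0, 1, 1], [0, 1, 1, 1]
        assert emd_similarity(a, b) == pytest.approx(1 - emd_oracle(a, b))

    def test_random_histograms_match_oracle(self):
        rng = random.Random(42)
        for _ in range(100):
            a = [rng.randint(0, 9) for _ in range(rng.randint(2, 20))]
            b = [rng.randint(0, 9) for _ in range(rng.randint(2, 20))]
            lo, hi = min(a + b), max(a + b)
            if hi == lo:
                assert emd_similarity(a, b) == 1.0
                continue
            sa = [(x - lo) / (hi - lo) for x in a]
            sb = [(x - lo) / (hi - lo) for x in b]
            assert emd_similarity(a, b) == pytest.approx(1 - emd_oracle(sa, sb))

    def test_disjoint_categorical_sets_score_zero(self):
        assert total_variation_similarity(["a", "b"], ["c", "d"]) == 0.0

    def test_symmetry_and_identity(self):
        a, b = ["x", "x", "y"], ["x", "y", "y"]
        assert total_variation_similarity(a, b) == total_variation_similarity(b, a)
        assert total_variation_similarity(a, a) == 1.0

    def test_kind_mismatch_scores_zero(self):
        src = validate_table({"n": ["1", "2", "3"]})
        tgt = validate_table({"t": ["a", "b", "c"]})
        ranked = rank_schema_matches(src, as_target_schema(tgt), method="distribution_based")
        assert ranked[0].candidates[0][1] == 0.0

    def test_insufficient_data_warns_and_scores_zero(self):
        src = validate_table({"n": ["1"]})
        tgt = validate_table({"m": ["1", "2"]})
        with pytest.warns(InsufficientDataWarning):
            ranked = rank_schema_matches(src, as_target_schema(tgt),
                                         method="distribution_based")
        assert ranked[0].candidates[0][1] == 0.0


# ---------------------------------------------------------------------------
# fuzzy Jaccard


class TestFuzzyJaccard:
    def test_theta_zero_equals_exact_jaccard(self):
        rng = random.Random(7)
        alphabet = ["aa", "ab", "ba", "bb", "abc", "xyz", "x", ""]
        for _ in range(100):
            sa = rng.sample(alphabet, rng.randint(1, 6))
            sb = rng.sample(alphabet, rng.randint(1, 6))
            exact = len(set(sa) & set(sb)) / len(set(sa) | set(sb))
            assert fuzzy_jaccard(sa, sb, theta=0.0) == pytest.approx(exact)

    def test_cnv_pair_fully_matches_at_half_threshold(self):
        # distances verified against the DP oracle
        assert dp_levenshtein("CNV_LOW", "CNV_L") / 7 <= 0.5
        assert dp_levenshtein("CNV_HIGH", "CNV_H") / 8 <= 0.5
        sim = fuzzy_jaccard(["CNV_LOW", "CNV_HIGH"], ["CNV_L", "CNV_H"], theta=0.5)
        assert sim == 1.0

    def test_greedy_pairing_bounded_by_optimal(self):
        rng = random.Random(3)
        words = ["cat", "cart", "car", "dog", "dig", "fish", "dish", "x", "xy"]
        agreements = 0
        for _ in range(60):
            sa = rng.sample(words, rng.randint(1, 5))
            sb = rng.sample(words, rng.randint(1, 5))
            theta = rng.choice([0.25, 0.4, 0.6])
            optimal = brute_force_fuzzy_intersection(sa, sb, theta)
            sim = fuzzy_jaccard(sa, sb, theta)
            greedy = round(sim * (len(sa) + len(sb)) / (1 + sim))
            assert greedy <= optimal
            agreements += greedy == optimal
        assert agreements >= 55  # greedy rarely falls short of optimal here

    def test_monotone_in_theta(self):
        sa, sb = ["alpha", "beta", "gamma"], ["alpa", "betta", "delta"]
        sims = [fuzzy_jaccard(sa, sb, th) for th in (0.0, 0.2, 0.4, 0.8, 1.0)]
        assert sims == sorted(sims)


# ---------------------------------------------------------------------------
# embedding + bipartite reranking


class TestEmbedColumn:
    def test_serialization_scheme(self):
        t = validate_table({"bmi": ["22.1", "30.4"]})
        assert serialize_column(t.column("bmi")) == "name: bmi. values: 22.1, 30.4"

    def test_empty_column_boundary(self):
        t = validate_table({"bmi": []})
        assert serialize_column(t.column("bmi")) == "name: bmi. values: "

    def test_value_cap_at_fifteen(self):
        t = validate_table({"c": [str(i) for i in range(40)]})
        text = serialize_column(t.column("c"))
        assert text.count(",") == 14

    def test_identical_columns_cosine_one(self):
        t = validate_table({"a": ["x", "y"]})
        u = validate_table({"a": ["x", "y"]})
        va = embed_column(t.column("a"))
        vb = embed_column(u.column("a"))
        assert float(va @ vb) == pytest.approx(1.0)

    def test_unit_norm(self):
        t = validate_table({"a": ["x"]})
        assert np.linalg.norm(embed_column(t.column("a"))) == pytest.approx(1.0)


class TestBipartiteRerank:
    def test_identity_matrix_gives_diagonal(self):
        assert bipartite_rerank(np.eye(4)) == [0, 1, 2, 3]

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        levels = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        for _ in range(100):
            shape = rng.integers(1, 6, size=2)
            m = levels[rng.integers(0, 5, size=tuple(shape))]
            assignment = bipartite_rerank(m)
            total = sum(m[i, j] for i, j in enumerate(assignment) if j is not None)
            assert total == pytest.approx(brute_force_assignment_value(m))

    def test_dominant_column_assigned_once(self):
        m = np.array([[0.9, 0.1, 0.1], [0.8, 0.1, 0.1], [0.7, 0.1, 0.1]])
        assignment = bipartite_rerank(m)
        assert sorted(a for a in assignment if a is not None) == [0, 1, 2]
        assert len(set(assignment)) == 3  # one-to-one

    def test_wide_matrix_leaves_no_row_unassigned(self):
        m = np.array([[0.2, 0.9, 0.4, 0.3]])
        assert bipartite_rerank(m) == [1]


class TestMagneto:
    def test_self_match_perfect(self, clean_fixture_pair):
        _, target, _ = clean_fixture_pair
        matches = match_schema(target, as_target_schema(target), method="magneto_zs_bp")
        assert all(m.source_attribute == m.target_attribute for m in matches)

    def test_perturbed_fixture_accuracy(self):
        from tablign.fixtures import FixtureSpec, generate_fixture, schema_accuracy
        src, tgt, truth = generate_fixture(
            FixtureSpec(seed=2, perturbations=frozenset({"case_change", "snake_camel"})))
        matches = match_schema(src, as_target_schema(tgt), method="magneto_zs_bp")
        assert schema_accuracy(matches, truth) >= 0.9

    def test_competing_sources_resolved_one_to_one(self):
        src = validate_table({"gender": ["female", "male"], "gender_code": ["female", "male"]})
        tgt = validate_table({"gender": ["female", "male"], "sex": ["female", "male"]})
        matches = match_schema(src, as_target_schema(tgt), method="magneto_zs_bp")
        winners = [m.target_attribute for m in matches]
        assert len(set(winners)) == len(winners)


# ---------------------------------------------------------------------------
# meta matchers


class TestTwoPhase:
    def test_same_method_both_phases_is_idempotent(self, clean_fixture_pair):
        _, target, _ = clean_fixture_pair
        schema = as_target_schema(target)
        both = match_schema(target, schema, method="two_phase",
                            phase1="composite_name", phase2="composite_name")
        single = match_schema(target, schema, method="composite_name")
        assert [(m.source_attribute, m.target_attribute) for m in both] == [
            (m.source_attribute, m.target_attribute) for m in single]

    def test_value_agreement_overrides_misleading_names(self):
        # names point to 'status', values agree with 'cnv_class'
        src = validate_table({"status": ["CNV_L", "CNV_H", "CNV_L"]})
        tgt = validate_table({
            "status": ["alive", "dead", "alive"],
            "cnv_class": ["CNV_L", "CNV_H", "CNV_H"],
        })
        matches = match_schema(src, as_target_schema(tgt), method="two_phase",
                               phase1="composite_name", phase2="jaccard_distance",
                               prune_k=5)
        assert matches[0].target_attribute == "cnv_class"

    def test_prune_to_one_makes_phase2_irrelevant(self):
        src = validate_table({"gender": ["f"]})
        tgt = validate_table({"gender": ["x"], "gondor": ["f"]})
        matches = match_schema(src, as_target_schema(tgt), method="two_phase",
                               phase1="composite_name", phase2="jaccard_distance",
                               prune_k=1)
        assert matches[0].target_attribute == "gender"


class TestMaxValSim:
    def test_value_backed_candidate_outranks_name_sibling(self, geo_source, geo_target_table):
        ranked = rank_schema_matches(geo_source, as_target_schema(geo_target_table),
                                     MatcherConfig("max_val_sim", top_k=3))
        by_src = {r.source_attribute: r for r in ranked}
        assert by_src["Assay Type"].candidates[0][0] == "Assay"
        assert by_src["Organism"].candidates[0][0] == "Species"

    def test_identical_value_set_scores_one(self):
        src = validate_table({"col_a": ["x", "y"]})
        tgt = validate_table({"other": ["x", "y"]})
        ranked = rank_schema_matches(src, as_target_schema(tgt), method="max_val_sim")
        assert ranked[0].candidates[0][1] == pytest.approx(1.0)

    def test_mean_of_best_similarity_oracle(self):
        from tablign.value_matching import value_tfidf
        src = validate_table({"c": ["alpha", "beta"]})
        tgt = validate_table({"t1": ["alpha", "gamma"], "t2": ["delta", "beta"]})
        ranked = rank_schema_matches(src, as_target_schema(tgt), method="max_val_sim")
        scores = dict(ranked[0].candidates)
        for cand, cand_vals in [("t1", ["alpha", "gamma"]), ("t2", ["delta", "beta"])]:
            sim = value_tfidf(["alpha", "beta"], cand_vals)
            expected = float(np.mean(sim.max(axis=1)))
            assert scores[cand] == pytest.approx(expected, abs=1e-6)


class _RaisingAdapter:
    name = "boom"
    model_id = "boom"

    def select(self, query, candidates):
        raise AdapterError("backend unavailable")


class _OutOfSetThenValidAdapter:
    """First answer is a hallucinated name; later answers are honest."""

    name = "flaky"
    model_id = "flaky"

    def __init__(self):
        self.calls = 0

    def select(self, query, candidates):
        self.calls += 1
        if self.calls == 1:
            return Selection("not_a_real_attribute", 0.9)
        from tablign.backends import mock_select
        return mock_select(candidates, query)


class TestLlmMatcher:
    def test_mock_adapter_matches_clinical_names(self, rcc_source, toy_cdm_schema):
        matches = match_schema(rcc_source, toy_cdm_schema, method="llm")
        by_src = {m.source_attribute: m.target_attribute for m in matches}
        assert by_src["Gender"] == "gender"

    def test_adapter_failure_falls_back_to_name_matching(self, rcc_source, toy_cdm_schema, caplog):
        with caplog.at_level("WARNING"):
            matches = match_schema(rcc_source, toy_cdm_schema, method="llm",
                                   adapter=_RaisingAdapter())
        by_src = {m.source_attribute: m.target_attribute for m in matches}
        assert by_src["Gender"] == "gender"
        assert any("falling back" in r.message for r in caplog.records)

    def test_out_of_set_answer_rejected(self, toy_cdm_schema):
        src = validate_table({"Gender": ["Female", "Male"]})
        matches = match_schema(src, toy_cdm_schema, method="llm",
                               adapter=_OutOfSetThenValidAdapter())
        assert matches[0].target_attribute == "gender"


# ---------------------------------------------------------------------------
# dispatch contract


class TestDispatch:
    def test_unknown_method_rejected(self):
        with pytest.raises(UnknownMethodError):
            MatcherConfig("cupid")

    def test_empty_target_schema_rejected(self, rcc_source):
        with pytest.raises(EmptySchemaError):
            match_schema(rcc_source, TargetSchema(attributes=[]))

    def test_one_match_per_source_column(self, rcc_source, toy_cdm_schema):
        matches = match_schema(rcc_source, toy_cdm_schema, method="composite_name")
        assert [m.source_attribute for m in matches] == rcc_source.column_names

    def test_forced_single_candidate(self):
        src = validate_table({"a": ["1"], "b": ["2"], "c": ["3"], "d": ["4"]})
        tgt = validate_table({"only": ["1"]})
        matches = match_schema(src, as_target_schema(tgt), method="composite_name")
        assert [m.target_attribute for m in matches] == ["only"] * 4

    def test_top_k_clamps_to_target_size(self, rcc_source):
        tgt = validate_table({"x": ["1"], "y": ["2"]})
        ranked = rank_schema_matches(rcc_source, as_target_schema(tgt),
                                     MatcherConfig("composite_name", top_k=10))
        assert all(len(r.candidates) == 2 for r in ranked)

    def test_top_one_matches_match_schema(self, rcc_source, toy_cdm_schema):
        ranked = rank_schema_matches(rcc_source, toy_cdm_schema,
                                     MatcherConfig("composite_name", top_k=1))
        top1 = [(r.source_attribute, r.candidates[0][0]) for r in ranked]
        matches = match_schema(rcc_source, toy_cdm_schema, method="composite_name")
        assert top1 == [(m.source_attribute, m.target_attribute) for m in matches]

    @pytest.mark.parametrize("method", SCHEMA_METHODS)
    def test_similarities_in_unit_interval(self, method, perturbed_fixture_pair):
        src, tgt, _ = perturbed_fixture_pair
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = rank_schema_matches(src, as_target_schema(tgt),
                                         MatcherConfig(method, top_k=3))
        for r in ranked:
            for _, sim in r.candidates:
                assert 0.0 <= sim <= 1.0

    @pytest.mark.parametrize("method", ["composite_name", "jaccard_distance",
                                        "distribution_based", "magneto_zs_bp"])
    def test_row_order_invariance(self, method):
        cells = {"gender": ["female", "male", "female", "male"],
                 "age": ["1", "2", "3", "4"]}
        shuffled = {"gender": ["male", "female", "male", "female"],
                    "age": ["4", "2", "3", "1"]}
        tgt = as_target_schema(validate_table({"gender": ["female", "male"],
                                               "age_years": ["2", "3"]}))
        a = match_schema(validate_table(cells), tgt, method=method)
        b = match_schema(validate_table(shuffled), tgt, method=method)
        assert [(m.source_attribute, m.target_attribute) for m in a] == [
            (m.source_attribute, m.target_attribute) for m in b]
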