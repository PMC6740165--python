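import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saltc import (
    Category,
    cosine_similarity,
    euclidean_distance,
    map_corpus,
    match_value,
    vectorize,
)
from saltc._scheme import SCHEME


class TestVectorize:
    def test_counts_named_positions(self):
        v = vectorize("neg")
        nonzero = {SCHEME[i]: int(c) for i, c in enumerate(v) if c}
        assert nonzero == {"n": 1, "e": 1, "g": 1}

    def test_out_of_scheme_characters_are_transparent(self):
        assert (vectorize("+++ 6") == vectorize("+++")).all()
        assert int(vectorize("+++ 6").sum()) == 3

    def test_empty_and_junk_give_zero_vector(self):
        assert not vectorize("").any()
        assert not vectorize("**** (2.00) ??").any()

    def test_binary_mode_records_presence(self):
        assert int(vectorize("eee", binary=True).sum()) == 1

    @given(st.text(alphabet=SCHEME + " 0123456789*^", max_size=20),
           st.text(alphabet=SCHEME + " 0123456789*^", max_size=20))
    @settings(derandomize=True, max_examples=200)
    def test_concatenation_additivity(self, s, t):
        assert (vectorize(s + t) == vectorize(s) + vectorize(t)).all()


class TestSimilarities:
    def test_cosine_self_similarity(self):
        assert cosine_similarity(vectorize("neg"), vectorize("neg")) == 1.0

    def test_anagrams_are_identical_vectors(self):
        assert cosine_similarity(vectorize("starw"), vectorize("straw")) == 1.0

    def test_cosine_hand_value(self):
        # dot(negative, neg-) = n:1 + e:2 + g:1 = 4; norms sqrt(10) and 2
        got = cosine_similarity(vectorize("negative"), vectorize("neg-"))
        assert got == pytest.approx(4 / (2 * math.sqrt(10)))

    def test_cosine_undefined_for_zero_vector(self):
        with pytest.raises(ValueError):
            cosine_similarity(vectorize("****"), vectorize("neg"))

    def test_euclidean_identity_of_indiscernibles(self):
        assert euclidean_distance(vectorize("+++ 6"), vectorize("+++")) == 0.0
        assert euclidean_distance(vectorize("+++ 6"), vectorize("++++")) == 1.0
        assert euclidean_distance(vectorize("ab"), vectorize("ab")) == 0.0

    @given(st.text(alphabet="negpos+-", min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=200)
    def test_permuting_characters_never_changes_scores(self, s, rnd):
        chars = list(s)
        rnd.shuffle(chars)
        assert (vectorize("".join(chars)) == vectorize(s)).all()

    @given(st.text(alphabet="negpos+-", min_size=1, max_size=8),
           st.integers(min_value=2, max_value=4))
    @settings(derandomize=True, max_examples=100)
    def test_cosine_is_scale_invariant(self, s, k):
        ref = vectorize("posi")
        assert cosine_similarity(vectorize(s * k), ref) == pytest.approx(
            cosine_similarity(vectorize(s), ref), abs=1e-12
        )


class TestMatchValue:
    def test_hybrid_resolves_collinear_grade_tie(self, registry):
        r = match_value("+++ 6", Category.URINE_DIPSTICK, registry, "hybrid")
        assert r.best.label == "+++"
        assert r.cosine_score == pytest.approx(1.0)
        assert r.euclidean_distance == 0.0

    def test_concentration_prefixed_trace(self, registry):
        r = match_value("10 tr", Category.URINE_DIPSTICK, registry)
        assert r.best.label == "trace"
        assert r.cosine_score == pytest.approx(1.0)

    def test_junk_is_unmapped_with_zero_vector_reason(self, registry):
        r = match_value("****", Category.URINE_DIPSTICK, registry)
        assert r.unmapped and r.best is None
        assert "zero vector" in r.reason

    def test_abbreviated_negative(self, registry):
        r = match_value("neg -", Category.PRESENCE_FINDING, registry)
        assert r.best.label == "negative"
        assert r.cosine_score == pytest.approx(1.0)

    def test_full_tie_goes_to_manual_review(self, registry):
        # "rh" is equidistant from rh+ and rh- at equal cosine
        r = match_value("rh", Category.BLOOD_TYPE, registry, "hybrid")
        assert r.unmapped and r.tie_after_hybrid

    def test_hybrid_equals_cosine_when_argmax_unique(self, registry):
        for text in ("strow", "negative", "w-react", "posi +"):
            for cat in (Category.URINE_COLOR, Category.PRESENCE_FINDING,
                        Category.PATHOGENESIS):
                h = match_value(text, cat, registry, "hybrid")
                c = match_value(text, cat, registry, "cosine")
                if not h.tie_after_hybrid:
                    assert h.best == c.best

    def test_parameter_validation(self, registry):
        with pytest.raises(ValueError):
            match_value("x", Category.URINE_COLOR, registry, "jaccard")
        with pytest.raises(ValueError):
            match_value("x", Category.UNCLASSIFIED, registry)

    def test_min_cosine_floor_routes_to_review(self, registry):
        r = match_value("g", Category.URINE_DIPSTICK, registry, min_cosine=0.8)
        assert r.unmapped and "below floor" in r.reason


class TestMapCorpus:
    def test_blood_type_corpus_end_to_end(self, registry):
        records = [("abo group", v) for v in ["a", "b", "o", "ab"] * 3]
        result = map_corpus(records, registry)
        assert result.assignments["abo group"].category is Category.BLOOD_TYPE
        assert {r.mapped_label for r in result.records} == {"a", "b", "o", "ab"}
        assert result.summary["n_unmapped"] == 0

    def test_empty_corpus(self, registry):
        result = map_corpus([], registry)
        assert result.records == ()
        assert result.summary["n_records"] == 0
        assert result.summary["n_tests"] == 0

    def test_dipstick_grades_carry_snomed(self, registry):
        result = map_corpus([("urine glucose", "4+")] * 6, registry)
        assert all(r.mapped_label == "++++" for r in result.records)
        assert all(r.snomed_id == "260350009" for r in result.records)

    def test_unclassified_tests_pass_through_unmapped(self, registry):
        result = map_corpus([("mystery test", "zzz"), ("mystery test", "qqq")], registry)
        assert all(r.unmapped and r.reason == "unclassified test" for r in result.records)
        assert result.summary["n_unclassified_tests"] == 1

    def test_rh_correction_applies_in_blood_context(self, registry):
        result = map_corpus([("rh type", "+"), ("rh type", "-")], registry)
        assert [r.mapped_label for r in result.records] == ["rh+", "rh-"]

    def test_coverage_cutoff_routes_tail_to_review(self, registry):
        records = [("urine color", "straw")] * 96 + [("urine color", "steaw")] * 4
        full = map_corpus(records, registry)
        assert all(not r.unmapped for r in full.records)
        cut = map_corpus(records, registry, coverage_cutoff=0.95)
        tail = [r for r in cut.records if r.clean_value == "steaw"]
        assert all(r.unmapped and "coverage cutoff" in r.reason for r in tail)

    def test_group_blood_variants_folds_cis_ab(self, registry):
        records = [("abo group", v) for v in ("a", "b", "o", "cis-ab")]
        plain = map_corpus(records, registry)
        assert plain.records[-1].mapped_label == "cis-ab"
        folded = map_corpus(records, registry, group_blood_variants=True)
        assert folded.records[-1].mapped_label == "ab"


def test_levenshtein_oracle_agrees_on_printed_typos(registry):
    """Sanity cross-check with an edit-distance nearest-neighbor oracle."""
    edlib = pytest.importorskip("edlib")
    colors = [v.label for v in registry.values_for(Category.URINE_COLOR)]
    for variant in ("strow", "steaw", "traw"):
        by_lev = min(colors, key=lambda c: edlib.align(variant, c)["editDistance"])
        ours = match_value(variant, Category.URINE_COLOR, registry).best.label
        assert ours == by_lev == "straw"
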