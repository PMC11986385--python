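"""Normalization, similarity, alignment, and concept linking."""

import pytest
from hypothesis import given, strategies as st

from sepsiskg import (
    ConfigurationError,
    EntityMention,
    FusionConfig,
    align_entities,
    combined_similarity,
    jaccard_similarity,
    link_concept,
    load_concept_dictionary,
    normalize_name,
)
from sepsiskg.fusion import NormalizationRules


def M(surface, etype="Diseases", doc="d1"):
    return EntityMention(doc_id=doc, surface=surface, etype=etype)


# -- normalization ----------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Heart Failure", "heart failure"),
        ("HF", "heart failure"),
        ("sepsis.", "sepsis"),
        ("  Septic   Shock ", "septic shock"),
        ("C-reactive protein", "c reactive protein"),
        ("CRP", "c reactive protein"),
    ],
)
def test_normalize_examples(raw, expected):
    assert normalize_name(raw) == expected


@given(st.text(max_size=40))
def test_normalize_is_idempotent(raw):
    once = normalize_name(raw)
    assert normalize_name(once) == once


def test_rules_order_abbreviations_after_punctuation():
    # "HF." only expands because case and punctuation are handled first
    assert normalize_name("HF.") == "heart failure"


def test_unstable_abbreviation_map_rejected():
    with pytest.raises(ValueError, match="idempotent"):
        NormalizationRules(abbreviation_map={"hf": "hf syndrome"})


# -- similarity -------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("septic shock", "septic shock", 1.0),
        ("fever", "bradycardia", 0.0),
        ("septic shock", "septic shock syndrome", 2 / 3),
        ("", "", 1.0),
    ],
)
def test_jaccard_examples(a, b, expected):
    assert jaccard_similarity(a, b) == pytest.approx(expected)


words = st.lists(
    st.sampled_from([f"tok{i}" for i in range(12)]), min_size=0, max_size=8
)


@given(words, words)
def test_jaccard_matches_brute_force_set_arithmetic(ta, tb):
    a, b = " ".join(ta), " ".join(tb)
    sa, sb = set(ta), set(tb)
    expected = 1.0 if not (sa | sb) else len(sa & sb) / len(sa | sb)
    assert jaccard_similarity(a, b) == pytest.approx(expected)


@given(st.text(max_size=30), st.text(max_size=30))
def test_combined_similarity_symmetric_and_bounded(a, b):
    cfg = FusionConfig()
    s = combined_similarity(a, b, cfg)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(combined_similarity(b, a, cfg))


def test_combined_modes():
    class FixedEmbedder:
        def __init__(self, mapping):
            self.mapping = mapping

        def embed(self, text):
            import numpy as np

            return np.array(self.mapping[text], dtype=float)

    # jaccard("a b c d e", "a b x y z") = 2/8; orthogonal-ish embeddings
    a, b = "a b c d e", "a b x y z"
    emb = FixedEmbedder({a: [1.0, 0.0], b: [0.8, 0.6]})  # cos=0.8 -> 0.9
    jac = jaccard_similarity(a, b)
    assert jac == pytest.approx(0.25)
    assert combined_similarity(a, b, FusionConfig(similarity_mode="jaccard")) == jac
    assert combined_similarity(
        a, b, FusionConfig(similarity_mode="embedding"), emb
    ) == pytest.approx(0.9)
    assert combined_similarity(
        a, b, FusionConfig(similarity_mode="max"), emb
    ) == pytest.approx(0.9)
    assert combined_similarity(
        a, b, FusionConfig(similarity_mode="mean"), emb
    ) == pytest.approx((0.25 + 0.9) / 2)


def test_identical_strings_score_one_in_every_mode():
    for mode in ("jaccard", "embedding", "max", "mean"):
        cfg = FusionConfig(similarity_mode=mode)
        assert combined_similarity("septic shock", "Septic Shock.", cfg) == 1.0


def test_missing_embedder_is_configuration_error():
    cfg = FusionConfig(similarity_mode="embedding", embedder_id="bio-bert-xl")
    with pytest.raises(ConfigurationError):
        combined_similarity("a", "b", cfg)


# -- alignment --------------------------------------------------------------


def test_abbreviation_variants_merge():
    res = align_entities([M("heart failure"), M("HF", doc="d2")])
    assert len(res.clusters) == 1
    assert res.clusters[0].canonical_surface in {"heart failure", "HF"}
    assert res.clusters[0].normalized_surface == "heart failure"


def test_entity_types_never_merge():
    res = align_entities([M("heart failure", "Diseases"), M("heart failure", "Symptoms")])
    assert len(res.clusters) == 2
    assert {c.etype for c in res.clusters} == {"Diseases", "Symptoms"}


def test_singleton_cluster():
    res = align_entities([M("sepsis")])
    assert len(res.clusters) == 1 and res.review_queue == []


def test_canonical_surface_is_modal_with_lexicographic_tie_break():
    res = align_entities([M("HF"), M("HF", doc="d2"), M("heart failure", doc="d3")])
    assert res.clusters[0].canonical_surface == "HF"
    tied = align_entities([M("HF"), M("heart failure", doc="d2")])
    assert tied.clusters[0].canonical_surface == "HF"  # lexicographic


def test_alignment_is_deterministic(gold50, perfect_extraction):
    mentions = [m for r in perfect_extraction for m in r.mentions]
    r1 = align_entities(mentions)
    r2 = align_entities(mentions)
    key = lambda r: [
        (c.etype, c.canonical_surface, sorted(m.surface for m in c.mentions))
        for c in r.clusters
    ]
    assert key(r1) == key(r2)
    assert [p.model_dump() for p in r1.review_queue] == [
        p.model_dump() for p in r2.review_queue
    ]


def test_alignment_partition_and_review_band(gold50, perfect_extraction):
    mentions = [m for r in perfect_extraction for m in r.mentions]
    cfg = FusionConfig()
    res = align_entities(mentions, cfg)
    res.assert_partition(mentions)
    for pair in res.review_queue:
        assert cfg.threshold - cfg.review_band <= pair.score < cfg.threshold


def test_cluster_count_monotone_in_threshold(gold50, perfect_extraction):
    mentions = [m for r in perfect_extraction for m in r.mentions]
    prev = 0
    for i in range(21):
        tau = i * 0.05
        n = len(align_entities(mentions, FusionConfig(threshold=tau)).clusters)
        assert n >= prev
        prev = n


# -- concept linking --------------------------------------------------------


def test_link_hypertension_to_standard_concept():
    concepts = load_concept_dictionary()
    c = link_concept("hypertension", concepts)
    assert c is not None
    assert c.concept_id == "C0020538"
    assert c.canonical_name == "Hypertensive disease"


def test_link_by_synonym_and_abbreviation():
    concepts = load_concept_dictionary()
    assert link_concept("HF", concepts).concept_id == "C9000004"
    assert link_concept("pyrexia", concepts).canonical_name == "Fever"


def test_below_threshold_surface_retained():
    concepts = load_concept_dictionary()
    assert link_concept("qi deficiency pattern", concepts) is None


def test_empty_dictionary_yields_no_link():
    assert link_concept("sepsis", []) is None
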