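"""Entity/triple scoring and generation metrics."""

from functools import lru_cache
from random import Random

import pytest

from sepsiskg import (
    EntityMention,
    Triple,
    bleu_score,
    evaluate_generation,
    match_entities,
    rouge_scores,
    score_triples,
)
from sepsiskg.evaluation import tokenize_for_eval


def M(surface, etype="Diseases", doc="d1", span=None):
    return EntityMention(doc_id=doc, surface=surface, etype=etype, span=span)


def T(s, r, o, doc="d1"):
    return Triple(subject=s, relation=r, object=o, doc_id=doc)


# -- entity matching --------------------------------------------------------


def test_identical_sets_score_perfectly():
    gold = [M("sepsis"), M("fever", "Symptoms"), M("pct", "Biomarkers"), M("aki")]
    rep = match_entities(gold, list(gold))
    m = rep.micro
    assert (m.tp, m.fp, m.fn) == (4, 0, 0) and m.f1 == 1.0


def test_hand_counted_partial_match():
    # 4 gold, 3 predictions of which 2 correct: P=2/3, R=1/2, F1=4/7
    gold = [M("sepsis"), M("pneumonia"), M("fever", "Symptoms"), M("aki")]
    pred = [M("sepsis"), M("fever", "Symptoms"), M("wrong")]
    m = match_entities(gold, pred).micro
    assert (m.tp, m.fp, m.fn) == (2, 1, 2)
    assert m.precision == pytest.approx(2 / 3)
    assert m.recall == pytest.approx(1 / 2)
    assert m.f1 == pytest.approx(4 / 7)


def test_correct_span_wrong_type_is_fp_plus_fn():
    gold = [M("fever", "Symptoms", span=(0, 5))]
    pred = [M("fever", "Diseases", span=(0, 5))]
    rep = match_entities(gold, pred, mode="strict")
    assert rep.micro.tp == 0 and rep.micro.fp == 1 and rep.micro.fn == 1
    assert rep.per_type["Symptoms"].fn == 1 and rep.per_type["Diseases"].fp == 1


def test_strict_requires_exact_span_relaxed_accepts_overlap():
    gold = [M("septic shock", span=(10, 22))]
    pred = [M("shock", span=(17, 22))]
    assert match_entities(gold, pred, mode="strict").micro.tp == 0
    assert match_entities(gold, pred, mode="relaxed").micro.tp == 1


def test_relaxed_surface_containment_without_spans():
    gold = [M("septic shock")]
    pred = [M("shock")]
    assert match_entities(gold, pred, mode="strict").micro.tp == 0
    assert match_entities(gold, pred, mode="relaxed").micro.tp == 1


def test_mixed_span_protocol_rejected():
    gold = [M("a", span=(0, 1)), M("b")]
    with pytest.raises(ValueError, match="ambiguous"):
        match_entities(gold, [])


def _random_case(rng):
    pool = ["a", "a b", "b", "b c", "c", "c d e", "d"]
    types = ["Diseases", "Symptoms"]
    mk = lambda: [
        M(rng.choice(pool), rng.choice(types), doc=f"d{rng.randrange(2)}")
        for _ in range(rng.randrange(0, 6))
    ]
    return mk(), mk()


def test_greedy_matches_optimal_assignment_almost_always():
    """Greedy vs maximum-cardinality assignment on 1,000 random small cases.

    Under strict matching the match relation is an equivalence, so greedy is
    provably optimal; under relaxed containment greedy may fall short, but
    only in the documented direction (greedy TP <= optimal TP) and rarely.
    """
    rng = Random(20240901)
    disagreements = 0
    for _ in range(1000):
        gold, pred = _random_case(rng)
        for mode in ("strict", "relaxed"):
            g = match_entities(gold, pred, mode=mode, assignment="greedy").micro
            o = match_entities(gold, pred, mode=mode, assignment="optimal").micro
            assert g.tp <= o.tp
            if mode == "strict":
                assert g.tp == o.tp
            elif g.tp != o.tp:
                disagreements += 1
    assert disagreements <= 10  # <=1% of 1,000 relaxed comparisons


def test_relaxed_tp_never_below_strict(gold50, perfect_extraction):
    gold = [m.model_copy(update={"span": None}) for m in gold50.gold_mentions]
    pred = [
        m.model_copy(update={"span": None})
        for r in perfect_extraction for m in r.mentions
    ]
    strict = match_entities(gold, pred, mode="strict").micro
    relaxed = match_entities(gold, pred, mode="relaxed").micro
    assert relaxed.tp >= strict.tp


# -- triple scoring ---------------------------------------------------------


def test_triple_identity_and_partial():
    gold = [T("sepsis", "complications", "pneumonia"),
            T("sepsis", "has symptom", "fever")]
    assert score_triples(gold, list(gold)).micro.f1 == 1.0
    pred = [T("sepsis", "complications", "pneumonia"),
            T("sepsis", "has symptom", "chills")]
    m = score_triples(gold, pred).micro
    assert m.precision == 0.5 and m.recall == 0.5 and m.f1 == 0.5


def test_no_predictions_scores_zero_by_convention():
    gold = [T("sepsis", "complications", "pneumonia")]
    m = score_triples(gold, []).micro
    assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0


def test_triple_match_uses_normalized_surfaces_and_doc():
    gold = [T("Heart Failure", "complications", "pneumonia")]
    assert score_triples(gold, [T("HF", "complications", "pneumonia.")]).micro.f1 == 1.0
    assert score_triples(gold, [T("HF", "complications", "pneumonia", doc="d2")]).micro.tp == 0


def test_f1_between_min_and_max_of_p_and_r():
    gold = [T("a", "complications", f"b{i}") for i in range(5)]
    pred = gold[:2] + [T("a", "complications", "zz")]
    m = score_triples(gold, pred).micro
    assert min(m.precision, m.recall) <= m.f1 <= max(m.precision, m.recall)


# -- BLEU -------------------------------------------------------------------


def test_bleu_identity_and_disjoint():
    assert bleu_score("the patient has sepsis", ["the patient has sepsis"]) == 1.0
    assert bleu_score("alpha beta", ["gamma delta"], smooth=False) == 0.0


def test_bleu_hand_counted_unigram():
    # "the cat sat" vs "the cat ran": 2 of 3 unigrams match, equal lengths
    assert bleu_score("the cat sat", ["the cat ran"], max_n=1, smooth=False) == (
        pytest.approx(2 / 3)
    )


def test_bleu_brevity_penalty():
    import math

    # candidate 2 tokens vs reference 4: BP = exp(1 - 4/2), unigram p = 1
    got = bleu_score("a b", ["a b c d"], max_n=1, smooth=False)
    assert got == pytest.approx(math.exp(1 - 2.0))


def test_bleu_empty_candidate_zero():
    assert bleu_score("", ["reference"]) == 0.0


def test_bleu_smoothing_rescues_short_candidates():
    # 4-gram BLEU on a 3-token candidate is 0 unsmoothed, positive smoothed
    assert bleu_score("sepsis causes fever", ["sepsis causes chills"],
                      smooth=False) == 0.0
    assert bleu_score("sepsis causes fever", ["sepsis causes chills"]) > 0.0


# -- ROUGE ------------------------------------------------------------------


def test_rouge_identity():
    r = rouge_scores("early goal directed therapy", "early goal directed therapy")
    assert r["rouge1"].f1 == r["rouge2"].f1 == r["rougeL"].f1 == 1.0


def test_rouge_hand_counted():
    r = rouge_scores("a b c", "a b d")
    assert r["rouge1"].recall == pytest.approx(2 / 3)
    assert r["rougeL"].recall == pytest.approx(2 / 3)
    assert r["rougeL"].precision == pytest.approx(2 / 3)
    assert r["rougeL"].f1 == pytest.approx(2 / 3)


def test_rouge_empty_conventions():
    both = rouge_scores("", "")
    assert both["rouge1"].f1 == both["rougeL"].f1 == 1.0
    one = rouge_scores("", "text here")
    assert one["rouge1"].f1 == one["rougeL"].f1 == 0.0


def _lcs_oracle(a, b):
    """Independent recursive-memoized LCS, structurally unlike the DP."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def test_rouge_l_agrees_with_recursive_lcs_oracle():
    rng = Random(7)
    vocab = ["s", "e", "p", "t", "ic", "shock", "fever"]
    for _ in range(1000):
        a = tuple(rng.choice(vocab) for _ in range(rng.randrange(0, 12)))
        b = tuple(rng.choice(vocab) for _ in range(rng.randrange(0, 12)))
        if not a and not b:
            continue
        lcs = _lcs_oracle(a, b)
        got = rouge_scores(list(a), list(b))["rougeL"]
        want_r = lcs / len(b) if b else 0.0
        assert abs(got.recall - want_r) < 1e-9
        want_p = lcs / len(a) if a else 0.0
        assert abs(got.precision - want_p) < 1e-9


def test_generation_report_bounds():
    rep = evaluate_generation("fluids and antibiotics", "antibiotics then fluids")
    assert 0.0 <= rep.bleu <= 1.0
    for t in (rep.rouge1, rep.rouge2, rep.rougeL):
        assert 0.0 <= t.f1 <= 1.0


def test_cjk_tokenization_splits_characters():
    assert tokenize_for_eval("脓毒症 sepsis") == ["脓", "毒", "症", "sepsis"]
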