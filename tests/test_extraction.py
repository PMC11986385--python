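"""Prompt rendering, response parsing, backends, and document extraction."""

import pytest
from hypothesis import given, strategies as st

from sepsiskg import (
    BackendError,
    DictionaryMockBackend,
    Document,
    Exemplar,
    PromptTemplate,
    extract_corpus,
    extract_document,
    parse_triple_response,
    render_prompt,
    serialize_triples,
)
from sepsiskg.extraction import DEFAULT_RELATION_LABELS

AHF_TEXT = (
    "In adults, about 1/3 of AHF (Acute Heart Failure) patients may develop "
    "concurrent fungal infections, primarily caused by Candida albicans. "
    "Circulatory system issues may lead to sinus bradycardia, with a slower "
    "heart rate occurring relatively late, and in a minority of cases, sudden "
    "cardiac arrest can occur."
)
AHF_TRIPLES = [
    ("AHF", "Complications", "sinus bradycardia"),
    ("AHF", "Complications", "fungal infection"),
    ("Fungal infection", "Biomarker", "Candida albicans"),
]
# the response dialect as a model prints it, curly quotes and all
AHF_RESPONSE = (
    "“Triple list”: [[“AHF”, “Complications”, “sinus bradycardia”], "
    "[“AHF”, “Complications”, “fungal infection”], "
    "[“Fungal infection”, “Biomarker”, “Candida albicans”]]"
)
PANCREATIC_RESPONSE = (
    '"Triple list": [["Pancreatic cancer", "Clinical Presentation", '
    '"pancreatic mass"], ["Pancreatic cancer", "Imaging examination", '
    '"upper abdominal ultrasound examination"], ["Pancreatic cancer", '
    '"Clinical Presentation", "liver metastasis"]]'
)


class StubBackend:
    """Returns a fixed response; counts calls."""

    backend_id = "stub"

    def __init__(self, response):
        self.response = response
        self.calls = 0

    def complete(self, prompt):
        self.calls += 1
        return self.response


class FailingBackend:
    backend_id = "failing"

    def __init__(self):
        self.calls = 0

    def complete(self, prompt):
        self.calls += 1
        raise BackendError("boom")


# -- prompt rendering -------------------------------------------------------


def test_zero_shot_prompt_contents():
    d = Document(doc_id="d1", text="Sepsis presented with fever.")
    p = render_prompt(d, PromptTemplate())
    assert "extract the subject and object in the sentence" in p
    for label in DEFAULT_RELATION_LABELS:
        assert label in p
    assert "Examples" not in p
    assert p.rstrip().endswith("Sepsis presented with fever.")


def test_few_shot_prompt_includes_exemplars():
    t = PromptTemplate(
        mode="few_shot",
        exemplars=[Exemplar(text=AHF_TEXT, triple_list=AHF_TRIPLES)],
    )
    d = Document(doc_id="d1", text="target sentence here")
    p = render_prompt(d, t)
    assert AHF_TEXT in p
    assert '"AHF", "Complications", "sinus bradycardia"' in p
    # instruction and relation list come before exemplars, sentence last
    assert p.index("extract the subject") < p.index(AHF_TEXT) < p.index(
        "target sentence here"
    )


def test_prompt_is_deterministic():
    d = Document(doc_id="d1", text="text")
    t = PromptTemplate()
    assert render_prompt(d, t) == render_prompt(d, t)


def test_template_mode_invariants():
    with pytest.raises(ValueError):
        PromptTemplate(mode="few_shot")
    with pytest.raises(ValueError):
        PromptTemplate(
            mode="zero_shot",
            exemplars=[Exemplar(text="t", triple_list=[("a", "b", "c")])],
        )


# -- response parsing -------------------------------------------------------


def test_parse_worked_exemplar_responses():
    r1 = parse_triple_response(AHF_RESPONSE)
    assert not r1.parse_failed
    assert r1.triples == AHF_TRIPLES
    r2 = parse_triple_response(PANCREATIC_RESPONSE)
    assert not r2.parse_failed
    assert (
        "Pancreatic cancer", "Imaging examination",
        "upper abdominal ultrasound examination",
    ) in r2.triples
    assert len(r2.triples) == 3


def test_parse_well_formed_empty():
    for raw in ("no triples found", '"Triple list": []'):
        out = parse_triple_response(raw)
        assert out.triples == [] and not out.parse_failed


def test_parse_malformed_sets_flag():
    out = parse_triple_response("[[a,b")
    assert out.triples == [] and out.parse_failed


def test_parse_collapses_duplicates_preserving_order():
    raw = '[["a","r","b"], ["c","r","d"], ["a","r","b"]]'
    out = parse_triple_response(raw)
    assert out.triples == [("a", "r", "b"), ("c", "r", "d")]


def test_parse_tolerates_surrounding_prose():
    raw = "Here's the patient's extraction:\n" + AHF_RESPONSE + "\nDone."
    assert parse_triple_response(raw).triples == AHF_TRIPLES


surfaces = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters=" -"),
    min_size=1, max_size=20,
).filter(lambda s: s.strip())


@given(st.lists(st.tuples(surfaces, surfaces, surfaces), min_size=0, max_size=6))
def test_serialize_parse_round_trip(triples):
    deduped = list(dict.fromkeys((a.strip(), b.strip(), c.strip())
                                 for a, b, c in triples))
    out = parse_triple_response(serialize_triples(deduped))
    assert out.triples == deduped and not out.parse_failed


# -- mock backend -----------------------------------------------------------


def test_perfect_mock_reproduces_gold(gold50, perfect_extraction):
    pred = {t.key() for r in perfect_extraction for t in r.triples}
    gold = {t.key() for t in gold50.gold_triples}
    assert pred == gold


def test_mock_p_miss_one_is_silent(gold50):
    b = DictionaryMockBackend(gold50.sentences, p_miss=1.0, seed=3)
    d = gold50.documents[0]
    assert parse_triple_response(b.complete(d.text)).triples == []


def test_mock_seeded_determinism(gold50):
    b1 = DictionaryMockBackend(gold50.sentences, p_miss=0.5, seed=11)
    b2 = DictionaryMockBackend(gold50.sentences, p_miss=0.5, seed=11)
    prompts = [d.text for d in gold50.documents[:10]]
    assert [b1.complete(p) for p in prompts] == [b2.complete(p) for p in prompts]


# -- document extraction ----------------------------------------------------


def test_extract_document_canonicalizes_box_dialect(schema):
    d = Document(doc_id="d1", text=AHF_TEXT)
    res = extract_document(d, PromptTemplate(), StubBackend(AHF_RESPONSE), schema)
    assert [t.relation for t in res.triples] == [
        "complications", "complications", "the related biomarkers",
    ]
    assert res.raw_response == AHF_RESPONSE
    # mentions typed via relation defaults, spans located where possible
    kinds = {(m.surface, m.etype) for m in res.mentions}
    assert ("sinus bradycardia", "Diseases") in kinds
    assert ("Candida albicans", "Biomarkers") in kinds


def test_extract_document_rejects_offschema_relation(schema):
    d = Document(doc_id="d1", text="anything")
    res = extract_document(
        d, PromptTemplate(), StubBackend('[["sun","weather","rain"]]'), schema
    )
    assert res.triples == []
    assert len(res.rejected) == 1
    assert "unknown-relation" in res.rejected[0].reasons


def test_extract_document_never_emits_invalid(schema, gold50, perfect_extraction):
    from sepsiskg import validate_triple

    for r in perfect_extraction:
        for t in r.triples:
            assert validate_triple(t, schema).accepted


def test_empty_document_skips_backend(schema):
    d = Document.model_construct(doc_id="d1", text="   ", source="emr", meta={})
    b = StubBackend("unused")
    res = extract_document(d, PromptTemplate(), b, schema)
    assert res.triples == [] and b.calls == 0


def test_backend_retries_then_raises(schema):
    d = Document(doc_id="d1", text="note")
    b = FailingBackend()
    with pytest.raises(BackendError, match="3 attempts"):
        extract_document(d, PromptTemplate(), b, schema, sleep=lambda s: None)
    assert b.calls == 3


def test_extract_corpus_records_failures_and_continues(schema):
    docs = [Document(doc_id="a", text="x"), Document(doc_id="b", text="y")]
    results, failures = extract_corpus(
        docs, PromptTemplate(), FailingBackend(), schema, sleep=lambda s: None
    )
    assert results == [] and [f[0] for f in failures] == ["a", "b"]
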