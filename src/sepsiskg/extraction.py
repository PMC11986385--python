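"""Prompt-based entity/triple extraction with pluggable LLM backends.

The extraction stage renders a zero- or few-shot instruction prompt around a
clinical narrative, sends it to an :class:`ExtractorBackend`, and parses the
reply into ``(subject, relation, object)`` triples. Raw relation labels are
canonicalized against the ontology and every triple passes schema validation
before it reaches the graph; rejected triples are kept with machine-readable
reasons for audit.

Backends:

* :class:`DictionaryMockBackend` — deterministic and offline. It knows a set
  of relation-bearing sentences with their gold triples, recognizes those
  sentences inside the prompt, and replies in the same bracketed triple-list
  dialect a real model uses; configurable miss and spurious-triple rates make
  it a controllable stand-in for an imperfect extractor.
* :class:`OpenAIChatBackend` — a thin client for any OpenAI-compatible chat
  API, credentials read from the environment only.
"""

from __future__ import annotations

import ast
import json
import re
import time
import zlib
from random import Random
from typing import Callable, Iterable, Optional, Protocol, Sequence, runtime_checkable

from pydantic import BaseModel, Field, model_validator

from .errors import BackendError
from .models import Document, EntityMention, ExtractionResult, RejectedTriple, Triple
from .ontology import Schema, validate_triple

#: Instruction text of the triple-extraction prompt.
INSTRUCTION = (
    "Suppose you are an entity-relationship triple extraction model. "
    "I'll give you a list of head entity types: subject types, list of tail "
    "entity types: object types, list of relations: relations. Give you a "
    "sentence, please extract the subject and object in the sentence based "
    "on these three lists and form a triplet in the form of "
    "(subject, relation, object)."
)

#: The nine relation labels offered to the model, in prompt order.
DEFAULT_RELATION_LABELS: tuple[str, ...] = (
    "Clinical Presentation",
    "Surgical treatment",
    "biomarker",
    "subclass",
    "pathogenesis",
    "laboratory testing",
    "Imaging examination",
    "Complications",
    "Medication",
)

SENTENCE_MARKER = "The given sentence is"


class Exemplar(BaseModel):
    """A worked few-shot example: a text and its gold triple list."""

    text: str
    triple_list: list[tuple[str, str, str]]


class PromptTemplate(BaseModel):
    instruction: str = INSTRUCTION
    relation_labels: list[str] = Field(
        default_factory=lambda: list(DEFAULT_RELATION_LABELS)
    )
    exemplars: list[Exemplar] = Field(default_factory=list)
    mode: str = "zero_shot"

    @model_validator(mode="after")
    def _mode_consistent(self) -> "PromptTemplate":
        if self.mode not in ("zero_shot", "few_shot"):
            raise ValueError(f"unknown prompt mode {self.mode!r}")
        if self.mode == "zero_shot" and self.exemplars:
            raise ValueError("zero_shot template must not carry exemplars")
        if self.mode == "few_shot" and not self.exemplars:
            raise ValueError("few_shot template requires at least one exemplar")
        if not self.relation_labels:
            raise ValueError("relation_labels must be nonempty")
        return self


def serialize_triples(triples: Sequence[tuple[str, str, str]]) -> str:
    """Render triples in the bracketed response dialect the prompt teaches."""
    inner = ", ".join(
        "[" + ", ".join(json.dumps(part, ensure_ascii=False) for part in t) + "]"
        for t in triples
    )
    return f'"Triple list": [{inner}]'


def render_prompt(d: Document, t: PromptTemplate) -> str:
    """Render the full prompt: instruction, relation list, exemplars, sentence.

    Deterministic for fixed inputs; the document text is substituted into the
    sentence slot last.
    """
    parts = [t.instruction, "relations: " + json.dumps(t.relation_labels, ensure_ascii=False)]
    if t.exemplars:
        parts.append("Examples:")
        for ex in t.exemplars:
            parts.append(json.dumps({"text": ex.text}, ensure_ascii=False))
            parts.append(serialize_triples(ex.triple_list))
    parts.append(f"{SENTENCE_MARKER} \n{d.text}")
    return "\n".join(parts)


class ParsedResponse(BaseModel):
    """Triples recovered from a raw backend reply, plus a parse-failure flag."""

    triples: list[tuple[str, str, str]] = Field(default_factory=list)
    parse_failed: bool = False


_QUOTE_MAP = str.maketrans({"“": '"', "”": '"', "‘": "'", "’": "'"})


def _balanced_regions(s: str) -> tuple[list[str], bool]:
    """Top-level bracketed regions of ``s``; second value flags imbalance."""
    regions: list[str] = []
    depth = 0
    start = -1
    in_str: Optional[str] = None
    for i, ch in enumerate(s):
        if in_str:
            if ch == in_str and s[i - 1] != "\\":
                in_str = None
            continue
        # quote state only matters inside a bracket region; prose outside may
        # contain apostrophes that never close
        if depth > 0 and ch in "\"'":
            in_str = ch
        elif ch == "[":
            if depth == 0:
                start = i
            depth += 1
        elif ch == "]":
            if depth == 0:
                return regions, True
            depth -= 1
            if depth == 0:
                regions.append(s[start : i + 1])
    return regions, depth != 0 or in_str is not None


def _coerce_items(group: str) -> list[str]:
    """Parse one inner ``[...]`` group into string items, tolerantly."""
    for loader in (ast.literal_eval, json.loads):
        try:
            val = loader(group)
        except Exception:
            continue
        if isinstance(val, (list, tuple)):
            return [str(v).strip() for v in val]
    # last resort: naive comma split with quote stripping
    inner = group.strip()[1:-1]
    return [p.strip().strip("'\"").strip() for p in inner.split(",") if p.strip()]


def parse_triple_response(raw: str) -> ParsedResponse:
    """Recover triples from a raw reply; never raises.

    Accepts strict JSON arrays and the looser bracketed dialect (curly
    quotes, single quotes) anywhere in the response. Exact duplicates are
    collapsed, first-appearance order preserved. A reply with no bracket
    structure at all is a well-formed empty result; a reply whose bracket
    structure is unbalanced or yields no well-formed 3-element group is an
    empty result with ``parse_failed`` set.
    """
    text = raw.translate(_QUOTE_MAP)
    if "[" not in text and "]" not in text:
        return ParsedResponse()
    regions, broken = _balanced_regions(text)
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    saw_empty_list = False
    malformed_group = False
    for region in regions:
        inner_groups = re.findall(r"\[[^\[\]]*\]", region)
        if not inner_groups:
            if region.strip("[] \t\n") == "":
                saw_empty_list = True
            else:
                malformed_group = True
            continue
        for group in inner_groups:
            items = _coerce_items(group)
            if not items:
                saw_empty_list = True  # "[]" is a well-formed empty triple list
            elif len(items) == 3 and all(items):
                t = (items[0], items[1], items[2])
                if t not in seen:
                    seen.add(t)
                    triples.append(t)
            else:
                malformed_group = True
    if triples:
        return ParsedResponse(triples=triples, parse_failed=broken)
    if broken or (malformed_group and not saw_empty_list):
        return ParsedResponse(parse_failed=True)
    return ParsedResponse()


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


@runtime_checkable
class ExtractorBackend(Protocol):
    """Anything that can turn a prompt into a raw response string."""

    backend_id: str

    def complete(self, prompt: str) -> str:  # pragma: no cover - protocol
        ...


class DictionaryMockBackend:
    """Deterministic offline extractor driven by a gold sentence lexicon.

    ``gold_sentences`` maps a relation-bearing sentence to the triples it
    asserts (with prompt-dialect relation labels). On each call the backend
    finds which known sentences occur in the prompt's sentence slot and
    emits their triples in the bracketed dialect, dropping each with
    probability ``p_miss`` and injecting triples from ``spurious_pool`` with
    probability ``p_spur`` per response. Randomness is derived from
    ``(seed, crc32(document text))`` so responses are reproducible and
    independent of call order.
    """

    def __init__(
        self,
        gold_sentences: dict[str, list[tuple[str, str, str]]],
        p_miss: float = 0.0,
        p_spur: float = 0.0,
        spurious_pool: Sequence[tuple[str, str, str]] = (),
        seed: int = 0,
    ):
        if not (0.0 <= p_miss <= 1.0 and 0.0 <= p_spur <= 1.0):
            raise ValueError("p_miss and p_spur must lie in [0, 1]")
        self.gold_sentences = dict(gold_sentences)
        self.p_miss = p_miss
        self.p_spur = p_spur
        self.spurious_pool = list(spurious_pool)
        self.seed = seed
        self.backend_id = f"mock(p_miss={p_miss},p_spur={p_spur},seed={seed})"

    @staticmethod
    def _sentence_slot(prompt: str) -> str:
        idx = prompt.rfind(SENTENCE_MARKER)
        return prompt[idx + len(SENTENCE_MARKER) :] if idx >= 0 else prompt

    def complete(self, prompt: str) -> str:
        text = self._sentence_slot(prompt)
        rng = Random(self.seed * 2654435761 + zlib.crc32(text.encode("utf-8")))
        emitted: list[tuple[str, str, str]] = []
        for sentence in self.gold_sentences:
            if sentence in text:
                for triple in self.gold_sentences[sentence]:
                    if rng.random() >= self.p_miss:
                        emitted.append(triple)
        if self.spurious_pool and rng.random() < self.p_spur:
            emitted.append(self.spurious_pool[rng.randrange(len(self.spurious_pool))])
        if not emitted:
            return "no triples found"
        return serialize_triples(emitted)


class OpenAIChatBackend:
    """Minimal client for an OpenAI-compatible chat-completions API.

    Credentials come from ``OPENAI_API_KEY`` (and optionally
    ``OPENAI_BASE_URL``) in the environment — never from config files.
    Decoding defaults to temperature 0 for reproducibility.
    """

    def __init__(
        self,
        model: str = "gpt-4-turbo",
        temperature: float = 0.0,
        timeout: float = 60.0,
    ):
        self.model = model
        self.temperature = temperature
        self.timeout = timeout
        self.backend_id = f"openai:{model}"

    def complete(self, prompt: str) -> str:  # pragma: no cover - needs network
        import os
        import urllib.error
        import urllib.request

        key = os.environ.get("OPENAI_API_KEY")
        if not key:
            raise BackendError("OPENAI_API_KEY not set in environment")
        base = os.environ.get("OPENAI_BASE_URL", "https://api.openai.com/v1")
        payload = json.dumps(
            {
                "model": self.model,
                "temperature": self.temperature,
                "messages": [{"role": "user", "content": prompt}],
            }
        ).encode("utf-8")
        req = urllib.request.Request(
            base.rstrip("/") + "/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {key}",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
            raise BackendError(f"backend call failed: {exc}") from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError) as exc:
            raise BackendError(f"unexpected response shape: {body!r}") from exc


# ---------------------------------------------------------------------------
# Document- and corpus-level extraction
# ---------------------------------------------------------------------------


def _locate(text: str, surface: str) -> Optional[tuple[int, int]]:
    """Leftmost occurrence of ``surface`` in ``text`` as a character span."""
    idx = text.find(surface)
    return (idx, idx + len(surface)) if idx >= 0 else None


def _mentions_from_triples(
    triples: Sequence[Triple], d: Document, schema: Schema
) -> list[EntityMention]:
    """Derive typed mentions from triple arguments.

    Entity types come from the relation's default subject/object typing;
    spans by leftmost non-overlapping search (``None`` when the surface is
    not found verbatim, e.g. after model paraphrase).
    """
    mentions: list[EntityMention] = []
    seen: set[tuple[str, str]] = set()
    for t in triples:
        rdef = schema.relation(t.relation)
        for surface, etype in (
            (t.subject, rdef.default_subject_type),
            (t.object, rdef.default_object_type),
        ):
            etype = etype or "Diseases"
            if (surface, etype) in seen:
                continue
            seen.add((surface, etype))
            mentions.append(
                EntityMention(
                    doc_id=d.doc_id,
                    surface=surface,
                    etype=etype,
                    span=_locate(d.text, surface),
                )
            )
    return mentions


def extract_document(
    d: Document,
    t: PromptTemplate,
    b: ExtractorBackend,
    s: Schema,
    retries: int = 3,
    backoff: float = 1.0,
    sleep: Callable[[float], None] = time.sleep,
) -> ExtractionResult:
    """Run one document through the backend and validate its output.

    Accepted triples carry canonical relation names; parsed triples that
    fail validation are retained in ``rejected`` with reason codes. Backend
    transport failures are retried with exponential backoff and re-raised as
    :class:`BackendError` once retries are exhausted.
    """
    if not d.text.strip():
        return ExtractionResult(doc_id=d.doc_id, backend_id=b.backend_id)
    prompt = render_prompt(d, t)
    last_exc: Optional[BackendError] = None
    raw = None
    for attempt in range(retries):
        try:
            raw = b.complete(prompt)
            break
        except BackendError as exc:
            last_exc = exc
            if attempt < retries - 1:
                sleep(backoff * (2**attempt))
    if raw is None:
        raise BackendError(
            f"backend {b.backend_id} failed after {retries} attempts: {last_exc}"
        )
    parsed = parse_triple_response(raw)
    accepted: list[Triple] = []
    rejected: list[RejectedTriple] = []
    for subj, rel, obj in parsed.triples:
        candidate = Triple(subject=subj, relation=rel, object=obj, doc_id=d.doc_id)
        verdict = validate_triple(candidate, s)
        if verdict.accepted:
            accepted.append(
                candidate.model_copy(update={"relation": verdict.canonical_relation})
            )
        else:
            rejected.append(RejectedTriple(triple=candidate, reasons=verdict.reasons))
    return ExtractionResult(
        doc_id=d.doc_id,
        mentions=_mentions_from_triples(accepted, d, s),
        triples=accepted,
        rejected=rejected,
        raw_response=raw,
        backend_id=b.backend_id,
        parse_failed=parsed.parse_failed,
    )


def extract_corpus(
    docs: Iterable[Document],
    t: PromptTemplate,
    b: ExtractorBackend,
    s: Schema,
    retries: int = 3,
    backoff: float = 1.0,
    sleep: Callable[[float], None] = time.sleep,
) -> tuple[list[ExtractionResult], list[tuple[str, str]]]:
    """Extract every document; failures are recorded, the run continues.

    Returns ``(results, failures)`` where failures are ``(doc_id, message)``
    pairs for documents whose backend calls exhausted their retries.
    """
    results: list[ExtractionResult] = []
    failures: list[tuple[str, str]] = []
    for d in docs:
        try:
            results.append(
                extract_document(d, t, b, s, retries=retries, backoff=backoff, sleep=sleep)
            )
        except BackendError as exc:
            failures.append((d.doc_id, str(exc)))
    return results, failures
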