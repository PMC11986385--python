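"""Shared domain records: documents, entity mentions, triples, extraction results.

These types cross module boundaries (the ontology validates triples, fusion
clusters mentions, the graph consumes fused triples), so they live here rather
than in any one pipeline stage.
"""

from __future__ import annotations

from typing import Any, Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

Source = Literal["emr", "guideline", "database"]


class Document(BaseModel):
    """A deidentified source text (EMR narrative, guideline abstract, ...)."""

    doc_id: str
    text: str
    source: Source = "emr"
    meta: dict[str, Any] = Field(default_factory=dict)

    @field_validator("doc_id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("doc_id must be nonempty")
        return v

    @field_validator("text")
    @classmethod
    def _text_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("document text must be nonempty")
        return v


class EntityMention(BaseModel):
    """A typed surface-form occurrence in one document.

    ``span`` is optional because LLM output returns surfaces, not offsets;
    when present it must index the surface exactly in the document text.
    """

    doc_id: str
    surface: str
    etype: str
    span: Optional[tuple[int, int]] = None
    attrs: dict[str, Any] = Field(default_factory=dict)

    @field_validator("surface")
    @classmethod
    def _surface_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("mention surface must be nonempty")
        return v

    @model_validator(mode="after")
    def _span_ordered(self) -> "EntityMention":
        if self.span is not None:
            start, end = self.span
            if not (0 <= start < end):
                raise ValueError(f"invalid span {self.span}")
        return self


class Triple(BaseModel):
    """A (subject, relation, object) assertion with provenance.

    ``relation`` is a raw label as emitted by an extractor; it is mapped to a
    canonical relation by :func:`sepsiskg.ontology.canonicalize_relation`.
    """

    subject: str
    relation: str
    object: str
    doc_id: str
    confidence: Optional[float] = None

    @field_validator("subject", "relation", "object")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("triple fields must be nonempty")
        return v

    @field_validator("confidence")
    @classmethod
    def _confidence_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        return v

    def key(self) -> tuple[str, str, str, str]:
        """Identity used for dedup: (subject, relation, object, doc_id)."""
        return (self.subject, self.relation, self.object, self.doc_id)


class RejectedTriple(BaseModel):
    """A parsed triple that failed schema validation, with reason codes."""

    triple: Triple
    reasons: list[str]


class ExtractionResult(BaseModel):
    """Everything one backend call produced for one document."""

    doc_id: str
    mentions: list[EntityMention] = Field(default_factory=list)
    triples: list[Triple] = Field(default_factory=list)
    rejected: list[RejectedTriple] = Field(default_factory=list)
    raw_response: str = ""
    backend_id: str = ""
    parse_failed: bool = False

    @model_validator(mode="after")
    def _provenance_consistent(self) -> "ExtractionResult":
        for t in self.triples:
            if t.doc_id != self.doc_id:
                raise ValueError(
                    f"triple doc_id {t.doc_id!r} != result doc_id {self.doc_id!r}"
                )
        return self
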