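"""The entity/relation ontology that constrains extraction and graph building.

The ontology (pattern layer) fixes nine clinical entity concepts — Diseases,
Symptoms, Imaging examination, Biomarkers, Laboratory test, Subtypes,
Pathogenic mechanism, Pharmacotherapy, Surgery — and eight core directed
semantic relations between them (complications, has symptom, recommended
imaging examination, the related biomarkers, treat, recommended laboratory
tests, caused by, recommended medication). Extraction prompts use their own
relation labels ("Clinical Presentation", "Medication", ...); this module owns
the alias table that maps every prompt label onto exactly one canonical
relation, and the validation gate that keeps off-schema LLM output out of the
graph.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError, SchemaError, UnknownRelationError
from .models import Triple
from .textnorm import basic_normalize

REQUIRED_ATTRIBUTES = ("canonical name", "concept ID")


class EntityTypeDef(BaseModel):
    """One entity concept with its attribute list."""

    model_config = ConfigDict(extra="forbid")

    name: str
    attributes: list[str]
    description: str = ""

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("entity type name must be nonempty")
        return v

    @field_validator("attributes")
    @classmethod
    def _required_attributes(cls, v: list[str]) -> list[str]:
        lowered = {a.lower() for a in v}
        missing = [a for a in REQUIRED_ATTRIBUTES if a.lower() not in lowered]
        if missing:
            raise ValueError(f"attributes must include {missing}")
        return v


class RelationTypeDef(BaseModel):
    """One directed semantic relation, plus its prompt-label aliases.

    ``subject_types``/``object_types`` are hard constraints (empty means
    unconstrained); ``default_subject_type``/``default_object_type`` only
    supply the entity type assigned to triple arguments when no other typing
    information is available.
    """

    model_config = ConfigDict(extra="forbid")

    canonical_name: str
    prompt_labels: list[str] = Field(default_factory=list)
    subject_types: list[str] = Field(default_factory=list)
    object_types: list[str] = Field(default_factory=list)
    default_subject_type: Optional[str] = None
    default_object_type: Optional[str] = None
    meaning: str = ""
    extension: bool = False

    @field_validator("canonical_name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("relation canonical_name must be nonempty")
        return v


def _fold(label: str) -> str:
    """Case-insensitive, whitespace-trimmed key for label lookup."""
    return " ".join(label.strip().lower().split())


class Schema(BaseModel):
    """An ontology: entity types, relation types and the alias index."""

    entity_types: list[EntityTypeDef]
    relation_types: list[RelationTypeDef]
    version: str = "1.0"

    def model_post_init(self, __context) -> None:
        names = [e.name for e in self.entity_types]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate entity type name(s): {dup}")
        rnames = [r.canonical_name for r in self.relation_types]
        if len(rnames) != len(set(rnames)):
            dup = sorted({n for n in rnames if rnames.count(n) > 1})
            raise SchemaError(f"duplicate relation name(s): {dup}")
        # Build the alias index; a prompt label must map to exactly one relation.
        index: dict[str, str] = {}
        for r in self.relation_types:
            for label in [r.canonical_name, *r.prompt_labels]:
                key = _fold(label)
                if key in index and index[key] != r.canonical_name:
                    raise SchemaError(
                        f"label {label!r} maps to both {index[key]!r} "
                        f"and {r.canonical_name!r}"
                    )
                index[key] = r.canonical_name
        object.__setattr__(self, "_alias_index", index)
        etype_names = set(names)
        for r in self.relation_types:
            for t in [*r.subject_types, *r.object_types]:
                if t not in etype_names:
                    raise SchemaError(
                        f"relation {r.canonical_name!r} constrains unknown "
                        f"entity type {t!r}"
                    )

    # -- lookups ------------------------------------------------------------

    def entity_type(self, name: str) -> EntityTypeDef:
        for e in self.entity_types:
            if e.name == name:
                return e
        raise KeyError(name)

    def relation(self, canonical_name: str) -> RelationTypeDef:
        for r in self.relation_types:
            if r.canonical_name == canonical_name:
                return r
        raise KeyError(canonical_name)

    @property
    def entity_type_names(self) -> list[str]:
        return [e.name for e in self.entity_types]

    @property
    def canonical_relation_names(self) -> list[str]:
        return [r.canonical_name for r in self.relation_types]

    @property
    def core_relation_names(self) -> list[str]:
        """Canonical relations excluding extensions (the core set of 8)."""
        return [r.canonical_name for r in self.relation_types if not r.extension]


def default_schema_path() -> Path:
    return Path(str(resources.files("sepsiskg").joinpath("data/default_schema.yaml")))


def load_schema(path: Union[str, Path, None] = None) -> Schema:
    """Load an ontology config (YAML or JSON); ``None`` loads the bundled default.

    Unknown keys are rejected so typos in config files fail loudly rather
    than silently relaxing a constraint.
    """
    p = default_schema_path() if path is None else Path(path)
    if not p.exists():
        raise ConfigurationError(f"ontology config not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse ontology config {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"ontology config {p} must be a mapping")
    known = {"entity_types", "relation_types", "version"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in ontology config {p}: {sorted(unknown)}"
        )
    try:
        return Schema(**raw)
    except SchemaError:
        raise
    except Exception as exc:  # pydantic validation errors carry the field name
        raise ConfigurationError(f"invalid ontology config {p}: {exc}") from exc


def canonicalize_relation(label: str, schema: Schema) -> str:
    """Map a raw relation label to its canonical name.

    Lookup is case-insensitive and whitespace-trimmed, through prompt labels
    and canonical names alike; an unmapped label raises
    :class:`UnknownRelationError` carrying the raw label — it is never
    silently dropped.
    """
    index: dict[str, str] = getattr(schema, "_alias_index")
    key = _fold(label)
    if key not in index:
        raise UnknownRelationError(label)
    return index[key]


class Verdict(BaseModel):
    """Outcome of triple validation: accept, or reject with reason codes."""

    accepted: bool
    reasons: list[str] = Field(default_factory=list)
    canonical_relation: Optional[str] = None

    def __bool__(self) -> bool:
        return self.accepted


#: machine-readable reason codes
REASON_UNKNOWN_RELATION = "unknown-relation"
REASON_SELF_LOOP = "self-loop"
REASON_SUBJECT_TYPE = "subject-type-violation"
REASON_OBJECT_TYPE = "object-type-violation"


def validate_triple(
    t: Triple,
    schema: Schema,
    subject_type: Optional[str] = None,
    object_type: Optional[str] = None,
) -> Verdict:
    """Validate one triple against the ontology.

    Rejects when the relation cannot be canonicalized, when a configured
    domain/range constraint is violated (types must be supplied by the caller
    for this check to bite), or when subject and object normalize to the same
    string (self-loop). Returns a verdict, never raises: one bad LLM triple
    must not abort a corpus run.
    """
    reasons: list[str] = []
    canonical: Optional[str] = None
    try:
        canonical = canonicalize_relation(t.relation, schema)
    except UnknownRelationError:
        reasons.append(REASON_UNKNOWN_RELATION)

    if basic_normalize(t.subject) == basic_normalize(t.object):
        reasons.append(REASON_SELF_LOOP)

    if canonical is not None:
        rdef = schema.relation(canonical)
        if rdef.subject_types and subject_type is not None:
            if subject_type not in rdef.subject_types:
                reasons.append(REASON_SUBJECT_TYPE)
        if rdef.object_types and object_type is not None:
            if object_type not in rdef.object_types:
                reasons.append(REASON_OBJECT_TYPE)

    return Verdict(accepted=not reasons, reasons=reasons, canonical_relation=canonical)
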