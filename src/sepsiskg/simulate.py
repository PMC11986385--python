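"""Seeded synthetic clinical corpora with known gold annotations.

Each synthetic document is a short admission-style narrative assembled from
relation-bearing sentence templates ("Sepsis was complicated by pneumonia.",
"Procalcitonin is a biomarker associated with sepsis."), instantiated from a
typed lexicon of sepsis-relevant surfaces. Every instantiation is recorded as
a gold triple and gold mentions (with character spans), and the generator's
own bookkeeping of surface-variant groups yields the gold knowledge graph —
so extraction, fusion, graph construction and the evaluation metrics can all
be checked end-to-end with no network, no API key and no real patient text.

The lexicon's variant groups emulate the surface variation that knowledge
fusion must undo: abbreviations are handled by the default abbreviation map,
case/punctuation variants by normalization, and plural/suffix variants by the
similarity threshold. Contents are test fixtures, not clinical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .fusion import DEFAULT_RULES, NormalizationRules, normalize_name
from .graph import KnowledgeGraph, ResolvedTriple, build_graph
from .models import Document, EntityMention, Triple
from .ontology import Schema, canonicalize_relation, load_schema

#: surface-variant groups per entity type; the first surface is canonical.
DEFAULT_LEXICON: dict[str, list[list[str]]] = {
    "Diseases": [
        ["sepsis", "Sepsis"],
        ["septic shock", "Septic Shock"],
        ["pneumonia"],
        ["heart failure", "HF", "Heart Failure"],
        ["hypoproteinemia"],
        ["acute kidney injury", "AKI"],
        ["fungal infection", "fungal infections"],
        ["urinary tract infection", "UTI"],
        ["meningitis"],
        ["pancreatitis"],
    ],
    "Symptoms": [
        ["fever", "fevers"],
        ["tachypnea"],
        ["hypotension"],
        ["altered mental status"],
        ["oliguria"],
        ["dyspnea"],
        ["tachycardia"],
        ["abdominal pain", "abdominal pains"],
    ],
    "Imaging examination": [
        ["chest X-ray", "chest x ray"],
        ["chest radiograph", "chest radiographs"],
        ["abdominal ultrasound"],
        ["chest computed tomography"],
    ],
    "Biomarkers": [
        ["procalcitonin", "PCT"],
        ["C-reactive protein", "CRP"],
        ["interleukin 6"],
        ["serum lactate", "serum lactates"],
        ["presepsin"],
    ],
    "Laboratory test": [
        ["blood culture", "blood cultures"],
        ["complete blood count"],
        ["arterial blood gas"],
        ["urinalysis"],
    ],
    "Subtypes": [
        ["urosepsis"],
        ["neonatal sepsis"],
        ["surgical sepsis"],
    ],
    "Pathogenic mechanism": [
        ["bacterial infection", "bacterial infections"],
        ["gram negative bacteremia"],
        ["endotoxin release"],
        ["immune dysregulation"],
    ],
    "Pharmacotherapy": [
        ["physiological saline", "Physiological Saline"],
        ["glucose infusion"],
        ["vancomycin"],
        ["meropenem"],
        ["norepinephrine"],
        ["piperacillin tazobactam"],
    ],
    "Surgery": [
        ["abscess drainage"],
        ["surgical debridement"],
        ["appendectomy"],
        ["source control laparotomy"],
    ],
}

#: sentence frames per canonical relation; {subject}/{object} are slots.
DEFAULT_GRAMMAR: dict[str, list[str]] = {
    "complications": [
        "{subject} was complicated by {object}.",
        "In this patient {subject} gave rise to {object}.",
    ],
    "has symptom": [
        "{subject} presented with {object}.",
        "The course of {subject} was marked by {object}.",
    ],
    "recommended imaging examination": [
        "For {subject} a {object} was recommended.",
        "{subject} was evaluated with {object}.",
    ],
    "the related biomarkers": [
        "{object} is a biomarker associated with {subject}.",
        "Levels of {object} were monitored in {subject}.",
    ],
    "treat": [
        "{subject} was treated surgically with {object}.",
        "Management of {subject} required {object}.",
    ],
    "recommended laboratory tests": [
        "A {object} was ordered for suspected {subject}.",
        "Workup of {subject} included {object}.",
    ],
    "caused by": [
        "{subject} was caused by {object}.",
        "{subject} developed secondary to {object}.",
    ],
    "recommended medication": [
        "{subject} was managed with {object}.",
        "Treatment of {subject} included {object}.",
    ],
    "subtype of": [
        "{object} is a recognized subtype of {subject}.",
        "The presentation of {subject} was classified as {object}.",
    ],
}


class SimConfig(BaseModel):
    """Generator settings; defaults define the bundled study conditions."""

    n_docs: int = 50
    seed: int = 42
    lexicon: dict[str, list[list[str]]] = Field(
        default_factory=lambda: {
            k: [list(g) for g in v] for k, v in DEFAULT_LEXICON.items()
        }
    )
    relation_grammar: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRAMMAR.items()}
    )
    variant_rate: float = 0.3
    triples_per_doc: tuple[int, int] = (2, 5)

    @model_validator(mode="after")
    def _ranges(self) -> "SimConfig":
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if not (0.0 <= self.variant_rate <= 1.0):
            raise ValueError("variant_rate must lie in [0, 1]")
        lo, hi = self.triples_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("triples_per_doc must be a nonempty positive range")
        return self


@dataclass
class GoldCorpus:
    """A synthetic corpus with complete gold annotations and bookkeeping."""

    documents: list[Document]
    gold_mentions: list[EntityMention]
    gold_triples: list[Triple]  # canonical relations
    gold_graph: KnowledgeGraph
    #: sentence → [(subject surface, prompt relation label, object surface)];
    #: drives the dictionary mock backend
    sentences: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    #: (etype, canonical surface, realized surfaces) per variant group used
    groups_used: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    config: Optional[SimConfig] = None

    def multi_surface_group_count(
        self, rules: NormalizationRules = DEFAULT_RULES
    ) -> int:
        """Used variant groups whose realized surfaces span ≥2 distinct
        normalized forms — exactly the groups that stop merging when the
        fusion threshold is raised to 1.0."""
        n = 0
        for _, _, surfaces in self.groups_used:
            forms = {normalize_name(s, rules) for s in surfaces}
            if len(forms) >= 2:
                n += 1
        return n


def _prompt_label(schema: Schema, canonical: str) -> str:
    rdef = schema.relation(canonical)
    return rdef.prompt_labels[0] if rdef.prompt_labels else canonical


def _validate_config(cfg: SimConfig, schema: Schema) -> None:
    etypes = set(schema.entity_type_names)
    for t in cfg.lexicon:
        if t not in etypes:
            raise ConfigurationError(f"lexicon type {t!r} is not a schema entity type")
    for rel in cfg.relation_grammar:
        canonicalize_relation(rel, schema)  # raises if unknown
    for rel in cfg.relation_grammar:
        rdef = schema.relation(canonicalize_relation(rel, schema))
        for t in (rdef.default_subject_type, rdef.default_object_type):
            if t and not cfg.lexicon.get(t):
                raise ConfigurationError(
                    f"relation {rel!r} needs lexicon entries of type {t!r}"
                )


def generate_corpus(cfg: SimConfig, schema: Optional[Schema] = None) -> GoldCorpus:
    """Generate a seeded synthetic corpus with gold mentions, triples, graph.

    Deterministic for a fixed seed. Each document concatenates 2–5 (by
    default) instantiated relation templates over distinct
    (subject group, relation, object group) combinations; variant surfaces
    are drawn with probability ``variant_rate`` and recorded in the gold
    bookkeeping with their canonical group identity. Gold-graph weights equal
    the true per-document support counts.
    """
    schema = schema or load_schema()
    _validate_config(cfg, schema)
    rng = Random(cfg.seed)
    rules = DEFAULT_RULES

    relations = sorted(cfg.relation_grammar)
    documents: list[Document] = []
    gold_triples: list[Triple] = []
    sentences: dict[str, list[tuple[str, str, str]]] = {}
    mention_keys: set[tuple[str, str, str]] = set()
    gold_mentions: list[EntityMention] = []
    groups_used: dict[tuple[str, int], tuple[str, ...]] = {}
    # (doc, group-level triple) instances for the gold graph
    instances: list[tuple[str, tuple[str, int], str, tuple[str, int]]] = []

    def realize(etype: str, gidx: int) -> str:
        group = cfg.lexicon[etype][gidx]
        if len(group) > 1 and rng.random() < cfg.variant_rate:
            surface = group[1 + rng.randrange(len(group) - 1)]
        else:
            surface = group[0]
        prev = groups_used.get((etype, gidx), ())
        if surface not in prev:
            groups_used[(etype, gidx)] = prev + (surface,)
        return surface

    for i in range(cfg.n_docs):
        doc_id = f"doc{i:04d}"
        k = rng.randint(*cfg.triples_per_doc)
        combos: set[tuple[str, int, int]] = set()
        parts: list[str] = []
        for _ in range(k):
            for _try in range(40):
                rel = relations[rng.randrange(len(relations))]
                rdef = schema.relation(rel)
                stype = rdef.default_subject_type or "Diseases"
                otype = rdef.default_object_type or "Diseases"
                sgi = rng.randrange(len(cfg.lexicon[stype]))
                ogi = rng.randrange(len(cfg.lexicon[otype]))
                if stype == otype and sgi == ogi:
                    continue
                if (rel, sgi, ogi) not in combos:
                    combos.add((rel, sgi, ogi))
                    break
            else:
                continue  # lexicon exhausted for this doc size
            ssurf = realize(stype, sgi)
            osurf = realize(otype, ogi)
            template = cfg.relation_grammar[rel][
                rng.randrange(len(cfg.relation_grammar[rel]))
            ]
            sentence = template.format(subject=ssurf, object=osurf)
            parts.append(sentence)
            gold_triples.append(
                Triple(subject=ssurf, relation=rel, object=osurf, doc_id=doc_id)
            )
            sentences.setdefault(sentence, [])
            entry = (ssurf, _prompt_label(schema, rel), osurf)
            if entry not in sentences[sentence]:
                sentences[sentence].append(entry)
            instances.append((doc_id, (stype, sgi), rel, (otype, ogi)))
            for surf, etype in ((ssurf, stype), (osurf, otype)):
                if (doc_id, surf, etype) not in mention_keys:
                    mention_keys.add((doc_id, surf, etype))
                    gold_mentions.append(
                        EntityMention(doc_id=doc_id, surface=surf, etype=etype)
                    )
        if parts:
            documents.append(Document(doc_id=doc_id, text=" ".join(parts)))

    # spans: leftmost occurrence in the final text (same rule extraction uses)
    doc_text = {d.doc_id: d.text for d in documents}
    for m in gold_mentions:
        idx = doc_text[m.doc_id].find(m.surface)
        if idx >= 0:
            m.span = (idx, idx + len(m.surface))

    # gold graph from the generator's own group bookkeeping ("perfect fusion"):
    # elect each group's canonical surface the same way alignment does —
    # modal mention surface, lexicographic tie-break
    counts: dict[tuple[str, int], dict[str, int]] = {}
    surface_group: dict[tuple[str, str], tuple[str, int]] = {}
    for (etype, gidx), surfaces in groups_used.items():
        for s in surfaces:
            surface_group[(etype, s)] = (etype, gidx)
    for m in gold_mentions:
        gkey = surface_group[(m.etype, m.surface)]
        counts.setdefault(gkey, {})
        counts[gkey][m.surface] = counts[gkey].get(m.surface, 0) + 1
    elected: dict[tuple[str, int], tuple[str, str]] = {}
    for gkey, surf_counts in counts.items():
        canonical = min(surf_counts, key=lambda s: (-surf_counts[s], s))
        elected[gkey] = (canonical, normalize_name(canonical, rules))
    resolved = [
        ResolvedTriple(
            subject_id=elected[sg][1],
            subject_label=sg[0],
            subject_name=elected[sg][0],
            relation=rel,
            object_id=elected[og][1],
            object_label=og[0],
            object_name=elected[og][0],
            doc_id=doc_id,
        )
        for doc_id, sg, rel, og in instances
    ]
    gold_graph = build_graph(resolved, schema)

    return GoldCorpus(
        documents=documents,
        gold_mentions=gold_mentions,
        gold_triples=gold_triples,
        gold_graph=gold_graph,
        sentences=sentences,
        groups_used=[
            (etype, cfg.lexicon[etype][gidx][0], surfaces)
            for (etype, gidx), surfaces in sorted(groups_used.items())
        ],
        config=cfg,
    )


def spurious_pool(
    gold: GoldCorpus, schema: Optional[Schema] = None, limit: int = 200
) -> list[tuple[str, str, str]]:
    """Schema-valid (subject, prompt label, object) triples absent from gold.

    Drawn deterministically from canonical lexicon surfaces; used by the
    dictionary mock backend and by :func:`corrupt_predictions` to inject
    plausible-but-wrong extractions.
    """
    schema = schema or load_schema()
    cfg = gold.config or SimConfig()
    gold_keys = {
        (normalize_name(t.subject), t.relation, normalize_name(t.object))
        for t in gold.gold_triples
    }
    pool: list[tuple[str, str, str]] = []
    for rel in sorted(cfg.relation_grammar):
        rdef = schema.relation(rel)
        stype = rdef.default_subject_type or "Diseases"
        otype = rdef.default_object_type or "Diseases"
        for sgroup in cfg.lexicon[stype]:
            for ogroup in cfg.lexicon[otype]:
                if stype == otype and sgroup is ogroup:
                    continue
                key = (normalize_name(sgroup[0]), rel, normalize_name(ogroup[0]))
                if key in gold_keys:
                    continue
                pool.append((sgroup[0], _prompt_label(schema, rel), ogroup[0]))
                if len(pool) >= limit:
                    return pool
    return pool


def corrupt_predictions(
    gold: GoldCorpus,
    p_miss: float,
    p_spur: float,
    seed: int,
    schema: Optional[Schema] = None,
) -> list[Triple]:
    """Derive an imperfect prediction set from the gold standard.

    Each gold triple is independently dropped with probability ``p_miss``;
    each document independently receives one spurious schema-valid triple
    (guaranteed off-gold, so always a false positive) with probability
    ``p_spur``. Deterministic per seed. Relations stay canonical, so the
    output feeds :func:`sepsiskg.evaluation.score_triples` directly.
    """
    if not (0.0 <= p_miss <= 1.0 and 0.0 <= p_spur <= 1.0):
        raise ValueError("p_miss and p_spur must lie in [0, 1]")
    schema = schema or load_schema()
    rng = Random(seed)
    preds: list[Triple] = [
        t.model_copy() for t in gold.gold_triples if rng.random() >= p_miss
    ]
    pool = spurious_pool(gold, schema)
    if not pool:
        return preds
    for d in gold.documents:
        if rng.random() < p_spur:
            subj, label, obj = pool[rng.randrange(len(pool))]
            preds.append(
                Triple(
                    subject=subj,
                    relation=canonicalize_relation(label, schema),
                    object=obj,
                    doc_id=d.doc_id,
                )
            )
    return preds
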