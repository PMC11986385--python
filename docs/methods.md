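# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic corpus does and does not emulate,
and the choices made where the design was genuinely open.

## Pipeline model

The toolkit treats knowledge-graph construction as five composable stages:

```
corpus → prompt-based extraction → ontology validation → fusion → graph
```

Each stage is a pure function over explicit inputs; the only stateful
component is an extractor backend, and the bundled mock backend is
deterministic given its seed. This makes the end-to-end pipeline a testable
mathematical object: for a corpus whose gold triples are known, a perfect
extractor must yield micro-F1 = 1.0 and the built graph must equal the gold
graph exactly.

## Ontology

The pattern layer has nine entity concepts and eight core directed
relations (see `src/sepsiskg/data/default_schema.yaml`, which reproduces the
concept and relation tables verbatim, including the `UIs` spelling in the
Pathogenic-mechanism attribute list). Extraction prompts use nine relation
labels; eight map onto the core relations through a fixed alias table:

| prompt label | canonical relation |
|---|---|
| Clinical Presentation | has symptom |
| Surgical treatment | treat |
| biomarker | the related biomarkers |
| pathogenesis | caused by |
| laboratory testing | recommended laboratory tests |
| Imaging examination | recommended imaging examination |
| Complications | complications |
| Medication | recommended medication |
| subclass | **subtype of** (extension) |

This alias table is the only semantically coherent bijection between the
two label sets. The ninth label, `subclass`, has no core counterpart; rather
than discard information a model may legitimately return, the default
schema adds an extension relation `subtype of` (Diseases → Subtypes),
flagged `extension: true` and removable by deleting one block from the
config. `has complication` is accepted as an alias of `complications`
because ranking queries are conventionally written with the former.

Domain/range constraints default to *unconstrained* (the tables define no
domain/range); each relation carries default subject/object entity types
used only to type triple arguments when no other typing information exists.
Edge direction is subject = disease/condition, object = associated
finding/intervention, matching all worked exemplars.

## Extraction

Prompts contain, in order: the instruction, the relation-label list, the
few-shot exemplars (if any), and the document text in the sentence slot.
Response parsing accepts both strict JSON arrays and the looser bracketed
dialect with curly/single quotes, anywhere in the reply; a reply with no
bracket structure is a well-formed empty result, while unbalanced brackets
or malformed groups set a `parse_failed` flag on an empty result — parsing
never raises, so one bad reply cannot abort a corpus run. Exact duplicate
triples are collapsed preserving first appearance.

Single-pass convention: entities are derived from validated triple
arguments (typed via the relation's default subject/object types, spans by
leftmost string search), rather than running a separate NER pass; both can
be composed from the public API, but the single triple pass is the default
because it keeps entity and relation output mutually consistent.

Backend contract: `complete(prompt) -> str`, stateless per call. The remote
client defaults to temperature 0 for reproducibility and reads credentials
only from the environment. Transport failures are retried 3 times with
exponential backoff, then recorded per document while the corpus run
continues. The dictionary mock recognizes known relation-bearing sentences
inside the prompt's sentence slot and replies in the taught dialect; its
miss/spurious behaviour is driven by a generator seeded from
`seed × 2654435761 + crc32(document text)`, making responses reproducible
and independent of call order.

## Fusion

Normalization order is fixed: lowercase → punctuation strip (punctuation
becomes a space, preserving token boundaries) → whitespace collapse →
abbreviation expansion (whole-token, case-insensitive). Expansions are
validated not to contain abbreviation keys, which makes normalization
idempotent by construction.

Similarity combines two signals on normalized strings:

* token **Jaccard** |A∩B| / |A∪B| (two empty strings score 1), and
* cosine over a **character-n-gram hashing embedder** (n = 2–4, 256
  dimensions, CRC32 hashing — deterministic, no model download), rescaled
  to [0, 1] via (1 + cos)/2 since cosine can be negative. A real biomedical
  embedder can be dropped in behind the same `embed` protocol.

The default combination is `max`: a pair merges if *either* signal is
confident. Rationale: Jaccard is blind to morphological variants
(`infection`/`infections`) and the embedder is blind to synonymy handled by
the abbreviation map; taking the max lets each cover the other's gap. The
alternatives (`jaccard`, `embedding`, `mean`) are one config field away.

Alignment is **single-linkage clustering within entity type** at threshold
τ = 0.85 — types never merge, because a symptom and a disease may share a
surface. Single linkage (rather than centroids) matches the pairwise
"corresponding entities" framing of threshold-based alignment. The
canonical surface of a cluster is its modal member surface with a
lexicographic tie-break, so output is deterministic. Pairs scoring in
[τ − 0.15, τ) go to a review queue exported as TSV; the 0.15 band is
package plumbing (wide enough to catch borderline lexical variants, narrow
enough not to flood a reviewer) and the queue never blocks the pipeline.
Thresholds above 1 are deliberately legal: they express "merge nothing" and
are used by the threshold-sweep diagnostics.

Concept linking prefers exact normalized match on a dictionary name or
synonym, then the best combined similarity ≥ τ, else no link — the original
surface is retained rather than force-mapped. The bundled dictionary
(`data/mini_concepts_synthetic.tsv`) is a ~50-concept **synthetic**
stand-in for a licensed terminology: `C0020538` (Hypertensive disease) is
the documented reference mapping; the `C90xxxxx` identifiers are
deliberately outside any real CUI range.

## Graph

Node identity is the linked concept id when a cluster is linked, else the
cluster's normalized canonical surface, always paired with the entity type
(so unlinked homonyms of different types never collapse). Edges are
directed and keyed by canonical relation. **Edge weight = number of
distinct supporting documents** (provenance is the sorted document list);
repeated assertions inside one document count once. This reading makes
"top edges by weight" a cross-document prevalence ranking, which is what
clinical frequency queries intend; a raw per-instance count ships behind
`dedup_per_doc=False`, and `stats()` reports both merged-edge and instance
counts since "number of relationships" can mean either. Ranking ties break
lexicographically on (source, target) for total determinism.

Subgraph retrieval matches seeds by fusion normalization + exact equality
against node names/ids, then takes the induced subgraph within an
undirected hop radius; radius 0 returns matched nodes only, with no edges.

## Evaluation

Entity matching is a one-to-one assignment: strict = same document, type
and span (or identical normalized surface when spans are absent); relaxed =
≥1 character of span overlap (or normalized-surface containment). The
default assignment is greedy in document order with gold order as the
tie-break; a maximum-cardinality bipartite assignment is available via
`assignment="optimal"`. Under strict matching the match relation is an
equivalence, so greedy is provably optimal; under relaxed containment
greedy can fall short of optimal by a match — the test suite checks that
such disagreements are rare and only ever in that direction. Micro
averaging (pooled TP/FP/FN) is the default report; gold files mixing
span-annotated and span-free mentions within one document are rejected as
protocol-ambiguous. Triple scoring is exact matching on (normalized
subject, canonical relation, normalized object, document).

BLEU: geometric mean of modified n-gram precisions up to n = 4 with the
standard brevity penalty; smoothing (add-one on zero-precision orders) is
**on by default** because unsmoothed 4-gram BLEU is degenerately zero on
short clinical answers. Tokenization for generation metrics is whitespace
after fusion normalization, with CJK characters split individually so
Chinese text scores at character granularity. ROUGE-1/2 are n-gram
precision/recall/F1; ROUGE-L uses an iterative dynamic-programming LCS
(cross-checked in tests against an independently written recursive oracle).
Two empty texts score 1 (identical emptiness); exactly one empty scores 0.

## Synthetic corpus

Documents are concatenations of instantiated sentence frames, 2–5 triples
per document (uniform), over a lexicon of ~60 sepsis-relevant surfaces in
the nine entity types; 50 documents at seed 42 are the default study
conditions, with 200 documents used for metric calibration. The variant
rate (probability a mention uses a non-canonical group surface) defaults to
0.3 — high enough that every multi-variant group is exercised at the
default corpus size, low enough that canonical surfaces stay modal.

Variant groups are constructed so the fusion defaults resolve them exactly:
abbreviation and case/punctuation variants normalize to identical strings
(similarity 1), plural/suffix variants score in [0.85, 1) through the
n-gram embedder, and all cross-group pairs within a type stay below 0.85.
A fixture-audit test asserts this structure, so a change to the lexicon or
the similarity function that breaks the separation fails loudly. A
consequence used by the threshold-sensitivity check: raising τ to 1.0
splits exactly the groups with ≥2 distinct normalized surfaces.

`corrupt_predictions` drops each gold triple with probability `p_miss` and
injects at most one spurious triple per document with probability `p_spur`,
drawn from schema-valid lexicon pairs guaranteed absent from gold — so
expected recall is 1 − p_miss and expected precision is
0.8·G / (0.8·G + 0.1·D) at the calibration settings, both checked within 3
binomial standard errors.

What the generator does **not** emulate: negation and uncertainty hedging,
coreference, temporal ordering, section structure, misspellings, nested or
discontinuous mentions, and genuinely ambiguous relation context. Passing
the closure test therefore demonstrates the *correctness of the pipeline
machinery* — parsing, validation, fusion semantics, weight bookkeeping —
not the linguistic robustness of any particular LLM on real clinical notes.
Real-model performance must be measured with the evaluation harness on
annotated real text.

## Numerical and degenerate-input conventions

* Precision/recall are 0 when their denominators are 0; F1 is 0 when
  P + R = 0 (the empty-prediction convention).
* Jaccard of two empty token sets is 1; cosine of two zero vectors is 1,
  of one zero vector 0. Identical vectors short-circuit to cosine 1 to
  avoid float round-off below the merge threshold.
* An empty document yields an empty extraction result without a backend
  call; an empty triple list builds an empty graph; a seed matching no
  node retrieves an empty subgraph. None of these are errors.
* All randomness flows through explicitly seeded `random.Random`
  instances; nothing touches the global generator.

## Known limitations

* The similarity threshold, review band and embedder dimensionality are
  fixed scalars, not learned; heavily abbreviation-laden real text will
  need an extended abbreviation map or a domain embedder.
* The concept dictionary is a test-scale synthetic stand-in, not a
  terminology service; linking quality on real text depends entirely on
  the dictionary supplied.
* The edge-list CSV export cannot represent isolated nodes (GraphML can).
* Greedy entity assignment can undercount relaxed-mode TP by one per
  pathological containment chain; use `assignment="optimal"` when exact
  maximum matching matters.
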