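# sepsiskg

A toolkit for building **sepsis knowledge graphs from clinical text with
LLM-based extraction** — and for testing every stage of such a pipeline
offline, deterministically, against a synthetic gold standard.

Sepsis care generates large volumes of unstructured narrative (admission and
discharge notes, guideline text). Turning that text into a queryable
knowledge graph takes four steps, each of which this package implements as a
library module with a thin CLI on top:

1. **Corpus handling** (`sepsiskg.corpus`) — read plain-text or JSON-lines
   document collections and deidentify them with a rule-based scrubber
   (every identifier match becomes `[REDACTED]`).
2. **Extraction** (`sepsiskg.extraction`) — render zero-/few-shot prompts
   that ask a model to return `(subject, relation, object)` triples in a
   bracketed "Triple list" dialect; parse replies tolerantly (strict JSON,
   curly quotes, surrounding prose); validate every triple against the
   ontology. Backends are pluggable: an OpenAI-compatible client, or a
   seeded **dictionary mock** with configurable miss/spurious rates so the
   whole pipeline runs without a network or an API key.
3. **Fusion** (`sepsiskg.fusion`) — normalize entity names (case,
   punctuation, abbreviations: `HF` → `heart failure`), score pairs with
   token Jaccard and a deterministic character-n-gram embedder, merge
   mentions by single-linkage **within entity type** at a similarity
   threshold **τ = 0.85**, queue near-misses for manual review, and link
   clusters to UMLS-style concepts (`hypertension` →
   `Hypertensive disease (C0020538)`).
4. **Graph** (`sepsiskg.graph`) — a directed property graph with one node
   per fused concept-and-type and one edge per `(source, relation, target)`.
   The edge weight is the **number of distinct supporting documents**, so
   ranking queries like "top complications by `r.weight`" order by
   cross-document frequency. Exports: GraphML, edge-list CSV, Cypher
   `CREATE` scripts (backtick-quoted relation names, ready for a Neo4j
   load); plus a radius-bounded subgraph retriever for graph-augmented
   generation.

The **ontology** (`sepsiskg.ontology`) fixes nine clinical entity concepts
(Diseases, Symptoms, Imaging examination, Biomarkers, Laboratory test,
Subtypes, Pathogenic mechanism, Pharmacotherapy, Surgery) and eight core
relations (complications, has symptom, recommended imaging examination, the
related biomarkers, treat, recommended laboratory tests, caused by,
recommended medication), with an alias table mapping every prompt label
(`Clinical Presentation` → `has symptom`, `Medication` →
`recommended medication`, …) onto exactly one canonical relation.

The **evaluation harness** (`sepsiskg.evaluation`) scores extraction with
TP/FP/FN-based precision, recall and F1 — per type and micro-averaged,
strict or relaxed matching, greedy or optimal one-to-one assignment — and
generated answers with BLEU and ROUGE-1/2/L.

The **synthetic corpus generator** (`sepsiskg.simulate`) produces seeded
clinical narratives with known gold mentions, triples and gold graph, so the
repository's central claim is executable: *a perfect extractor plus correct
fusion reproduces the gold graph exactly.*

## Worked example

```bash
python examples/01_end_to_end_graph.py
```

prints (abridged):

```
corpus: 50 documents, 172 gold triples
extracted 172 triples, micro-F1 vs gold = 1.000
fusion: 314 mentions -> 46 concepts (17 near-miss pairs queued for review)
graph: {'nodes': 46, 'edges_merged': 138, 'edge_instances': 172, ...}
matches gold graph exactly: True
```

Reading: the 50 seeded documents assert 172 triples; the mock backend
recovers all of them (micro-F1 = 1.0); fusion collapses 314 raw mentions to
46 concepts because surface variants (`HF`/`heart failure`,
`fungal infection`/`fungal infections`) merge at τ = 0.85; the 172 assertion
instances merge into 138 weighted edges (repeats within a document never
inflate a weight); and the built graph equals the generator's gold graph
node-for-node, edge-for-edge, weight-for-weight.

`examples/04_evaluation_metrics.py` corrupts the gold standard with a 20%
miss rate and 10% spurious rate and shows micro-recall ≈ 0.8 as expected;
the other examples demonstrate prompt rendering/parsing, fusion and concept
linking, ranking queries, and exports.

The same pipeline is available as a CLI:

```bash
sepsiskg simulate --n-docs 50 --seed 42 --out sim/
sepsiskg extract --corpus sim/corpus.jsonl --backend mock \
    --mock-sentences sim/sentences.json --out extractions.jsonl
sepsiskg build-graph --extractions extractions.jsonl --out graph.graphml
sepsiskg query --graph graph.graphml --relation "has complication" --top 10
sepsiskg evaluate --gold sim/gold.jsonl --pred extractions.jsonl
```

## Layout

```
src/sepsiskg/        library (ontology, corpus, extraction, fusion, graph,
                     evaluation, simulate, annotations, cli)
src/sepsiskg/data/   bundled ontology config + synthetic mini concept dictionary
examples/            one short narrative script per capability
tests/               pytest suite (unit, property, end-to-end)
scripts/             acceptance script
docs/methods.md      models, parameters, design choices, limitations
```
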