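"""Score an imperfect extractor and a generated answer.

Corrupts the gold triples with known miss/spurious rates and shows that
micro-recall tracks 1 - p_miss; then scores a generated clinical answer
against a reference with BLEU and ROUGE-1/2/L.
"""

from sepsiskg import evaluate_generation, load_schema, score_triples
from sepsiskg.simulate import SimConfig, corrupt_predictions, generate_corpus

schema = load_schema()
gold = generate_corpus(SimConfig(n_docs=100, seed=42), schema)
preds = corrupt_predictions(gold, p_miss=0.2, p_spur=0.1, seed=7, schema=schema)

report = score_triples(gold.gold_triples, preds)
m = report.micro
print(f"gold triples: {len(gold.gold_triples)}, predictions: {len(preds)}")
print(f"micro P={m.precision:.3f} R={m.recall:.3f} F1={m.f1:.3f} "
      f"(recall expectation: 0.800)")
print("per-relation F1:")
for rel, c in sorted(report.per_type.items()):
    print(f"  {rel:35} TP={c.tp:3d} FP={c.fp:2d} FN={c.fn:2d} F1={c.f1:.3f}")

candidate = "start broad spectrum antibiotics and fluid resuscitation promptly"
reference = "prompt fluid resuscitation and broad spectrum antibiotics are recommended"
gen = evaluate_generation(candidate, reference)
print(f"\nBLEU={gen.bleu:.3f} ROUGE-1 F1={gen.rouge1.f1:.3f} "
      f"ROUGE-2 F1={gen.rouge2.f1:.3f} ROUGE-L F1={gen.rougeL.f1:.3f}")
# BLEU rewards n-gram precision of the candidate; ROUGE-L rewards the longest
# in-order overlap with the reference, so word-order changes lower it.
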