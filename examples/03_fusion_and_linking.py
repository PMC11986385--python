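"""Normalize entity names, align surface variants, link to concepts.

Demonstrates the fusion stage in isolation: abbreviation-aware
normalization, Jaccard vs n-gram-embedding similarity, threshold alignment
with a manual-review queue, and UMLS-style concept linking against the
bundled synthetic mini-dictionary.
"""

from sepsiskg import (
    EntityMention,
    FusionConfig,
    align_entities,
    combined_similarity,
    jaccard_similarity,
    link_concept,
    load_concept_dictionary,
    normalize_name,
)

for raw in ("Heart Failure", "HF", "sepsis.", "C-reactive protein"):
    print(f"normalize {raw!r:24} -> {normalize_name(raw)!r}")

cfg = FusionConfig()  # threshold 0.85, mode "max" (jaccard OR embedding)
pairs = [("septic shock", "septic shock syndrome"),
         ("fungal infection", "fungal infections"),
         ("fever", "bradycardia")]
for a, b in pairs:
    print(f"jaccard({a!r}, {b!r}) = {jaccard_similarity(a, b):.3f}   "
          f"combined = {combined_similarity(a, b, cfg):.3f}")

mentions = [
    EntityMention(doc_id="d1", surface="heart failure", etype="Diseases"),
    EntityMention(doc_id="d2", surface="HF", etype="Diseases"),
    EntityMention(doc_id="d2", surface="fungal infections", etype="Diseases"),
    EntityMention(doc_id="d3", surface="fungal infection", etype="Diseases"),
    EntityMention(doc_id="d3", surface="fever", etype="Symptoms"),
]
result = align_entities(mentions, cfg)
for c in result.clusters:
    print(f"cluster [{c.etype}] {c.canonical_surface!r}: "
          f"{sorted(m.surface for m in c.mentions)}")

concepts = load_concept_dictionary()  # synthetic stand-in dictionary
linked = link_concept("hypertension", concepts)
print(f"link 'hypertension' -> {linked.canonical_name} ({linked.concept_id})")
print(f"link 'qi deficiency pattern' -> {link_concept('qi deficiency pattern', concepts)}")
# Below-threshold surfaces stay unlinked: the original value is retained
# rather than force-mapped to the nearest concept.
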