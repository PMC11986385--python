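"""Render extraction prompts and parse a model-style triple response.

Shows the zero-shot prompt layout (instruction, relation labels, sentence
slot), tolerant parsing of the bracketed "Triple list" response dialect —
curly quotes and surrounding prose included — and ontology validation with
relation canonicalization.
"""

from sepsiskg import (
    Document,
    PromptTemplate,
    Triple,
    load_schema,
    parse_triple_response,
    render_prompt,
    validate_triple,
)

doc = Document(doc_id="demo", text="Sepsis presented with tachypnea and fever.")
prompt = render_prompt(doc, PromptTemplate())
print("--- zero-shot prompt (first 300 chars) ---")
print(prompt[:300], "...\n")

response = (
    "Sure! Here is the extraction:\n"
    "“Triple list”: [[“AHF”, “Complications”, “sinus bradycardia”], "
    "[“AHF”, “Complications”, “fungal infection”], "
    "[“Fungal infection”, “Biomarker”, “Candida albicans”]]"
)
parsed = parse_triple_response(response)
print(f"parsed {len(parsed.triples)} triples (parse_failed={parsed.parse_failed})")

schema = load_schema()
for subj, rel, obj in parsed.triples:
    verdict = validate_triple(
        Triple(subject=subj, relation=rel, object=obj, doc_id="demo"), schema
    )
    print(f"  ({subj}, {rel}, {obj}) -> "
          f"{'accept as ' + verdict.canonical_relation if verdict.accepted else verdict.reasons}")
# Prompt-dialect labels ("Complications", "Biomarker") map onto the canonical
# relation set; off-schema or self-loop triples would be rejected with codes.
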