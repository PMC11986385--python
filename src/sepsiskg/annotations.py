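"""JSON-lines I/O for gold annotations and extraction results.

Gold annotation dialect: one record per document,
``{"doc_id": ..., "mentions": [...], "triples": [...]}`` with mentions as
``{surface, etype, span?}`` and triples as ``[subject, relation, object]``.
Extraction results serialize the full :class:`ExtractionResult` payload.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

from .errors import CorpusError
from .models import EntityMention, ExtractionResult, Triple


def write_gold_jsonl(
    mentions: Sequence[EntityMention],
    triples: Sequence[Triple],
    path: Union[str, Path],
) -> None:
    doc_ids: list[str] = []
    seen: set[str] = set()
    for x in [*mentions, *triples]:
        if x.doc_id not in seen:
            seen.add(x.doc_id)
            doc_ids.append(x.doc_id)
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc_id in doc_ids:
            rec = {
                "doc_id": doc_id,
                "mentions": [
                    {"surface": m.surface, "etype": m.etype,
                     **({"span": list(m.span)} if m.span else {})}
                    for m in mentions if m.doc_id == doc_id
                ],
                "triples": [
                    [t.subject, t.relation, t.object]
                    for t in triples if t.doc_id == doc_id
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_gold_jsonl(
    path: Union[str, Path],
) -> tuple[list[EntityMention], list[Triple]]:
    mentions: list[EntityMention] = []
    triples: list[Triple] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed record: {exc}") from exc
            doc_id = rec["doc_id"]
            for m in rec.get("mentions", []):
                mentions.append(
                    EntityMention(
                        doc_id=doc_id, surface=m["surface"], etype=m["etype"],
                        span=tuple(m["span"]) if m.get("span") else None,
                    )
                )
            for s, r, o in rec.get("triples", []):
                triples.append(
                    Triple(subject=s, relation=r, object=o, doc_id=doc_id)
                )
    return mentions, triples


def write_extractions_jsonl(
    results: Sequence[ExtractionResult], path: Union[str, Path]
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write(r.model_dump_json() + "\n")


def read_extractions_jsonl(path: Union[str, Path]) -> list[ExtractionResult]:
    out: list[ExtractionResult] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(ExtractionResult.model_validate_json(line))
    return out
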