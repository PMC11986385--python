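"""Corpus reading/writing and rule-based deidentification.

Two on-disk dialects are supported:

* **jsonl** — one JSON record per line with fields ``doc_id``, ``text`` and
  optionally ``source`` and ``meta``; and
* **txt** — one whole document per file, ``doc_id`` taken from the file stem.

Deidentification is a regex scrubber with a conservative bundled rule set
(numeric record identifiers, phone-like digit runs, date-of-birth patterns,
an optional name list); every match is replaced by the fixed placeholder
``[REDACTED]`` so the operation is idempotent and visibly auditable.
Text is UTF-8 throughout; mixed Chinese/English narratives pass through
untouched.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence, Union

from .errors import CorpusError
from .models import Document

PLACEHOLDER = "[REDACTED]"

#: Conservative default identifier patterns. Order matters only for overlap;
#: every match is replaced by the same placeholder.
DEFAULT_SCRUB_RULES: tuple[str, ...] = (
    # record / patient identifiers introduced by a keyword
    r"(?i)(?<=\bpatient id )\d[\d-]*",
    r"(?i)(?<=\bmrn )\d[\d-]*",
    r"(?i)(?<=\bid[:#] )\d[\d-]*",
    # phone-like digit runs: long bare runs or 3-3/4-4 separated groups
    r"\b\d{7,}\b",
    r"\b\d{3}[-.]\d{3,4}[-.]\d{4}\b",
    # date-of-birth style dates
    r"\b\d{4}[-/]\d{1,2}[-/]\d{1,2}\b",
    r"\b\d{1,2}[-/]\d{1,2}[-/]\d{4}\b",
)


def compile_rules(
    rules: Sequence[str] = DEFAULT_SCRUB_RULES, names: Sequence[str] = ()
) -> list[re.Pattern]:
    """Compile scrub patterns; ``names`` adds literal, case-insensitive names."""
    if not rules and not names:
        raise ValueError("scrub rule set must be nonempty")
    compiled = [re.compile(r) for r in rules]
    compiled.extend(
        re.compile(r"(?i)\b" + re.escape(n) + r"\b") for n in names if n.strip()
    )
    return compiled


def scrub_identifiers(
    d: Document, rules: Union[Sequence[str], Sequence[re.Pattern], None] = None
) -> Document:
    """Replace every identifier-pattern match with ``[REDACTED]``.

    ``doc_id`` and ``meta`` are untouched; idempotent because the placeholder
    matches none of the bundled patterns.
    """
    if rules is None:
        patterns = compile_rules()
    else:
        patterns = [re.compile(r) if isinstance(r, str) else r for r in rules]
        if not patterns:
            raise ValueError("scrub rule set must be nonempty")
    text = d.text
    for pat in patterns:
        text = pat.sub(PLACEHOLDER, text)
    return d.model_copy(update={"text": text})


def scrub_corpus(
    docs: Iterable[Document],
    rules: Union[Sequence[str], Sequence[re.Pattern], None] = None,
) -> list[Document]:
    """Scrub every document; count and ids are preserved."""
    return [scrub_identifiers(d, rules) for d in docs]


def _read_jsonl(path: Path) -> list[Document]:
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if not isinstance(rec, dict) or "doc_id" not in rec or "text" not in rec:
                raise CorpusError(
                    f"{path}:{lineno}: record must carry doc_id and text fields"
                )
            try:
                doc = Document(
                    doc_id=str(rec["doc_id"]),
                    text=rec["text"],
                    source=rec.get("source", "emr"),
                    meta=rec.get("meta", {}),
                )
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid record: {exc}") from exc
            if doc.doc_id in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def read_corpus(
    path: Union[str, Path], fmt: str = "jsonl", source: str = "emr"
) -> list[Document]:
    """Read documents from ``path`` in file order.

    ``fmt="jsonl"`` reads one record per line; ``fmt="txt"`` reads the whole
    file as a single document whose id is the file stem. An empty jsonl file
    is a valid empty corpus.
    """
    p = Path(path)
    if not p.exists():
        raise CorpusError(f"corpus file not found: {p}")
    if fmt == "jsonl":
        return _read_jsonl(p)
    if fmt == "txt":
        text = p.read_text(encoding="utf-8")
        if not text.strip():
            raise CorpusError(f"{p}: empty plain-text document")
        return [Document(doc_id=p.stem, text=text, source=source)]
    raise ValueError(f"unknown corpus format {fmt!r}")


def write_corpus(docs: Sequence[Document], path: Union[str, Path]) -> None:
    """Write documents as JSON-lines with canonical field order."""
    p = Path(path)
    with p.open("w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"doc_id": d.doc_id, "text": d.text, "source": d.source,
                   "meta": d.meta}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
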