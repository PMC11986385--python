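"""Low-level text normalization primitives shared across modules.

These are the building blocks behind entity-name normalization: the policy
(which steps run, which abbreviations expand) lives in
:class:`sepsiskg.fusion.NormalizationRules`; this module only supplies the
deterministic string operations.
"""

from __future__ import annotations

import re
import unicodedata

_WS_RE = re.compile(r"\s+")


def is_punctuation(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def strip_punctuation(s: str) -> str:
    """Replace every Unicode punctuation character with a space.

    Replacing (rather than deleting) keeps token boundaries: "IL-6" becomes
    "IL 6", not "IL6", so token-level operations stay stable.
    """
    return "".join(" " if is_punctuation(ch) else ch for ch in s)


def collapse_whitespace(s: str) -> str:
    return _WS_RE.sub(" ", s).strip()


def basic_normalize(s: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace.

    The abbreviation-free core of entity-name normalization; used wherever a
    cheap canonical form is needed without a rules object (e.g. self-loop
    detection during triple validation, seed matching in subgraph retrieval).
    """
    return collapse_whitespace(strip_punctuation(s.lower()))


def tokens(s: str) -> list[str]:
    """Whitespace tokens of the basic-normalized string."""
    norm = basic_normalize(s)
    return norm.split(" ") if norm else []
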