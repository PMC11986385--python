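"""Knowledge fusion: normalize entity names, align variants, link concepts.

Fusion turns raw extracted surfaces ("Heart Failure", "HF", "heart failure.")
into merged concept clusters before graph construction:

1. **Normalization** — unify letter case, strip punctuation, collapse
   whitespace, expand abbreviations (``HF`` → ``heart failure``).
2. **Similarity** — token Jaccard plus a deterministic character-n-gram
   hashing embedder (cosine rescaled to [0, 1]); the default combination is
   ``max`` so either a lexical or an embedding signal can license a merge.
3. **Alignment** — single-linkage clustering within each entity type at a
   similarity threshold (default 0.85); near-miss pairs just below the
   threshold go to a manual review queue instead of being merged.
4. **Concept linking** — clusters are mapped to canonical concepts in a
   UMLS-style dictionary (CUI, canonical name, TUIs, synonyms); below the
   threshold the original surface is retained rather than force-linked.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

import numpy as np
import zlib
from pydantic import BaseModel, Field, PrivateAttr, field_validator, model_validator

from .errors import ConfigurationError
from .models import EntityMention
from .textnorm import basic_normalize, collapse_whitespace, strip_punctuation

#: Default clinical abbreviation expansions. Keys are matched case-insensitively
#: as whole tokens after punctuation stripping; expansions must not themselves
#: contain keys (enforced), which keeps normalization idempotent.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "hf": "heart failure",
    "ahf": "acute heart failure",
    "ards": "acute respiratory distress syndrome",
    "aki": "acute kidney injury",
    "dic": "disseminated intravascular coagulation",
    "uti": "urinary tract infection",
    "pct": "procalcitonin",
    "crp": "c reactive protein",
    "wbc": "white blood cell",
    "bp": "blood pressure",
}


class NormalizationRules(BaseModel):
    lowercase: bool = True
    strip_punctuation: bool = True
    whitespace_collapse: bool = True
    abbreviation_map: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_ABBREVIATIONS)
    )

    @model_validator(mode="after")
    def _expansions_stable(self) -> "NormalizationRules":
        keys = {k.lower() for k in self.abbreviation_map}
        for k, v in self.abbreviation_map.items():
            if any(tok in keys for tok in v.lower().split()):
                raise ValueError(
                    f"expansion of {k!r} contains another abbreviation key; "
                    "normalization would not be idempotent"
                )
        return self


DEFAULT_RULES = NormalizationRules()


def normalize_name(raw: str, rules: NormalizationRules = DEFAULT_RULES) -> str:
    """Normalize an entity name: case → punctuation → whitespace → abbreviations.

    Deterministic and idempotent (expansions are validated not to re-expand).
    """
    s = raw
    if rules.lowercase:
        s = s.lower()
    if rules.strip_punctuation:
        s = strip_punctuation(s)
    if rules.whitespace_collapse:
        s = collapse_whitespace(s)
    else:
        s = s.strip()
    if rules.abbreviation_map:
        amap = {k.lower(): v for k, v in rules.abbreviation_map.items()}
        toks = s.split(" ") if s else []
        s = " ".join(amap.get(t, t) for t in toks)
        if rules.whitespace_collapse:
            s = collapse_whitespace(s)
    return s


def jaccard_similarity(
    a: str, b: str, rules: NormalizationRules = DEFAULT_RULES
) -> float:
    """Token Jaccard over normalized word tokens; two empty strings score 1."""
    ta = set(normalize_name(a, rules).split()) - {""}
    tb = set(normalize_name(b, rules).split()) - {""}
    if not ta and not tb:
        return 1.0
    return len(ta & tb) / len(ta | tb)


class Embedder(Protocol):
    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


class HashingNgramEmbedder:
    """Deterministic character-n-gram hashing embedder.

    Counts character n-grams (default 2–4, space-padded) of the normalized
    string into a fixed-width vector via CRC32 hashing. No model download, no
    randomness; a real biomedical embedder can be dropped in behind the same
    ``embed`` protocol.
    """

    def __init__(self, dim: int = 256, ngram_range: tuple[int, int] = (2, 4)):
        self.dim = dim
        self.ngram_range = ngram_range

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        padded = f" {text} "
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                gram = padded[i : i + n]
                vec[zlib.crc32(gram.encode("utf-8")) % self.dim] += 1.0
        return vec


def get_embedder(embedder_id: str) -> Embedder:
    if embedder_id == "char-ngram":
        return HashingNgramEmbedder()
    raise ConfigurationError(
        f"no bundled embedder {embedder_id!r}; pass an Embedder instance"
    )


def _rescaled_cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine mapped to [0, 1] via (1 + cos)/2; cosine can be negative."""
    if np.array_equal(u, v):
        return 1.0  # exact, avoiding float round-off on identical vectors
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 and nv == 0.0:
        return 1.0
    if nu == 0.0 or nv == 0.0:
        return 0.0
    cos = float(np.dot(u, v) / (nu * nv))
    return (1.0 + max(-1.0, min(1.0, cos))) / 2.0


class FusionConfig(BaseModel):
    threshold: float = 0.85
    similarity_mode: str = "max"
    embedder_id: str = "char-ngram"
    review_band: float = 0.15

    @field_validator("threshold")
    @classmethod
    def _threshold_range(cls, v: float) -> float:
        # values above 1 are permitted: they express "merge nothing", used by
        # threshold-sweep diagnostics
        if v < 0.0:
            raise ValueError("threshold must be non-negative")
        return v

    @field_validator("similarity_mode")
    @classmethod
    def _mode_known(cls, v: str) -> str:
        if v not in ("jaccard", "embedding", "max", "mean"):
            raise ValueError(f"unknown similarity mode {v!r}")
        return v


def combined_similarity(
    a: str,
    b: str,
    cfg: FusionConfig,
    embedder: Optional[Embedder] = None,
    rules: NormalizationRules = DEFAULT_RULES,
) -> float:
    """Symmetric similarity in [0, 1] under the configured combination mode."""
    jac = jaccard_similarity(a, b, rules)
    if cfg.similarity_mode == "jaccard":
        return jac
    if embedder is None:
        embedder = get_embedder(cfg.embedder_id)
    na, nb = normalize_name(a, rules), normalize_name(b, rules)
    emb = _rescaled_cosine(embedder.embed(na), embedder.embed(nb))
    if cfg.similarity_mode == "embedding":
        return emb
    if cfg.similarity_mode == "max":
        return max(jac, emb)
    return (jac + emb) / 2.0


class CanonicalConcept(BaseModel):
    """A dictionary concept: CUI-style id, canonical name, TUIs, synonyms."""

    concept_id: str
    canonical_name: str
    tuis: list[str] = Field(default_factory=list)
    synonyms: list[str] = Field(default_factory=list)

    @field_validator("concept_id", "canonical_name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("must be nonempty")
        return v


class Cluster(BaseModel):
    """One aligned group of mentions with an elected canonical surface."""

    etype: str
    mentions: list[EntityMention]
    canonical_surface: str
    normalized_surface: str
    concept: Optional[CanonicalConcept] = None
    _forms: set = PrivateAttr(default_factory=set)

    @property
    def forms(self) -> set:
        """Normalized member surfaces (for surface→cluster lookup)."""
        return self._forms

    @property
    def node_id(self) -> str:
        """Graph node identity: concept id when linked, else normalized surface."""
        return self.concept.concept_id if self.concept else self.normalized_surface


class ReviewPair(BaseModel):
    """A near-miss pair left unmerged, queued for manual review."""

    surface_a: str
    surface_b: str
    etype: str
    score: float


class AlignmentResult(BaseModel):
    clusters: list[Cluster]
    review_queue: list[ReviewPair] = Field(default_factory=list)

    def assert_partition(self, mentions: Sequence[EntityMention]) -> None:
        """Every input mention sits in exactly one cluster."""
        placed = [id(m) for c in self.clusters for m in c.mentions]
        if len(placed) != len(mentions) or set(placed) != {id(m) for m in mentions}:
            raise AssertionError("clusters do not partition the input mentions")

    def cluster_of(self, surface: str, etype: str,
                   rules: NormalizationRules = DEFAULT_RULES) -> Optional[Cluster]:
        norm = normalize_name(surface, rules)
        for c in self.clusters:
            if c.etype == etype and norm in c.forms:
                return c
        return None


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller index wins
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj


def align_entities(
    mentions: Sequence[EntityMention],
    cfg: FusionConfig = FusionConfig(),
    rules: NormalizationRules = DEFAULT_RULES,
    embedder: Optional[Embedder] = None,
) -> AlignmentResult:
    """Single-linkage alignment of mentions within each entity type.

    Pairs scoring ≥ the threshold are merged (transitively); entity types
    never merge with each other. Each cluster elects the most frequent member
    surface as canonical (lexicographic tie-break). Pairs scoring just below
    the threshold (within ``review_band``) are emitted to the review queue.
    Deterministic for identical inputs and config.
    """
    if not mentions:
        return AlignmentResult(clusters=[])
    if embedder is None and cfg.similarity_mode != "jaccard":
        embedder = get_embedder(cfg.embedder_id)

    clusters: list[Cluster] = []
    review: list[ReviewPair] = []
    etypes = sorted({m.etype for m in mentions})
    for etype in etypes:
        group = [m for m in mentions if m.etype == etype]
        # similarity depends only on the normalized form, so cluster over
        # distinct normalized surfaces and map mentions back afterwards
        forms = sorted({normalize_name(m.surface, rules) for m in group})
        idx = {f: i for i, f in enumerate(forms)}
        uf = _UnionFind(len(forms))
        lo_band = cfg.threshold - cfg.review_band
        for i in range(len(forms)):
            for j in range(i + 1, len(forms)):
                score = combined_similarity(forms[i], forms[j], cfg, embedder, rules)
                if score >= cfg.threshold:
                    uf.union(i, j)
                elif score >= lo_band:
                    review.append(
                        ReviewPair(
                            surface_a=forms[i], surface_b=forms[j],
                            etype=etype, score=score,
                        )
                    )
        by_root: dict[int, list[EntityMention]] = {}
        for m in group:
            root = uf.find(idx[normalize_name(m.surface, rules)])
            by_root.setdefault(root, []).append(m)
        for root in sorted(by_root):
            members = by_root[root]
            counts: dict[str, int] = {}
            for m in members:
                counts[m.surface] = counts.get(m.surface, 0) + 1
            canonical = min(counts, key=lambda s: (-counts[s], s))
            cluster = Cluster(
                etype=etype,
                mentions=members,
                canonical_surface=canonical,
                normalized_surface=normalize_name(canonical, rules),
            )
            cluster._forms = {normalize_name(m.surface, rules) for m in members}
            clusters.append(cluster)
    result = AlignmentResult(clusters=clusters, review_queue=review)
    result.assert_partition(mentions)
    return result


# ---------------------------------------------------------------------------
# Concept linking
# ---------------------------------------------------------------------------


def bundled_dictionary_path() -> Path:
    return Path(
        str(resources.files("sepsiskg").joinpath("data/mini_concepts_synthetic.tsv"))
    )


def load_concept_dictionary(
    path: Union[str, Path, None] = None,
) -> list[CanonicalConcept]:
    """Load a concept dictionary TSV (columns: concept_id, canonical_name,
    tuis, synonyms; the last two pipe-separated). ``None`` loads the bundled
    synthetic mini-dictionary."""
    p = bundled_dictionary_path() if path is None else Path(path)
    if not p.exists():
        raise ConfigurationError(f"concept dictionary not found: {p}")
    concepts: list[CanonicalConcept] = []
    seen: set[str] = set()
    with p.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cid = row["concept_id"].strip()
            if cid in seen:
                raise ConfigurationError(f"duplicate concept_id {cid!r} in {p}")
            seen.add(cid)
            concepts.append(
                CanonicalConcept(
                    concept_id=cid,
                    canonical_name=row["canonical_name"].strip(),
                    tuis=[t for t in (row.get("tuis") or "").split("|") if t],
                    synonyms=[s for s in (row.get("synonyms") or "").split("|") if s],
                )
            )
    return concepts


def link_concept(
    surface: str,
    concepts: Sequence[CanonicalConcept],
    cfg: FusionConfig = FusionConfig(),
    rules: NormalizationRules = DEFAULT_RULES,
    embedder: Optional[Embedder] = None,
) -> Optional[CanonicalConcept]:
    """Map a canonical surface to a dictionary concept, or ``None``.

    Exact match on normalized canonical name or synonym wins; otherwise the
    best similarity ≥ the threshold wins (ties broken by concept_id);
    otherwise no link and the original surface is retained by the caller.
    """
    if not concepts:
        return None
    norm = normalize_name(surface, rules)
    exact = [
        c for c in concepts
        if norm == normalize_name(c.canonical_name, rules)
        or any(norm == normalize_name(s, rules) for s in c.synonyms)
    ]
    if exact:
        return min(exact, key=lambda c: c.concept_id)
    if embedder is None and cfg.similarity_mode != "jaccard":
        embedder = get_embedder(cfg.embedder_id)
    best: Optional[CanonicalConcept] = None
    best_score = -1.0
    for c in sorted(concepts, key=lambda c: c.concept_id):
        names = [c.canonical_name, *c.synonyms]
        score = max(
            combined_similarity(surface, n, cfg, embedder, rules) for n in names
        )
        if score > best_score:
            best, best_score = c, score
    if best is not None and best_score >= cfg.threshold:
        return best
    return None


def link_clusters(
    alignment: AlignmentResult,
    concepts: Sequence[CanonicalConcept],
    cfg: FusionConfig = FusionConfig(),
    rules: NormalizationRules = DEFAULT_RULES,
    embedder: Optional[Embedder] = None,
) -> AlignmentResult:
    """Attach dictionary concepts to every cluster (in place); returns input."""
    for cluster in alignment.clusters:
        cluster.concept = link_concept(
            cluster.canonical_surface, concepts, cfg, rules, embedder
        )
    return alignment


def export_review_queue(result: AlignmentResult, path: Union[str, Path]) -> None:
    """Write the review queue as TSV: surface_a, surface_b, type, score."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["surface_a", "surface_b", "type", "score"])
        for pair in result.review_queue:
            writer.writerow(
                [pair.surface_a, pair.surface_b, pair.etype, f"{pair.score:.6f}"]
            )
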