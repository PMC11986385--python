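"""Scoring: extraction P/R/F1 (strict/relaxed, per-type and micro) and
generation metrics (BLEU, ROUGE-1/2/L).

Entity matching follows the TP/FP/FN protocol: a prediction is a true
positive when it can be assigned one-to-one to an unused gold mention of the
same document and entity type — under *strict* matching with an identical
span (or identical normalized surface when spans are absent), under *relaxed*
matching with ≥1 character of span overlap (or normalized-surface
containment). Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean; *micro* averaging pools counts across types. The default assignment is
greedy in document order (deterministic); an optimal maximum-cardinality
assignment is available for cross-checking.

BLEU is the geometric mean of modified n-gram precisions with a brevity
penalty (smoothing on by default, since unsmoothed 4-gram BLEU is
degenerately zero on short clinical answers); ROUGE-N is n-gram recall /
precision / F1 and ROUGE-L uses the longest common subsequence.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from typing import Optional, Sequence, Union

import networkx as nx
from pydantic import BaseModel, Field

from .fusion import DEFAULT_RULES, NormalizationRules, normalize_name
from .models import EntityMention, Triple


class Counts(BaseModel):
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


class MetricsReport(BaseModel):
    """TP/FP/FN and P/R/F1 per category plus the micro average."""

    per_type: dict[str, Counts] = Field(default_factory=dict)
    matching_mode: str = "strict"

    @property
    def micro(self) -> Counts:
        return Counts(
            tp=sum(c.tp for c in self.per_type.values()),
            fp=sum(c.fp for c in self.per_type.values()),
            fn=sum(c.fn for c in self.per_type.values()),
        )

    def as_dict(self) -> dict:
        return {
            "matching_mode": self.matching_mode,
            "per_type": {k: v.as_dict() for k, v in sorted(self.per_type.items())},
            "micro": self.micro.as_dict(),
        }


# ---------------------------------------------------------------------------
# Entity matching
# ---------------------------------------------------------------------------


def _mentions_match(
    gold: EntityMention,
    pred: EntityMention,
    mode: str,
    rules: NormalizationRules,
) -> bool:
    if gold.doc_id != pred.doc_id or gold.etype != pred.etype:
        return False
    if gold.span is not None and pred.span is not None:
        gs, ge = gold.span
        ps, pe = pred.span
        if mode == "strict":
            return (gs, ge) == (ps, pe)
        return max(gs, ps) < min(ge, pe)  # >=1 character of overlap
    gn = normalize_name(gold.surface, rules)
    pn = normalize_name(pred.surface, rules)
    if mode == "strict":
        return gn == pn
    return bool(gn and pn) and (gn in pn or pn in gn)


def _check_span_protocol(gold: Sequence[EntityMention]) -> None:
    by_doc: dict[str, set[bool]] = {}
    for m in gold:
        by_doc.setdefault(m.doc_id, set()).add(m.span is not None)
    for doc_id, flags in by_doc.items():
        if len(flags) > 1:
            raise ValueError(
                f"gold for document {doc_id!r} mixes span and span-free "
                "mentions; the matching protocol is ambiguous"
            )


def match_entities(
    gold: Sequence[EntityMention],
    pred: Sequence[EntityMention],
    mode: str = "strict",
    assignment: str = "greedy",
    rules: NormalizationRules = DEFAULT_RULES,
) -> MetricsReport:
    """One-to-one gold/pred mention matching with per-type breakdown.

    ``assignment="greedy"`` (default) walks predictions in document order and
    takes the first unused matching gold (gold order is the tie-break);
    ``assignment="optimal"`` computes a maximum-cardinality bipartite
    matching instead. Greedy can fall one short of optimal only in relaxed
    mode, where the match relation is not an equivalence.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown matching mode {mode!r}")
    if assignment not in ("greedy", "optimal"):
        raise ValueError(f"unknown assignment {assignment!r}")
    _check_span_protocol(gold)

    etypes = sorted({m.etype for m in gold} | {m.etype for m in pred})
    report = MetricsReport(
        per_type={t: Counts() for t in etypes}, matching_mode=mode
    )
    doc_order = []
    seen_docs = set()
    for m in [*gold, *pred]:
        if m.doc_id not in seen_docs:
            seen_docs.add(m.doc_id)
            doc_order.append(m.doc_id)

    for doc_id in doc_order:
        g_doc = [m for m in gold if m.doc_id == doc_id]
        p_doc = [m for m in pred if m.doc_id == doc_id]
        matched_gold: set[int] = set()
        matched_pred: set[int] = set()
        if assignment == "greedy":
            for pi, pm in enumerate(p_doc):
                for gi, gm in enumerate(g_doc):
                    if gi in matched_gold:
                        continue
                    if _mentions_match(gm, pm, mode, rules):
                        matched_gold.add(gi)
                        matched_pred.add(pi)
                        report.per_type[pm.etype].tp += 1
                        break
        else:
            b = nx.Graph()
            g_nodes = [("g", i) for i in range(len(g_doc))]
            p_nodes = [("p", i) for i in range(len(p_doc))]
            b.add_nodes_from(g_nodes, bipartite=0)
            b.add_nodes_from(p_nodes, bipartite=1)
            for gi, gm in enumerate(g_doc):
                for pi, pm in enumerate(p_doc):
                    if _mentions_match(gm, pm, mode, rules):
                        b.add_edge(("g", gi), ("p", pi))
            matching = nx.bipartite.maximum_matching(b, top_nodes=g_nodes)
            for (side, gi), partner in matching.items():
                if side == "g":
                    pi = partner[1]
                    matched_gold.add(gi)
                    matched_pred.add(pi)
                    report.per_type[g_doc[gi].etype].tp += 1
        for pi, pm in enumerate(p_doc):
            if pi not in matched_pred:
                report.per_type[pm.etype].fp += 1
        for gi, gm in enumerate(g_doc):
            if gi not in matched_gold:
                report.per_type[gm.etype].fn += 1
    return report


def score_triples(
    gold: Sequence[Triple],
    pred: Sequence[Triple],
    rules: NormalizationRules = DEFAULT_RULES,
) -> MetricsReport:
    """Exact triple matching keyed by canonical relation.

    A predicted triple is a true positive iff its (normalized subject,
    canonical relation, normalized object, document) tuple equals an unused
    gold triple; counts are reported per relation with the micro average
    pooled over relations. Relations must be canonicalized on both sides.
    """

    def key(t: Triple) -> tuple[str, str, str, str]:
        return (
            normalize_name(t.subject, rules),
            t.relation,
            normalize_name(t.object, rules),
            t.doc_id,
        )

    relations = sorted({t.relation for t in gold} | {t.relation for t in pred})
    report = MetricsReport(
        per_type={r: Counts() for r in relations}, matching_mode="strict"
    )
    gold_pool = Counter(key(t) for t in gold)
    for t in pred:
        k = key(t)
        if gold_pool.get(k, 0) > 0:
            gold_pool[k] -= 1
            report.per_type[t.relation].tp += 1
        else:
            report.per_type[t.relation].fp += 1
    for (_, rel, _, _), remaining in gold_pool.items():
        report.per_type[rel].fn += remaining
    return report


# ---------------------------------------------------------------------------
# Generation metrics
# ---------------------------------------------------------------------------

_CJK_RE = re.compile(r"([㐀-鿿])")


def tokenize_for_eval(
    text: str, rules: NormalizationRules = DEFAULT_RULES
) -> list[str]:
    """Whitespace tokens after fusion normalization; CJK split per character."""
    spaced = _CJK_RE.sub(r" \1 ", text)
    norm = normalize_name(spaced, rules)
    return norm.split() if norm else []


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _as_tokens(x: Union[str, Sequence[str]]) -> list[str]:
    return tokenize_for_eval(x) if isinstance(x, str) else list(x)


def bleu_score(
    candidate: Union[str, Sequence[str]],
    references: Sequence[Union[str, Sequence[str]]],
    max_n: int = 4,
    smooth: bool = True,
) -> float:
    """BLEU in [0, 1]: geometric mean of modified n-gram precisions × brevity
    penalty. With ``smooth`` the numerator and denominator of zero-precision
    orders are incremented by one (add-one smoothing); without it any zero
    order zeroes the score. An empty candidate scores 0 by convention."""
    cand = _as_tokens(candidate)
    refs = [_as_tokens(r) for r in references]
    if not cand or not refs:
        return 0.0
    log_sum = 0.0
    orders = 0
    for n in range(1, max_n + 1):
        cand_counts = _ngrams(cand, n)
        total = sum(cand_counts.values())
        if total == 0:
            continue  # candidate shorter than n
        max_ref: Counter = Counter()
        for r in refs:
            for gram, cnt in _ngrams(r, n).items():
                max_ref[gram] = max(max_ref[gram], cnt)
        clipped = sum(min(cnt, max_ref[gram]) for gram, cnt in cand_counts.items())
        if clipped == 0:
            if not smooth:
                return 0.0
            clipped, total = clipped + 1, total + 1
        log_sum += math.log(clipped / total)
        orders += 1
    if orders == 0:
        return 0.0
    geo = math.exp(log_sum / orders)
    c = len(cand)
    r = min((len(ref) for ref in refs), key=lambda L: (abs(L - c), L))
    bp = 1.0 if c >= r else math.exp(1.0 - r / c)
    return bp * geo


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Longest common subsequence length (dynamic programming)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


class RougeTriplet(BaseModel):
    precision: float
    recall: float
    f1: float


def _prf(matched: float, cand_total: float, ref_total: float) -> RougeTriplet:
    p = matched / cand_total if cand_total else 0.0
    r = matched / ref_total if ref_total else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return RougeTriplet(precision=p, recall=r, f1=f)


def rouge_scores(
    candidate: Union[str, Sequence[str]],
    reference: Union[str, Sequence[str]],
) -> dict[str, RougeTriplet]:
    """ROUGE-1, ROUGE-2 (n-gram overlap) and ROUGE-L (LCS).

    Two empty texts score 1.0 everywhere (identical emptiness); exactly one
    empty text scores 0.
    """
    cand = _as_tokens(candidate)
    ref = _as_tokens(reference)
    if not cand and not ref:
        one = RougeTriplet(precision=1.0, recall=1.0, f1=1.0)
        return {"rouge1": one, "rouge2": one, "rougeL": one}
    out: dict[str, RougeTriplet] = {}
    for name, n in (("rouge1", 1), ("rouge2", 2)):
        cg, rg = _ngrams(cand, n), _ngrams(ref, n)
        matched = sum((cg & rg).values())
        out[name] = _prf(matched, sum(cg.values()), sum(rg.values()))
    lcs = _lcs_length(cand, ref)
    out["rougeL"] = _prf(lcs, len(cand), len(ref))
    return out


class GenerationEvalReport(BaseModel):
    bleu: float
    rouge1: RougeTriplet
    rouge2: RougeTriplet
    rougeL: RougeTriplet

    def as_dict(self) -> dict:
        return {
            "bleu": self.bleu,
            "rouge1": self.rouge1.model_dump(),
            "rouge2": self.rouge2.model_dump(),
            "rougeL": self.rougeL.model_dump(),
        }


def evaluate_generation(
    candidate: Union[str, Sequence[str]],
    reference: Union[str, Sequence[str]],
    max_n: int = 4,
    smooth: bool = True,
) -> GenerationEvalReport:
    """BLEU + ROUGE-1/2/L for one candidate/reference pair."""
    rouge = rouge_scores(candidate, reference)
    return GenerationEvalReport(
        bleu=bleu_score(candidate, [reference], max_n=max_n, smooth=smooth),
        rouge1=rouge["rouge1"],
        rouge2=rouge["rouge2"],
        rougeL=rouge["rougeL"],
    )
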