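"""Strict micro-averaged precision/recall/F1 for concepts, relations, and
negation, in the 2018-n2c2 style, with document-bootstrap standard deviations.

Strict matching: a predicted concept counts only if its character boundaries
AND category both equal a gold annotation; a relation counts only if its type
and both endpoint spans match strictly; negation is scored as binary
classification over nodule entities with "negated" as the positive class.
Micro-averaging pools TP/FP/FN over categories before computing the metrics;
all 0/0 ratios are defined as 0.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .schema import Document, NEGATED

logger = logging.getLogger(__name__)


@dataclass
class CategoryCounts:
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


@dataclass
class EvalReport:
    """Per-category and micro-pooled counts with strict-match semantics."""

    per_category: dict[str, CategoryCounts] = field(default_factory=dict)
    match_mode: str = "strict"
    sd: dict[str, float] | None = None

    @property
    def overall(self) -> CategoryCounts:
        return CategoryCounts(
            tp=sum(c.tp for c in self.per_category.values()),
            fp=sum(c.fp for c in self.per_category.values()),
            fn=sum(c.fn for c in self.per_category.values()),
        )

    @property
    def precision(self) -> float:
        return self.overall.precision

    @property
    def recall(self) -> float:
        return self.overall.recall

    @property
    def f1(self) -> float:
        return self.overall.f1

    def as_dict(self) -> dict:
        out = {
            "match_mode": self.match_mode,
            "overall": {
                "tp": self.overall.tp, "fp": self.overall.fp, "fn": self.overall.fn,
                "precision": self.precision, "recall": self.recall, "f1": self.f1,
            },
            "per_category": {
                cat: {
                    "tp": c.tp, "fp": c.fp, "fn": c.fn,
                    "precision": c.precision, "recall": c.recall, "f1": c.f1,
                }
                for cat, c in sorted(self.per_category.items())
            },
        }
        if self.sd is not None:
            out["sd"] = dict(self.sd)
        return out

    def format_table(self) -> str:
        rows = [f"{'category':<18}{'P':>8}{'R':>8}{'F1':>8}{'TP':>6}{'FP':>6}{'FN':>6}"]
        for cat, c in sorted(self.per_category.items()):
            rows.append(
                f"{cat:<18}{c.precision:>8.4f}{c.recall:>8.4f}{c.f1:>8.4f}"
                f"{c.tp:>6}{c.fp:>6}{c.fn:>6}"
            )
        o = self.overall
        rows.append(
            f"{'overall (micro)':<18}{o.precision:>8.4f}{o.recall:>8.4f}{o.f1:>8.4f}"
            f"{o.tp:>6}{o.fp:>6}{o.fn:>6}"
        )
        if self.sd:
            rows.append(
                "bootstrap SD: "
                + ", ".join(f"{k}={v:.4f}" for k, v in self.sd.items())
            )
        return "\n".join(rows)


def _check_doc_ids(gold: Sequence[Document], pred: Sequence[Document]) -> None:
    g, p = {d.doc_id for d in gold}, {d.doc_id for d in pred}
    if g != p:
        missing = sorted(g - p)
        extra = sorted(p - g)
        raise ValueError(
            f"gold/pred doc_id mismatch: missing from pred {missing}, "
            f"unexpected in pred {extra}"
        )


def _score_items(
    gold_items: Iterable[tuple],
    pred_items: Iterable[tuple],
    category_of: Callable[[tuple], str],
) -> EvalReport:
    """Exact-tuple matching with per-category micro pooling.

    Duplicate items (identical tuples) are deduplicated before scoring, so a
    doubled prediction is neither rewarded nor punished twice.
    """
    gold_set, pred_set = set(gold_items), set(pred_items)
    report = EvalReport()
    for item in gold_set | pred_set:
        cat = category_of(item)
        counts = report.per_category.setdefault(cat, CategoryCounts())
        if item in gold_set and item in pred_set:
            counts.tp += 1
        elif item in pred_set:
            counts.fp += 1
        else:
            counts.fn += 1
    return report


def _entity_items(docs: Sequence[Document]) -> list[tuple]:
    return [(d.doc_id, e.start, e.end, e.category) for d in docs for e in d.entities]


def _relation_items(docs: Sequence[Document]) -> list[tuple]:
    return [
        (d.doc_id, r.rtype, r.head.start, r.head.end, r.tail.start, r.tail.end)
        for d in docs
        for r in d.relations
    ]


def _negated_items(docs: Sequence[Document]) -> list[tuple]:
    return [
        (d.doc_id, f.entity.start, f.entity.end)
        for d in docs
        for f in d.negations
        if f.label == NEGATED
    ]


def evaluate_entities(gold: Sequence[Document], pred: Sequence[Document]) -> EvalReport:
    """Strict concept scoring: TP iff (doc, start, end, category) match."""
    _check_doc_ids(gold, pred)
    return _score_items(_entity_items(gold), _entity_items(pred), lambda it: it[3])


def evaluate_relations(gold: Sequence[Document], pred: Sequence[Document]) -> EvalReport:
    """Strict relation scoring: TP iff the type and both endpoint spans match.

    Run with predictions built on gold entities for component evaluation, or
    on predicted entities for end-to-end evaluation — the matching rule is
    identical; upstream boundary errors simply surface as FP/FN here.
    """
    _check_doc_ids(gold, pred)
    return _score_items(_relation_items(gold), _relation_items(pred), lambda it: it[1])


def evaluate_negation(gold: Sequence[Document], pred: Sequence[Document]) -> EvalReport:
    """Negation scoring with "negated" as the positive class.

    An entity's flag is a TP only when a predicted negated nodule matches a
    gold negated nodule on exact span.
    """
    _check_doc_ids(gold, pred)
    report = _score_items(
        _negated_items(gold), _negated_items(pred), lambda it: NEGATED
    )
    if not report.per_category:
        logger.warning("no negated nodules in gold or predictions; metrics are 0/0 -> 0")
        report.per_category[NEGATED] = CategoryCounts()
    return report


def evaluate_end_to_end(gold: Sequence[Document], pred: Sequence[Document]) -> EvalReport:
    """Single pooled score over all three annotation layers.

    Pools strict entity items, strict relation items, and negated-nodule
    items into one micro-averaged report, so concept, linking, and negation
    errors all propagate into a single end-to-end figure.
    """
    _check_doc_ids(gold, pred)
    def items(docs: Sequence[Document]) -> list[tuple]:
        return (
            [("entity",) + it for it in _entity_items(docs)]
            + [("relation",) + it for it in _relation_items(docs)]
            + [("negation",) + it for it in _negated_items(docs)]
        )

    return _score_items(items(gold), items(pred), lambda it: it[0])


def bootstrap_sd(
    metric_fn: Callable[[Sequence[Document], Sequence[Document]], EvalReport],
    gold: Sequence[Document],
    pred: Sequence[Document],
    n_reps: int = 20,
    seed: int = 13,
) -> dict[str, float]:
    """Document-level bootstrap standard deviation of P/R/F1.

    Resamples documents with replacement (annotations travel with their
    document), recomputes the metric per replicate, and returns the sample
    SD over ``n_reps`` replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    _check_doc_ids(gold, pred)
    if len(gold) < 2:
        logger.warning("bootstrap over a single document is unreliable")
    pred_by_id = {d.doc_id: d for d in pred}
    gold_list = list(gold)
    rng = random.Random(seed)
    samples: dict[str, list[float]] = {"precision": [], "recall": [], "f1": []}
    for rep in range(n_reps):
        chosen = [rng.choice(gold_list) for _ in gold_list]
        # re-key duplicates so doc_ids stay unique within the replicate
        g_rep, p_rep = [], []
        for i, g in enumerate(chosen):
            rep_id = f"{g.doc_id}#{i}"
            p = pred_by_id[g.doc_id]
            g_rep.append(Document(rep_id, g.text, g.entities, g.relations, g.negations))
            p_rep.append(Document(rep_id, p.text, p.entities, p.relations, p.negations))
        report = metric_fn(g_rep, p_rep)
        samples["precision"].append(report.precision)
        samples["recall"].append(report.recall)
        samples["f1"].append(report.f1)

    def sample_sd(xs: list[float]) -> float:
        m = sum(xs) / len(xs)
        return (sum((x - m) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5

    return {k: sample_sd(v) for k, v in samples.items()}


__all__ = [
    "CategoryCounts",
    "EvalReport",
    "bootstrap_sd",
    "evaluate_end_to_end",
    "evaluate_entities",
    "evaluate_negation",
    "evaluate_relations",
]
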