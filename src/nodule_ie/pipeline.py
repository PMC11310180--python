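"""End-to-end orchestration: preprocessing -> concept extraction -> relation
identification -> negation detection -> postprocessing to BRAT output.

Postprocessing performs the three-step merge: BIO predictions are converted
to entity spans, detected relations are attached to those entities, and
negation flags are attached to nodule entities; results are organized by
document id, identifiers are canonicalized (T1..Tn by start offset), and
every emitted document re-parses cleanly.

A failure in any stage skips that document with a logged error and the
batch continues; the run reports how many documents failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import brat
from .negation import predict_negation
from .ner import NerModel, predict_document
from .preprocessing import normalize_and_segment
from .relation import DEFAULT_CROSS_DISTANCE_CAP, predict_relations
from .schema import (
    NEGATED,
    NODULE,
    NON_NEGATED,
    Document,
    NegationFlag,
    Relation,
    validate_document,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cross_distance_cap: int = DEFAULT_CROSS_DISTANCE_CAP
    negation_window: int = 0
    drop_relations_of_negated: bool = False
    seed: int = 13


@dataclass
class PipelineResult:
    documents: list[Document]
    n_failed: int = 0
    counters: dict[str, int] = field(default_factory=dict)


def _canonicalize(doc: Document) -> Document:
    """Re-identify annotations in document order (T1..Tn by start offset)
    so outputs are canonical and diffable."""
    order = sorted(doc.entities, key=lambda e: (e.start, e.end, e.category))
    rename = {e.ent_id: f"T{i}" for i, e in enumerate(order, start=1)}
    entities = [replace(e, ent_id=rename[e.ent_id]) for e in order]
    by_id = {e.ent_id: e for e in entities}
    rels = sorted(doc.relations, key=lambda r: (r.head.start, r.tail.start, r.rtype))
    relations = [
        Relation(f"R{i}", r.rtype, by_id[rename[r.head.ent_id]], by_id[rename[r.tail.ent_id]])
        for i, r in enumerate(rels, start=1)
    ]
    negations = [
        NegationFlag(by_id[rename[f.entity.ent_id]], f.label)
        for f in doc.negations
        if f.entity.ent_id in rename
    ]
    return Document(doc.doc_id, doc.text, entities, relations, negations)


def assemble_output(
    ner_doc: Document,
    relations: list[Relation],
    negation_labels: dict[str, str],
    doc_id: str,
) -> Document:
    """Three-step merge of per-stage outputs into one Document.

    Relations referencing entities absent from the concept-extraction
    output (e.g. removed by BIO repair) are dropped with a warning.
    """
    if ner_doc.doc_id != doc_id:
        raise ValueError(f"doc_id mismatch: {ner_doc.doc_id!r} != {doc_id!r}")
    ent_ids = {e.ent_id for e in ner_doc.entities}
    kept = []
    for r in relations:
        if r.head.ent_id not in ent_ids or r.tail.ent_id not in ent_ids:
            logger.warning(
                "%s: dropping relation %s with missing endpoint", doc_id, r.rel_id
            )
            continue
        kept.append(r)
    negations = [
        NegationFlag(e, negation_labels.get(e.ent_id, NON_NEGATED))
        for e in ner_doc.entities
        if e.category == NODULE
    ]
    return _canonicalize(
        Document(doc_id, ner_doc.text, list(ner_doc.entities), kept, negations)
    )


def run_pipeline(
    raw_docs: list[tuple[str, str]],
    ner_model: NerModel,
    pair_classifier,
    negation_model,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full system over (doc_id, text) pairs.

    Every produced document passes :func:`validate_document`; documents
    whose processing raises are skipped and counted in ``n_failed``.
    """
    config = config or PipelineConfig()
    out: list[Document] = []
    counters = {"docs": 0, "entities": 0, "candidates": 0, "relations": 0, "negated": 0}
    n_failed = 0
    for doc_id, text in raw_docs:
        try:
            ner_doc = predict_document(ner_model, doc_id, text)
            tokens, sentences = normalize_and_segment(ner_doc.text)
            relations = (
                predict_relations(
                    ner_doc, pair_classifier, tokens, sentences,
                    max_cross_distance=config.cross_distance_cap,
                )
                if ner_doc.entities
                else []
            )
            negation_labels = {}
            for e in ner_doc.entities:
                if e.category == NODULE:
                    label, _prob = predict_negation(
                        negation_model, e, ner_doc, sentences, config.negation_window
                    )
                    negation_labels[e.ent_id] = label
            merged = assemble_output(ner_doc, relations, negation_labels, doc_id)
            if config.drop_relations_of_negated:
                negated_ids = {
                    f.entity.ent_id for f in merged.negations if f.label == NEGATED
                }
                merged.relations = [
                    r for r in merged.relations if r.head.ent_id not in negated_ids
                ]
            violations = validate_document(merged)
            if violations:
                raise ValueError("invalid pipeline output: " + "; ".join(violations))
            out.append(merged)
            counters["docs"] += 1
            counters["entities"] += len(merged.entities)
            counters["relations"] += len(merged.relations)
            counters["negated"] += sum(
                1 for f in merged.negations if f.label == NEGATED
            )
        except Exception:
            logger.exception("document %s failed; skipping", doc_id)
            n_failed += 1
    logger.info("pipeline counters: %s (failed: %d)", counters, n_failed)
    return PipelineResult(out, n_failed=n_failed, counters=counters)


def run_pipeline_to_dir(
    raw_docs: list[tuple[str, str]],
    ner_model: NerModel,
    pair_classifier,
    negation_model,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    result = run_pipeline(raw_docs, ner_model, pair_classifier, negation_model, config)
    brat.write_corpus_dir(result.documents, out_dir)
    return result


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "assemble_output",
    "run_pipeline",
    "run_pipeline_to_dir",
]
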