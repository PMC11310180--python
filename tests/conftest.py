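"""Shared fixtures: synthetic corpora and trained models.

Training is done once per session on the default-shape corpus (300 training
documents, the study-scale split) and shared across pipeline/acceptance
tests; smaller seeded corpora serve the cheap unit tests.
"""

from __future__ import annotations

import random

import pytest

from nodule_ie.negation import train_negation_classifier
from nodule_ie.ner import NerConfig, train_ner
from nodule_ie.relation import train_pair_classifier
from nodule_ie.schema import Document, Entity, NegationFlag, Relation
from nodule_ie.synth import GeneratorConfig, generate_corpus, split_documents


@pytest.fixture(scope="session")
def study_corpus():
    """433 documents so the train split holds 300 documents (273:31:90 ratio)."""
    docs, splits = generate_corpus(GeneratorConfig(n_docs=433, seed=13))
    return docs, splits


@pytest.fixture(scope="session")
def study_splits(study_corpus):
    docs, splits = study_corpus
    return split_documents(docs, splits)


@pytest.fixture(scope="session")
def trained_models(study_splits):
    """All three stages trained on the 300-document training split, seed 13."""
    train, val, _ = study_splits
    ner = train_ner(train, val, NerConfig(backend="crf", seed=13))
    rel = train_pair_classifier(train, backend="margin", seed=13)
    neg = train_negation_classifier(train, seed=13)
    return ner, rel, neg


@pytest.fixture(scope="session")
def small_corpus():
    docs, splits = generate_corpus(GeneratorConfig(n_docs=80, seed=13))
    return split_documents(docs, splits)


def perturb_predictions(docs: list[Document], seed: int) -> list[Document]:
    """Seeded noisy 'predictions': drop entities, shift boundaries, flip
    categories/labels — shared by evaluator-oracle tests."""
    rng = random.Random(seed)
    out = []
    for doc in docs:
        entities = []
        for e in doc.entities:
            r = rng.random()
            if r < 0.15:
                continue  # missed entity
            if r < 0.30 and e.end + 1 <= len(doc.text):
                e = Entity(e.ent_id, e.category, e.start, e.end + 1,
                           doc.text[e.start:e.end + 1])
            elif r < 0.40:
                cats = [c for c in
                        ("Nodule", "Site", "Laterality", "Size", "Course",
                         "Texture", "Shape") if c != e.category]
                e = Entity(e.ent_id, rng.choice(cats), e.start, e.end, e.surface)
            entities.append(e)
        spans = {e.span for e in entities}
        by_span = {e.span: e for e in entities}
        relations = []
        for r_ in doc.relations:
            if r_.head.span in spans and r_.tail.span in spans and rng.random() < 0.8:
                relations.append(
                    Relation(r_.rel_id, r_.rtype, by_span[r_.head.span],
                             by_span[r_.tail.span])
                )
        negations = []
        for f in doc.negations:
            if f.entity.span in spans and by_span[f.entity.span].category == "Nodule":
                label = f.label
                if rng.random() < 0.1:
                    label = "negated" if label == "non-negated" else "non-negated"
                negations.append(NegationFlag(by_span[f.entity.span], label))
        out.append(Document(doc.doc_id, doc.text, entities, relations, negations))
    return out
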