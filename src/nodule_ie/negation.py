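"""Negation detection for nodule mentions.

Each extracted nodule entity is classified as negated / non-negated from
its containing sentence only — wider context windows were not observed to
help for the highly conventionalized negation patterns of radiology
reports ("No pulmonary nodule", "without evidence of ...").  The target
mention is signaled to the classifier with reserved marker tokens, since a
sentence may contain several nodules.

Backends: a logistic-regression classifier with softmax probabilities and
fivefold cross-validated regularization (the trained path), and a
dependency-free trigger-word rule backend for smoke tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline

from .preprocessing import SentenceMap, normalize_and_segment
from .schema import Document, Entity, NEGATED, NODULE, NON_NEGATED

logger = logging.getLogger(__name__)

ENTITY_OPEN = "[NOD]"
ENTITY_CLOSE = "[/NOD]"


@dataclass(frozen=True)
class NegationExample:
    entity: Entity
    context: str
    label: str | None = None


def extract_context(
    entity: Entity,
    doc: Document,
    sentences: SentenceMap | None = None,
    window: int = 0,
) -> NegationExample:
    """Context sentence(s) for one nodule mention with the mention marked.

    ``window`` extra sentences on each side are concatenated when
    configured; the default is the containing sentence only.
    """
    if entity.category != NODULE:
        raise ValueError(f"negation context requested for {entity.category} entity")
    if sentences is None:
        _, sentences = normalize_and_segment(doc.text)
    si = sentences.sentence_of_char(entity.start)
    lo = max(0, si - window)
    hi = min(len(sentences) - 1, si + window)
    start = sentences.char_span(lo)[0]
    end = sentences.char_span(hi)[1]
    marked = (
        doc.text[start : entity.start]
        + f" {ENTITY_OPEN} "
        + doc.text[entity.start : entity.end]
        + f" {ENTITY_CLOSE} "
        + doc.text[entity.end : end]
    )
    return NegationExample(entity, marked.strip())


def corpus_to_examples(docs: list[Document], window: int = 0) -> list[NegationExample]:
    out = []
    for doc in docs:
        _, sentences = normalize_and_segment(doc.text)
        for e in doc.entities:
            if e.category != NODULE:
                continue
            ex = extract_context(e, doc, sentences, window)
            out.append(NegationExample(e, ex.context, doc.negation_label(e)))
    return out


class NegationClassifier(BaseEstimator):
    """Bag-of-n-grams sentence classifier with calibrated class probabilities.

    The two softmax probabilities always sum to one; the decision threshold
    is 0.5 (argmax).
    """

    def __init__(self, seed: int = 13, cv_folds: int = 5, window: int = 0):
        self.seed = seed
        self.cv_folds = cv_folds
        self.window = window

    def fit(self, contexts: list[str], y: list[str]):
        if len(set(y)) < 2:
            raise ValueError(
                "negation training data contains a single class; include both "
                "negated and non-negated nodule mentions"
            )
        pipe = Pipeline(
            [
                ("vec", CountVectorizer(ngram_range=(1, 2), lowercase=True,
                                        token_pattern=r"[^\s]+")),
                ("clf", LogisticRegression(max_iter=500, random_state=self.seed)),
            ]
        )
        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(
            pipe, {"clf__C": [0.1, 1.0, 10.0]}, cv=cv, scoring="f1_macro", n_jobs=1
        )
        search.fit(contexts, y)
        self.best_estimator_ = search.best_estimator_
        self.cv_results_ = {
            "best_params": search.best_params_,
            "best_score": float(search.best_score_),
        }
        self.classes_ = list(search.best_estimator_.classes_)
        logger.info("negation CV best %s score=%.4f",
                    search.best_params_, search.best_score_)
        return self

    def predict(self, contexts: list[str]) -> list[str]:
        return list(self.best_estimator_.predict(contexts))

    def predict_proba(self, contexts: list[str]) -> np.ndarray:
        return self.best_estimator_.predict_proba(contexts)


#: Rule backend triggers; not part of the trained protocol — a transparent
#: fallback for dependency-free smoke testing.
NEGATION_TRIGGERS = (
    "no", "without", "negative", "resolved", "absence", "free of", "neither",
)


class RuleNegationDetector(BaseEstimator):
    """Trigger-word rule: negated iff a trigger occurs in the sentence."""

    def fit(self, contexts: list[str] | None = None, y: list[str] | None = None):
        self.classes_ = [NEGATED, NON_NEGATED]
        return self

    def predict(self, contexts: list[str]) -> list[str]:
        out = []
        for c in contexts:
            lc = f" {c.lower()} "
            hit = any(f" {t} " in lc or lc.startswith(f"{t} ") for t in NEGATION_TRIGGERS)
            out.append(NEGATED if hit else NON_NEGATED)
        return out

    def predict_proba(self, contexts: list[str]) -> np.ndarray:
        pred = self.predict(contexts)
        return np.array([[1.0, 0.0] if p == NEGATED else [0.0, 1.0] for p in pred])


def train_negation_classifier(
    docs: list[Document], seed: int = 13, window: int = 0
) -> NegationClassifier:
    examples = corpus_to_examples(docs, window)
    clf = NegationClassifier(seed=seed, window=window)
    clf.fit([e.context for e in examples], [e.label for e in examples])
    return clf


def predict_negation(
    model: NegationClassifier | RuleNegationDetector,
    entity: Entity,
    doc: Document,
    sentences: SentenceMap | None = None,
    window: int = 0,
) -> tuple[str, float]:
    """(label, probability of the predicted label) for one nodule mention."""
    ex = extract_context(entity, doc, sentences, window)
    proba = model.predict_proba([ex.context])[0]
    idx = int(np.argmax(proba))
    return model.classes_[idx], float(proba[idx])


def save_negation_model(model, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"kind": type(model).__name__}
    if hasattr(model, "cv_results_"):
        meta["cv_results"] = model.cv_results_
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model, path / "model.joblib")


def load_negation_model(path: str | Path):
    return joblib.load(Path(path) / "model.joblib")


__all__ = [
    "ENTITY_CLOSE",
    "ENTITY_OPEN",
    "NEGATION_TRIGGERS",
    "NegationClassifier",
    "NegationExample",
    "RuleNegationDetector",
    "corpus_to_examples",
    "extract_context",
    "load_negation_model",
    "predict_negation",
    "save_negation_model",
    "train_negation_classifier",
]
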