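"""Concept extraction: trainable BIO sequence labelers.

Two interchangeable backends satisfy the same ``predict_tags`` contract:

``crf``
    A linear-chain conditional random field over sparse lexical features
    (word identity, shape, affixes, neighbors), trained by penalized maximum
    likelihood with L-BFGS and decoded with Viterbi, so every emitted
    sequence is transition-legal.  This is the classical pre-transformer
    sequence labeler for clinical concept extraction.

``subtoken``
    A per-sub-token classifier in the style of sub-word token-classification
    models: words are deterministically split into sub-token pieces, the
    leading piece carries the word's BIO label and non-leading pieces carry
    the auxiliary ``X`` tag, which is masked out of the training loss;
    predictions are collapsed back to word level and passed through BIO
    repair.

Both are scikit-learn-style estimators (``fit``/``predict``,
``get_params``/``set_params``) operating on lists of token-surface
sequences and BIO tag sequences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .preprocessing import (
    SentenceMap,
    Token,
    attach_surfaces,
    collapse_subtokens,
    decode_bio,
    encode_bio,
    expand_subtokens,
    normalize_and_segment,
    repair_bio,
    X_TAG,
)
from .schema import Document, Entity

logger = logging.getLogger(__name__)


@dataclass
class NerConfig:
    """Training protocol defaults.

    ``max_epochs``/``seed`` follow the historical protocol for this task
    (30 epochs, seed 13); for the convex CRF objective ``max_epochs`` is an
    L-BFGS iteration budget multiplier and ``batch_size``/``learning_rate``
    are accepted for interface compatibility but ignored (L-BFGS is
    full-batch with its own step control).
    """

    backend: str = "crf"
    word_embedding_dim: int = 100
    max_epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 1e-5
    seed: int = 13
    patience: int = 5

    def validate(self) -> None:
        if self.backend not in ("crf", "subtoken"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for name in ("word_embedding_dim", "max_epochs", "batch_size", "seed", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# feature extraction


def _shape(word: str) -> str:
    out = []
    for ch in word:
        if ch.isupper():
            c = "X"
        elif ch.islower():
            c = "x"
        elif ch.isdigit():
            c = "d"
        else:
            c = ch
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def token_features(words: list[str], i: int) -> list[str]:
    w = words[i]
    lw = w.lower()
    prev = words[i - 1].lower() if i > 0 else "<s>"
    nxt = words[i + 1].lower() if i + 1 < len(words) else "</s>"
    feats = [
        "bias",
        f"w={lw}",
        f"shape={_shape(w)}",
        f"suf3={lw[-3:]}",
        f"pre2={lw[:2]}",
        f"prev={prev}",
        f"next={nxt}",
        f"prev|w={prev}|{lw}",
        f"w|next={lw}|{nxt}",
    ]
    if w.replace(".", "").isdigit():
        feats.append("isnum")
    return feats


# ---------------------------------------------------------------------------
# linear-chain CRF


class CrfTagger(BaseEstimator):
    """Linear-chain CRF with sparse lexical features.

    Parameters
    ----------
    c2 : float
        L2 penalty weight on all parameters.
    max_iter : int
        L-BFGS iteration budget.
    seed : int
        Stored for protocol compatibility; the objective is convex and the
        optimization deterministic, so the seed does not influence the fit.
    """

    def __init__(self, c2: float = 0.1, max_iter: int = 120, seed: int = 13):
        self.c2 = c2
        self.max_iter = max_iter
        self.seed = seed

    # -- model surface ------------------------------------------------------

    def fit(self, X: list[list[str]], y: list[list[str]], extra_labels: tuple = ()):
        if not X:
            raise ValueError("empty training set")
        if any(len(s) != len(t) for s, t in zip(X, y)):
            raise ValueError("sentence/tag length mismatch")
        labels = sorted({t for ts in y for t in ts} | set(extra_labels) | {"O"})
        self.classes_ = labels
        label_index = {l: i for i, l in enumerate(labels)}

        feat_index: dict[str, int] = {}
        rows: list[list[int]] = []
        for words in X:
            for i in range(len(words)):
                idxs = []
                for f in token_features(words, i):
                    if f not in feat_index:
                        feat_index[f] = len(feat_index)
                    idxs.append(feat_index[f])
                rows.append(idxs)
        self.feature_index_ = feat_index
        F, L = len(feat_index), len(labels)

        Xmat = self._rows_to_csr(rows, F)
        lengths = np.array([len(s) for s in X if len(s) > 0], dtype=int)
        nonempty = [ts for ts in y if len(ts) > 0]
        ygold = np.concatenate(
            [np.array([label_index[t] for t in ts], dtype=int) for ts in nonempty]
        )
        self._fit_packed(Xmat, ygold, lengths, F, L)
        return self

    def predict(self, X: list[list[str]]) -> list[list[str]]:
        out = []
        for words in X:
            if not words:
                out.append([])
                continue
            emis = self._emissions(words)
            path = self.viterbi(emis, self.transitions_, self.start_)
            out.append([self.classes_[i] for i in path])
        return out

    # -- scoring primitives (shared with the brute-force oracle tests) -----

    @staticmethod
    def path_score(
        emissions: np.ndarray, transitions: np.ndarray, start: np.ndarray, path: list[int]
    ) -> float:
        s = start[path[0]] + emissions[0, path[0]]
        for i in range(1, len(path)):
            s += transitions[path[i - 1], path[i]] + emissions[i, path[i]]
        return float(s)

    @staticmethod
    def viterbi(
        emissions: np.ndarray, transitions: np.ndarray, start: np.ndarray
    ) -> list[int]:
        n, L = emissions.shape
        delta = start + emissions[0]
        back = np.zeros((n, L), dtype=int)
        for t in range(1, n):
            scores = delta[:, None] + transitions
            back[t] = np.argmax(scores, axis=0)
            delta = emissions[t] + np.max(scores, axis=0)
        path = [int(np.argmax(delta))]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _rows_to_csr(rows: list[list[int]], n_feats: int) -> sparse.csr_matrix:
        indptr = np.zeros(len(rows) + 1, dtype=int)
        indices = []
        for i, r in enumerate(rows):
            indices.extend(r)
            indptr[i + 1] = len(indices)
        data = np.ones(len(indices))
        return sparse.csr_matrix(
            (data, np.array(indices, dtype=int), indptr), shape=(len(rows), n_feats)
        )

    def _emissions(self, words: list[str]) -> np.ndarray:
        rows = []
        for i in range(len(words)):
            rows.append(
                [self.feature_index_[f] for f in token_features(words, i)
                 if f in self.feature_index_]
            )
        Xmat = self._rows_to_csr(rows, len(self.feature_index_))
        return np.asarray(Xmat @ self.weights_.T)

    def _fit_packed(
        self, Xmat: sparse.csr_matrix, ygold: np.ndarray, lengths: np.ndarray,
        F: int, L: int,
    ) -> None:
        S = len(lengths)
        Tmax = int(lengths.max())
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        N = int(offsets[-1])
        # index of the flat token at (sentence, position), -1 when padded
        pos_index = -np.ones((S, Tmax), dtype=int)
        for s in range(S):
            pos_index[s, : lengths[s]] = np.arange(offsets[s], offsets[s + 1])
        valid = pos_index >= 0
        safe = np.where(valid, pos_index, 0)
        onehot = np.zeros((N, L))
        onehot[np.arange(N), ygold] = 1.0
        emp_emit = Xmat.T @ onehot  # (F, L)
        emp_start = np.zeros(L)
        emp_trans = np.zeros((L, L))
        for s in range(S):
            seq = ygold[offsets[s] : offsets[s + 1]]
            emp_start[seq[0]] += 1
            np.add.at(emp_trans, (seq[:-1], seq[1:]), 1.0)
        gold_emit_score_idx = (np.arange(N), ygold)

        def unpack(w):
            W = w[: L * F].reshape(L, F)
            T = w[L * F : L * F + L * L].reshape(L, L)
            b = w[L * F + L * L :]
            return W, T, b

        def objective(w):
            W, T, b = unpack(w)
            emis_flat = np.asarray(Xmat @ W.T)  # (N, L)
            emis = np.zeros((S, Tmax, L))
            emis[valid] = emis_flat[safe[valid]]
            # forward
            A = np.full((S, Tmax, L), -np.inf)
            A[:, 0, :] = b + emis[:, 0, :]
            for t in range(1, Tmax):
                act = lengths > t
                if not act.any():
                    break
                prev = A[act, t - 1, :]
                A[act, t, :] = emis[act, t, :] + logsumexp(
                    prev[:, :, None] + T[None, :, :], axis=1
                )
            last = lengths - 1
            logZ = logsumexp(A[np.arange(S), last, :], axis=1)
            # backward
            B = np.zeros((S, Tmax, L))
            for t in range(Tmax - 2, -1, -1):
                act = lengths > t + 1
                if not act.any():
                    continue
                nxt = emis[act, t + 1, :] + B[act, t + 1, :]
                B[act, t, :] = logsumexp(T[None, :, :] + nxt[:, None, :], axis=2)
            gamma = np.exp(A + B - logZ[:, None, None])  # (S, Tmax, L)
            gamma_flat = np.zeros((N, L))
            gamma_flat[pos_index[valid]] = gamma[valid]
            # pairwise expectations
            exp_trans = np.zeros((L, L))
            for t in range(Tmax - 1):
                act = lengths > t + 1
                if not act.any():
                    break
                xi = (
                    A[act, t, :, None]
                    + T[None, :, :]
                    + (emis[act, t + 1, :] + B[act, t + 1, :])[:, None, :]
                    - logZ[act, None, None]
                )
                exp_trans += np.exp(xi).sum(axis=0)
            gold_score = (
                float(emis_flat[gold_emit_score_idx].sum())
                + float((emp_trans * T).sum())
                + float((emp_start * b).sum())
            )
            nll = float(logZ.sum()) - gold_score
            dW = ((Xmat.T @ gamma_flat) - emp_emit).T  # (L, F)
            dT = exp_trans - emp_trans
            first = pos_index[:, 0]
            db = gamma_flat[first].sum(axis=0) - emp_start
            grad = np.concatenate([dW.ravel(), dT.ravel(), db])
            nll += self.c2 * float(w @ w)
            grad += 2.0 * self.c2 * w
            return nll, grad

        w0 = np.zeros(L * F + L * L + L)
        res = minimize(
            objective, w0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        W, T, b = unpack(res.x)
        self.weights_ = W
        self.transitions_ = T
        self.start_ = b
        self.n_iter_ = int(res.nit)


# ---------------------------------------------------------------------------
# sub-token classifier backend


def subtokenize(word: str) -> list[str]:
    """Deterministic sub-word split: a leading 4-character piece followed by
    3-character continuation pieces (mimicking fixed-vocabulary sub-word
    tokenizers; short words stay whole)."""
    if len(word) <= 4:
        return [word]
    pieces = [word[:4]]
    rest = word[4:]
    for i in range(0, len(rest), 3):
        pieces.append("##" + rest[i : i + 3])
    return pieces


class SubtokenTagger(BaseEstimator):
    """Per-sub-token BIO classifier with X-masked loss.

    Words are split by :func:`subtokenize`; word tags are expanded so
    non-leading pieces carry ``X``, which is excluded from the training
    loss.  At prediction time every piece is classified, word labels are
    taken from leading pieces (:func:`collapse_subtokens`), and the result
    passes through BIO repair.
    """

    def __init__(self, C: float = 10.0, max_iter: int = 200, seed: int = 13):
        self.C = C
        self.max_iter = max_iter
        self.seed = seed

    @staticmethod
    def _piece_features(words: list[str], i: int, piece: str, j: int) -> dict:
        feats = {
            f"piece={piece.lower()}": 1.0,
            f"word={words[i].lower()}": 1.0,
            f"shape={_shape(words[i])}": 1.0,
            f"prev={words[i - 1].lower() if i > 0 else '<s>'}": 1.0,
            f"next={words[i + 1].lower() if i + 1 < len(words) else '</s>'}": 1.0,
            f"lead={j == 0}": 1.0,
        }
        return feats

    def fit(self, X: list[list[str]], y: list[list[str]], extra_labels: tuple = ()):
        if not X:
            raise ValueError("empty training set")
        feats, labels = [], []
        for words, tags in zip(X, y):
            counts = [len(subtokenize(w)) for w in words]
            sub_tags = expand_subtokens(list(tags), counts)
            k = 0
            for i, w in enumerate(words):
                for j, piece in enumerate(subtokenize(w)):
                    if sub_tags[k] != X_TAG:  # X masked out of the loss
                        feats.append(self._piece_features(words, i, piece, j))
                        labels.append(sub_tags[k])
                    k += 1
        self._vec = DictVectorizer()
        Xmat = self._vec.fit_transform(feats)
        all_labels = sorted(set(labels) | set(extra_labels) | {"O"})
        self._clf = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.seed
        )
        self._clf.fit(Xmat, labels)
        self.classes_ = all_labels
        return self

    def predict(self, X: list[list[str]]) -> list[list[str]]:
        out = []
        for words in X:
            if not words:
                out.append([])
                continue
            counts = [len(subtokenize(w)) for w in words]
            feats = [
                self._piece_features(words, i, piece, j)
                for i, w in enumerate(words)
                for j, piece in enumerate(subtokenize(w))
            ]
            sub_pred = list(self._clf.predict(self._vec.transform(feats)))
            out.append(repair_bio(collapse_subtokens(sub_pred, counts)))
        return out


# ---------------------------------------------------------------------------
# corpus-level training / prediction surface


@dataclass
class NerModel:
    """A fitted tagger plus its label alphabet and training configuration."""

    backend: str
    estimator: object
    labels: list[str]
    config: NerConfig
    val_f1: float | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(
            json.dumps(
                {"backend": self.backend, "labels": self.labels,
                 "val_f1": self.val_f1, "config": asdict(self.config)},
                indent=2,
            )
        )
        joblib.dump(self.estimator, path / "model.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "NerModel":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        estimator = joblib.load(path / "model.joblib")
        return cls(
            backend=meta["backend"],
            estimator=estimator,
            labels=meta["labels"],
            config=NerConfig(**meta["config"]),
            val_f1=meta.get("val_f1"),
        )


def corpus_to_bio(docs: list[Document]) -> tuple[list[list[str]], list[list[str]]]:
    """Gold documents -> per-sentence word and BIO tag sequences."""
    X, y = [], []
    for doc in docs:
        tokens, sentences = normalize_and_segment(doc.text)
        sent_tokens, sent_tags = encode_bio(doc, tokens, sentences)
        for toks, tags in zip(sent_tokens, sent_tags):
            X.append([t.surface for t in toks])
            y.append(tags)
    return X, y


def _make_estimator(config: NerConfig):
    if config.backend == "crf":
        # iteration budget scales with the epoch setting (30 epochs -> 120)
        return CrfTagger(c2=0.1, max_iter=4 * config.max_epochs, seed=config.seed)
    return SubtokenTagger(max_iter=10 * config.max_epochs, seed=config.seed)


def train_ner(
    train_docs: list[Document],
    val_docs: list[Document],
    config: NerConfig | None = None,
) -> NerModel:
    """Train a concept-extraction model and report validation strict F1.

    A label present in validation but absent from training is retained in
    the alphabet with a warning.
    """
    from .evaluation import evaluate_entities  # local import avoids a cycle

    config = config or NerConfig()
    config.validate()
    if not train_docs:
        raise ValueError("empty training set")
    if not val_docs:
        raise ValueError("validation set must be non-empty")
    X_train, y_train = corpus_to_bio(train_docs)
    X_val, y_val = corpus_to_bio(val_docs)
    train_labels = {t for ts in y_train for t in ts}
    val_labels = {t for ts in y_val for t in ts}
    missing = val_labels - train_labels
    if missing:
        logger.warning("labels present only in validation: %s", sorted(missing))
    estimator = _make_estimator(config)
    estimator.fit(X_train, y_train, extra_labels=tuple(sorted(missing)))
    model = NerModel(
        backend=config.backend,
        estimator=estimator,
        labels=list(estimator.classes_),
        config=config,
    )
    pred_val = [predict_document(model, d.doc_id, d.text) for d in val_docs]
    model.val_f1 = evaluate_entities(val_docs, pred_val).f1
    logger.info("NER backend=%s validation strict F1 = %.4f", config.backend, model.val_f1)
    return model


def predict_tags(
    model: NerModel, tokens: list[Token], sentences: SentenceMap
) -> list[list[str]]:
    """One BIO label per token, per sentence, after sub-token collapse."""
    sent_words: list[list[str]] = [[] for _ in range(len(sentences))]
    for t in tokens:
        sent_words[t.sent_index].append(t.surface)
    return model.estimator.predict(sent_words)


def predict_document(model: NerModel, doc_id: str, text: str) -> Document:
    """Run concept extraction on raw text, returning an entities-only Document."""
    from .schema import normalize_newlines

    text = normalize_newlines(text)
    tokens, sentences = normalize_and_segment(text)
    if not tokens:
        return Document(doc_id, text)
    tags = predict_tags(model, tokens, sentences)
    flat_tags = [tag for sent in tags for tag in sent]
    entities = attach_surfaces(decode_bio(flat_tags, tokens), text)
    return Document(doc_id, text, entities=entities)


__all__ = [
    "CrfTagger",
    "NerConfig",
    "NerModel",
    "SubtokenTagger",
    "corpus_to_bio",
    "predict_document",
    "predict_tags",
    "subtokenize",
    "token_features",
    "train_ner",
]
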