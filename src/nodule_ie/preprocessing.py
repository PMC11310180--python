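"""Tokenization, sentence segmentation, and BIO tag-sequence conversion.

Radiology reports are not standard prose — they mix short narrative
sentences with section headers ("FINDINGS:") and list-like lines — so both
the tokenizer and the sentence splitter are deterministic rule sets rather
than learned models, and the rules are documented here because the relation
module's cross-distance depends on sentence boundaries.

Tokenizer rules: maximal runs of letters; maximal runs of digits with an
internal decimal point ("1.2" is one token, "4mm" splits into "4" + "mm");
every other non-whitespace character is its own token.  Offsets always index
the original text — segmentation never rewrites characters.

Sentence rules: a boundary falls after a sentence-terminal token (. ! ?),
after a header colon followed by a line break, and at any blank or new line
between tokens.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

from .schema import Document, Entity, CATEGORIES

logger = logging.getLogger(__name__)

TOKEN_RE = re.compile(r"[A-Za-z]+|\d+(?:\.\d+)?|[^\sA-Za-z0-9]")
_TERMINAL = {".", "!", "?"}

#: Word-level BIO alphabet over the seven concept categories.
BIO_LABELS: tuple[str, ...] = ("O",) + tuple(
    f"{b}-{c}" for c in CATEGORIES for b in ("B", "I")
)
X_TAG = "X"


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    sent_index: int = 0


@dataclass(frozen=True)
class Sentence:
    sent_index: int
    first_token: int
    last_token: int  # inclusive
    start: int
    end: int


class SentenceMap:
    """Sentence spans over a token sequence, with char->sentence lookup."""

    def __init__(self, sentences: list[Sentence]):
        self.sentences = sentences

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __getitem__(self, i: int) -> Sentence:
        return self.sentences[i]

    def sentence_of_char(self, offset: int) -> int:
        """Sentence index containing a character offset.

        Offsets in inter-sentence whitespace are attached to the preceding
        sentence; an entity spanning a boundary is assigned to the sentence
        containing its first character.
        """
        for s in self.sentences:
            if offset < s.end:
                return s.sent_index
        return self.sentences[-1].sent_index if self.sentences else 0

    def char_span(self, sent_index: int) -> tuple[int, int]:
        s = self.sentences[sent_index]
        return (s.start, s.end)


def normalize_and_segment(text: str) -> tuple[list[Token], SentenceMap]:
    """Tokenize and sentence-split; offsets index the original text.

    Empty or all-whitespace text yields an empty token list and an empty
    sentence map.
    """
    raw = [(m.group(), m.start(), m.end()) for m in TOKEN_RE.finditer(text)]
    if not raw:
        return [], SentenceMap([])

    # boundary AFTER token i?
    boundaries: list[bool] = []
    for i, (surface, start, end) in enumerate(raw):
        if i == len(raw) - 1:
            boundaries.append(True)
            continue
        gap = text[end : raw[i + 1][1]]
        if surface in _TERMINAL:
            boundaries.append(True)
        elif "\n" in gap:
            boundaries.append(True)
        else:
            boundaries.append(False)

    tokens: list[Token] = []
    sentences: list[Sentence] = []
    sent_index = 0
    first = 0
    for i, (surface, start, end) in enumerate(raw):
        tokens.append(Token(surface, start, end, sent_index))
        if boundaries[i]:
            sentences.append(
                Sentence(sent_index, first, i, tokens[first].start, end)
            )
            sent_index += 1
            first = i + 1
    return tokens, SentenceMap(sentences)


def _resolve_overlaps(entities: list[Entity]) -> list[Entity]:
    """Drop overlapping gold spans: keep the longer span, ties -> earlier."""
    chosen: list[Entity] = []
    for e in sorted(entities, key=lambda e: (-(e.end - e.start), e.start, e.ent_id)):
        if any(e.start < c.end and c.start < e.end for c in chosen):
            logger.warning("dropping overlapping entity %s (%s)", e.ent_id, e.surface)
            continue
        chosen.append(e)
    return sorted(chosen, key=lambda e: e.start)


def align_tokens(tokens: list[Token], entities: list[Entity]) -> list[Token]:
    """Split any token that an entity boundary crosses mid-token.

    Splitting is lossless (offsets preserved) and keeps strict-boundary
    evaluation faithful to gold; it is logged because it signals a
    tokenizer/annotation mismatch.
    """
    cuts: set[int] = set()
    for e in entities:
        cuts.add(e.start)
        cuts.add(e.end)
    out: list[Token] = []
    for t in tokens:
        inner = sorted(c for c in cuts if t.start < c < t.end)
        if not inner:
            out.append(t)
            continue
        logger.warning("splitting token %r at entity boundaries %s", t.surface, inner)
        edges = [t.start] + inner + [t.end]
        for a, b in zip(edges, edges[1:]):
            out.append(Token(t.surface[a - t.start : b - t.start], a, b, t.sent_index))
    return out


def encode_bio(
    doc: Document, tokens: list[Token], sentences: SentenceMap
) -> tuple[list[list[Token]], list[list[str]]]:
    """Project gold entities onto per-sentence BIO tag sequences.

    Returns ``(sentence_tokens, sentence_tags)``; the returned tokens are
    the input tokens possibly split at entity boundaries (misalignment
    policy), grouped by sentence.  The entity's leading token gets
    ``B-category``, the rest of its covered tokens ``I-category``, all other
    tokens ``O``.
    """
    entities = _resolve_overlaps(list(doc.entities))
    toks = align_tokens(tokens, entities)
    tags = ["O"] * len(toks)
    for e in entities:
        covered = [i for i, t in enumerate(toks) if t.start >= e.start and t.end <= e.end]
        if not covered:
            logger.warning("entity %s covers no tokens; skipped", e.ent_id)
            continue
        tags[covered[0]] = f"B-{e.category}"
        for i in covered[1:]:
            tags[i] = f"I-{e.category}"

    n_sent = max((t.sent_index for t in toks), default=-1) + 1
    sent_tokens: list[list[Token]] = [[] for _ in range(n_sent)]
    sent_tags: list[list[str]] = [[] for _ in range(n_sent)]
    for t, g in zip(toks, tags):
        sent_tokens[t.sent_index].append(t)
        sent_tags[t.sent_index].append(g)
    return sent_tokens, sent_tags


def repair_bio(tags: list[str]) -> list[str]:
    """CoNLL-style repair making any label sequence well-formed.

    Orphan ``I-c`` (no preceding ``B-c``/``I-c`` of the same category) is
    promoted to ``B-c``; anything outside the BIO alphabet (e.g. a stray
    sub-token ``X``) becomes ``O``.
    """
    out: list[str] = []
    prev_cat: str | None = None
    for tag in tags:
        if tag in ("O", X_TAG) or "-" not in tag:
            out.append("O")
            prev_cat = None
            continue
        marker, cat = tag.split("-", 1)
        if cat not in CATEGORIES or marker not in ("B", "I"):
            out.append("O")
            prev_cat = None
            continue
        if marker == "I" and cat != prev_cat:
            out.append(f"B-{cat}")
        else:
            out.append(tag)
        prev_cat = cat
    return out


def decode_bio(tags: list[str], tokens: list[Token]) -> list[Entity]:
    """Recover entities from a token-aligned BIO sequence.

    Applies :func:`repair_bio` first, so any sequence over the alphabet
    decodes without error.  Entity char spans run from the first covered
    token's start to the last covered token's end; identifiers are assigned
    ``T1..Tn`` in span order (callers may re-identify).
    """
    if len(tags) != len(tokens):
        raise ValueError(f"{len(tags)} tags for {len(tokens)} tokens")
    tags = repair_bio(tags)
    spans: list[tuple[int, int, str]] = []  # (first_tok, last_tok, category)
    for i, tag in enumerate(tags):
        if tag == "O":
            continue
        marker, cat = tag.split("-", 1)
        if marker == "B" or not spans or spans[-1][1] != i - 1 or spans[-1][2] != cat:
            spans.append((i, i, cat))
        else:
            spans[-1] = (spans[-1][0], i, cat)
    entities = []
    for n, (a, b, cat) in enumerate(spans, start=1):
        start, end = tokens[a].start, tokens[b].end
        entities.append(Entity(f"T{n}", cat, start, end, surface=""))
    return entities


def attach_surfaces(entities: list[Entity], text: str) -> list[Entity]:
    """Fill entity surface strings from the document text."""
    return [replace(e, surface=text[e.start : e.end]) for e in entities]


def expand_subtokens(tags: list[str], subtoken_counts: list[int]) -> list[str]:
    """Expand word-level tags to sub-token level with the ``X`` tag.

    The leading sub-token keeps the word's tag; each remaining piece gets
    ``X`` so sub-word tokenization never disturbs word-level BIO labels.
    """
    if len(tags) != len(subtoken_counts):
        raise ValueError("tags and subtoken_counts must have equal length")
    out: list[str] = []
    for tag, count in zip(tags, subtoken_counts):
        if count < 1:
            raise ValueError("subtoken count must be >= 1")
        out.append(tag)
        out.extend([X_TAG] * (count - 1))
    return out


def collapse_subtokens(model_tags: list[str], subtoken_counts: list[int]) -> list[str]:
    """Inverse of :func:`expand_subtokens`: keep each word's leading label.

    Predicted labels on non-leading pieces are discarded; a predicted ``X``
    on a leading position carries no word-level information and falls back
    to ``O`` (logged).
    """
    if len(model_tags) != sum(subtoken_counts):
        raise ValueError(
            f"{len(model_tags)} sub-token tags for {sum(subtoken_counts)} sub-tokens"
        )
    out: list[str] = []
    pos = 0
    for count in subtoken_counts:
        tag = model_tags[pos]
        if tag == X_TAG:
            logger.warning("model predicted X on a leading sub-token; using O")
            tag = "O"
        out.append(tag)
        pos += count
    return out


__all__ = [
    "BIO_LABELS",
    "Sentence",
    "SentenceMap",
    "Token",
    "X_TAG",
    "align_tokens",
    "attach_surfaces",
    "collapse_subtokens",
    "decode_bio",
    "encode_bio",
    "expand_subtokens",
    "normalize_and_segment",
    "repair_bio",
]
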