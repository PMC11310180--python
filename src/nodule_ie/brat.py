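"""Reader/writer for BRAT standoff annotation (.ann) paired with plain text.

Supported line types: ``T`` (entity), ``R`` (relation), ``A`` (attribute,
used for the ``Negation`` flag on nodule mentions).  Event (E), normalization
(N) and note (#) lines are outside the schema and are skipped with a logged
warning.  Discontinuous spans (``;``-separated fragments) are rejected: the
nodule annotation schema uses contiguous spans only.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .schema import (
    CATEGORIES,
    NEGATED,
    NODULE,
    NON_NEGATED,
    Document,
    Entity,
    NegationFlag,
    Relation,
    normalize_newlines,
    validate_document,
)

logger = logging.getLogger(__name__)


class BratParseError(ValueError):
    """Malformed standoff content; message names the offending line."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_brat(text_content: str, ann_content: str, doc_id: str = "doc") -> Document:
    """Parse a (text, .ann) pair into a validated :class:`Document`.

    Negation is encoded as an attribute line ``A# Negation T#``; nodule
    entities without the attribute default to non-negated.
    """
    text = normalize_newlines(text_content)
    entities: dict[str, Entity] = {}
    relations: list[Relation] = []
    negated_ids: list[tuple[int, str]] = []
    pending_relations: list[tuple[int, str, str, str, str]] = []

    for lineno, raw in enumerate(ann_content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise BratParseError(lineno, "entity line needs 3 tab-separated fields")
            header, surface = fields[1], fields[2]
            if ";" in header:
                raise BratParseError(
                    lineno, "discontinuous spans are not supported by this schema"
                )
            parts = header.split()
            if len(parts) != 3:
                raise BratParseError(lineno, f"malformed entity header {header!r}")
            category = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BratParseError(lineno, f"malformed offsets in {header!r}") from exc
            if category not in CATEGORIES:
                raise BratParseError(lineno, f"unknown category {category!r}")
            if not (0 <= start < end <= len(text)):
                raise BratParseError(
                    lineno, f"span ({start},{end}) outside text of length {len(text)}"
                )
            if text[start:end] != surface:
                raise BratParseError(
                    lineno,
                    f"surface {surface!r} does not match text slice "
                    f"{text[start:end]!r}",
                )
            if tag in entities:
                raise BratParseError(lineno, f"duplicate entity id {tag}")
            entities[tag] = Entity(tag, category, start, end, surface)
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise BratParseError(lineno, "relation line needs 2 fields")
            parts = fields[1].split()
            if len(parts) != 3:
                raise BratParseError(lineno, f"malformed relation {fields[1]!r}")
            rtype = parts[0]
            args = {}
            for p in parts[1:]:
                if ":" not in p:
                    raise BratParseError(lineno, f"malformed relation argument {p!r}")
                role, ref = p.split(":", 1)
                args[role] = ref
            if set(args) != {"Arg1", "Arg2"}:
                raise BratParseError(lineno, "relation needs Arg1 and Arg2")
            pending_relations.append((lineno, tag, rtype, args["Arg1"], args["Arg2"]))
        elif tag.startswith("A"):
            parts = fields[1].split() if len(fields) > 1 else []
            if len(parts) != 2 or parts[0] != "Negation":
                logger.warning("skipping unsupported attribute line %d: %r", lineno, line)
                continue
            negated_ids.append((lineno, parts[1]))
        else:
            logger.warning("skipping unsupported line type %r at line %d", tag[:1], lineno)

    for lineno, rel_id, rtype, a1, a2 in pending_relations:
        if a1 not in entities or a2 not in entities:
            raise BratParseError(lineno, f"dangling entity reference in {rel_id}")
        relations.append(Relation(rel_id, rtype, entities[a1], entities[a2]))

    negations = []
    negated = set()
    for lineno, ref in negated_ids:
        if ref not in entities:
            raise BratParseError(lineno, f"dangling entity reference {ref}")
        negated.add(ref)
    for ent in entities.values():
        if ent.category == NODULE:
            label = NEGATED if ent.ent_id in negated else NON_NEGATED
            negations.append(NegationFlag(ent, label))

    return Document(
        doc_id=doc_id,
        text=text,
        entities=list(entities.values()),
        relations=relations,
        negations=negations,
    )


def write_brat(doc: Document) -> str:
    """Serialize a Document to .ann content; refuses invalid documents.

    Ordering is canonical (entities by start offset, relations by head then
    tail offset, negation attributes in entity order) so output is diffable
    and byte-stable.
    """
    violations = validate_document(doc)
    if violations:
        raise ValueError(
            "refusing to serialize invalid document: " + "; ".join(violations)
        )
    lines: list[str] = []
    for e in sorted(doc.entities, key=lambda e: (e.start, e.end, e.category)):
        lines.append(f"{e.ent_id}\t{e.category} {e.start} {e.end}\t{e.surface}")
    for r in sorted(doc.relations, key=lambda r: (r.head.start, r.tail.start, r.rtype)):
        lines.append(f"{r.rel_id}\t{r.rtype} Arg1:{r.head.ent_id} Arg2:{r.tail.ent_id}")
    a_num = 1
    for f in sorted(doc.negations, key=lambda f: f.entity.start):
        if f.label == NEGATED:
            lines.append(f"A{a_num}\tNegation {f.entity.ent_id}")
            a_num += 1
    return "\n".join(lines) + ("\n" if lines else "")


def read_corpus_dir(path: str | Path) -> list[Document]:
    """Load every ``<stem>.txt`` / ``<stem>.ann`` pair under a directory."""
    path = Path(path)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        ann = txt.with_suffix(".ann")
        docs.append(
            read_brat(
                txt.read_text(encoding="utf-8"),
                ann.read_text(encoding="utf-8") if ann.exists() else "",
                doc_id=txt.stem,
            )
        )
    return docs


def write_corpus_dir(docs: list[Document], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (path / f"{doc.doc_id}.ann").write_text(write_brat(doc), encoding="utf-8")


__all__ = [
    "BratParseError",
    "read_brat",
    "read_corpus_dir",
    "write_brat",
    "write_corpus_dir",
]
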