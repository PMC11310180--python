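"""Document/annotation data model for pulmonary-nodule information extraction.

The annotation schema distinguishes seven concept categories — the nodule
mention itself plus six characteristics radiologists document for Lung-RADS
scoring (anatomic site, laterality, size, interval course, texture/density,
shape) — six relation types linking each characteristic to its nodule, and a
binary negation attribute on nodule mentions ("No pulmonary nodule").

All character offsets are 0-based, end-exclusive indices into the document
text, which is newline-normalized to ``\\n`` on ingestion so offsets are
platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

NODULE = "Nodule"

#: The seven concept categories, in the canonical (frequency) order.
CATEGORIES: tuple[str, ...] = (
    "Nodule", "Site", "Laterality", "Size", "Course", "Texture", "Shape",
)

#: The six characteristic categories (everything but Nodule).
CHARACTERISTIC_CATEGORIES: tuple[str, ...] = CATEGORIES[1:]

#: Bijection between characteristic category and relation type.
RELATION_TYPE_FOR_CATEGORY: dict[str, str] = {
    c: f"nodule-{c.lower()}" for c in CHARACTERISTIC_CATEGORIES
}
CATEGORY_FOR_RELATION_TYPE: dict[str, str] = {
    v: k for k, v in RELATION_TYPE_FOR_CATEGORY.items()
}
RELATION_TYPES: tuple[str, ...] = tuple(RELATION_TYPE_FOR_CATEGORY.values())

NEGATED = "negated"
NON_NEGATED = "non-negated"
NEGATION_LABELS: tuple[str, str] = (NEGATED, NON_NEGATED)


@dataclass(frozen=True)
class Entity:
    """A typed character span (BRAT T-annotation)."""

    ent_id: str
    category: str
    start: int
    end: int
    surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Relation:
    """Directed nodule -> characteristic link (BRAT R-annotation)."""

    rel_id: str
    rtype: str
    head: Entity
    tail: Entity


@dataclass(frozen=True)
class NegationFlag:
    """Negation status of a nodule mention; absence of the BRAT attribute
    means non-negated."""

    entity: Entity
    label: str = NON_NEGATED


@dataclass
class Document:
    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    negations: list[NegationFlag] = field(default_factory=list)

    def entity_by_id(self, ent_id: str) -> Entity:
        for e in self.entities:
            if e.ent_id == ent_id:
                return e
        raise KeyError(ent_id)

    def negation_label(self, entity: Entity) -> str:
        for flag in self.negations:
            if flag.entity.ent_id == entity.ent_id:
                return flag.label
        return NON_NEGATED

    def nodules(self) -> list[Entity]:
        return [e for e in self.entities if e.category == NODULE]


def normalize_newlines(text: str) -> str:
    """Normalize CRLF/CR to LF so character offsets are platform-stable."""
    return text.replace("\r\n", "\n").replace("\r", "\n")


def validate_document(doc: Document) -> list[str]:
    """Check every schema invariant; return human-readable violations.

    Validation never raises: a malformed document yields messages naming the
    offending identifier and the rule it breaks, a valid one yields ``[]``.
    """
    violations: list[str] = []
    n = len(doc.text)
    seen_ids: set[str] = set()

    for e in doc.entities:
        if e.ent_id in seen_ids:
            violations.append(f"{e.ent_id}: duplicate identifier")
        seen_ids.add(e.ent_id)
        if e.category not in CATEGORIES:
            violations.append(f"{e.ent_id}: unknown category {e.category!r}")
        if not (0 <= e.start < e.end <= n):
            violations.append(
                f"{e.ent_id}: span ({e.start},{e.end}) outside text of length {n}"
            )
        elif doc.text[e.start:e.end] != e.surface:
            violations.append(
                f"{e.ent_id}: surface {e.surface!r} != text slice "
                f"{doc.text[e.start:e.end]!r}"
            )

    ent_ids = {e.ent_id for e in doc.entities}
    for r in doc.relations:
        if r.rel_id in seen_ids:
            violations.append(f"{r.rel_id}: duplicate identifier")
        seen_ids.add(r.rel_id)
        if r.head.ent_id not in ent_ids or r.tail.ent_id not in ent_ids:
            violations.append(f"{r.rel_id}: dangling entity reference")
        if r.head.category != NODULE:
            violations.append(f"{r.rel_id}: head must be Nodule, got {r.head.category}")
        if r.tail.category not in CHARACTERISTIC_CATEGORIES:
            violations.append(
                f"{r.rel_id}: tail must be a characteristic, got {r.tail.category}"
            )
        expected = RELATION_TYPE_FOR_CATEGORY.get(r.tail.category)
        if expected is not None and r.rtype != expected:
            violations.append(
                f"{r.rel_id}: type {r.rtype!r} inconsistent with tail category "
                f"{r.tail.category} (expected {expected!r})"
            )

    flagged: set[str] = set()
    for f in doc.negations:
        if f.entity.category != NODULE:
            violations.append(
                f"{f.entity.ent_id}: negation flag on non-Nodule entity"
            )
        if f.label not in NEGATION_LABELS:
            violations.append(f"{f.entity.ent_id}: unknown negation label {f.label!r}")
        if f.entity.ent_id in flagged:
            violations.append(f"{f.entity.ent_id}: multiple negation flags")
        flagged.add(f.entity.ent_id)
        if f.entity.ent_id not in ent_ids:
            violations.append(f"{f.entity.ent_id}: negation flag on unknown entity")

    return violations


def documents_equal(a: Document, b: Document) -> bool:
    """Field-for-field equality up to annotation ordering."""
    if a.doc_id != b.doc_id or a.text != b.text:
        return False
    key_e = lambda e: (e.start, e.end, e.category, e.ent_id)
    if sorted(a.entities, key=key_e) != sorted(b.entities, key=key_e):
        return False
    key_r = lambda r: (r.head.start, r.tail.start, r.rtype, r.rel_id)
    if sorted(a.relations, key=key_r) != sorted(b.relations, key=key_r):
        return False
    # compare effective negation status per nodule (default non-negated)
    def status(d: Document) -> dict[str, str]:
        out = {e.ent_id: NON_NEGATED for e in d.entities if e.category == NODULE}
        for f in d.negations:
            out[f.entity.ent_id] = f.label
        return out

    return status(a) == status(b)


__all__ = [
    "CATEGORIES",
    "CHARACTERISTIC_CATEGORIES",
    "CATEGORY_FOR_RELATION_TYPE",
    "Document",
    "Entity",
    "NEGATED",
    "NEGATION_LABELS",
    "NODULE",
    "NON_NEGATED",
    "NegationFlag",
    "RELATION_TYPES",
    "RELATION_TYPE_FOR_CATEGORY",
    "Relation",
    "documents_equal",
    "normalize_newlines",
    "validate_document",
]
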