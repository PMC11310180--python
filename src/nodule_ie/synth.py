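"""Seeded synthetic radiology-report generator with aligned gold annotations.

Real lung-cancer-screening corpora are protected health information, so
every trainable stage in this package is exercised on synthetic reports
whose statistical shape mirrors an annotated LDCT screening corpus: seven
concept categories with realistic relative frequencies (nodule mentions
dominate; shape descriptors are rare), roughly 29% of nodule mentions
negated, characteristic-to-nodule relations overwhelmingly within a
cross-distance of two sentences, and non-patient-specific guideline
boilerplate ("lung nodule follow up algorithm ...") interleaved as
annotation-free distractor text.

The generator is a template grammar, not a language model: every slot
filler's character offsets are recorded at construction time, so gold
annotations are exact by construction and the whole corpus is a pure
function of (config, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .schema import (
    NEGATED,
    NODULE,
    NON_NEGATED,
    RELATION_TYPE_FOR_CATEGORY,
    Document,
    Entity,
    NegationFlag,
    Relation,
)

# ---------------------------------------------------------------------------
# vocabularies (Lung-RADS-style descriptor language)

NODULE_TERMS = ["nodule", "nodules", "mass", "opacity", "lesion"]
SITE_TERMS = [
    "lower lobe", "upper lobe", "middle lobe", "lingula", "apex",
    "lung base", "perifissural region", "costophrenic angle",
]
LATERALITY_TERMS = ["left", "right", "bilateral"]
COURSE_TERMS = ["stable", "unchanged", "new", "enlarging", "decreased", "slightly increased"]
TEXTURE_TERMS = ["solid", "ground-glass", "part-solid", "calcified", "semisolid"]
SHAPE_TERMS = ["round", "oval", "spiculated", "lobulated", "irregular", "triangular"]

OPENING_SENTENCES = [
    "CT chest without contrast.",
    "Low dose CT of the chest was performed.",
    "Indication: lung cancer screening.",
    "FINDINGS:",
]
FILLER_SENTENCES = [
    "Comparison was made with the prior examination.",
    "The visualized airways are patent.",
    "Heart size is normal.",
    "No pleural effusion.",
    "The remaining lungs are clear.",
    "Mediastinal contours are unremarkable.",
]
BOILERPLATE_SENTENCES = [
    "Lung nodule follow up algorithm: for nodules less than 4 mm, repeat CT at 12 months.",
    "Fleischner society guidelines recommend follow up for solid nodules larger than 6 mm.",
    "Lung-RADS category assignment is based on nodule size and density.",
]

#: Concept-frequency weights defaulting to a screening corpus' training-set
#: counts (nodules dominate, shape descriptors rare).
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "Nodule": 426, "Site": 252, "Laterality": 240, "Size": 221,
    "Course": 135, "Texture": 111, "Shape": 27,
}
#: Fraction of nodule mentions in negated templates (116 / 404).
DEFAULT_NEGATED_FRACTION = 116 / 404
#: P(cross-distance = 0, 1, 2, >=3) for characteristic placement; >= 96%
#: of relations fall below distance three.
DEFAULT_CROSS_DISTANCE_DISTRIBUTION = (0.80, 0.11, 0.06, 0.03)
#: Train/validation/test document ratios (273 : 31 : 90).
DEFAULT_SPLIT_RATIOS = (273 / 394, 31 / 394, 90 / 394)


@dataclass
class GeneratorConfig:
    n_docs: int = 394
    seed: int = 13
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    negated_fraction: float = DEFAULT_NEGATED_FRACTION
    cross_distance_distribution: tuple[float, float, float, float] = (
        DEFAULT_CROSS_DISTANCE_DISTRIBUTION
    )
    boilerplate_rate: float = 0.3
    split_ratios: tuple[float, float, float] = DEFAULT_SPLIT_RATIOS

    def validate(self) -> None:
        if self.n_docs <= 0:
            raise ValueError("n_docs must be positive")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be nonnegative")
        if abs(sum(self.cross_distance_distribution) - 1.0) > 1e-9:
            raise ValueError("cross_distance_distribution must sum to 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        if not 0.0 <= self.negated_fraction <= 1.0:
            raise ValueError("negated_fraction must be in [0, 1]")

    def characteristic_probabilities(self) -> dict[str, float]:
        """Per positive (non-negated) nodule, probability of each
        characteristic, chosen so expected gold counts match the configured
        category weights (negated nodules carry no characteristics)."""
        w_nod = self.category_weights[NODULE]
        keep = 1.0 - self.negated_fraction
        return {
            c: min(1.0, (w / w_nod) / keep) if keep > 0 else 0.0
            for c, w in self.category_weights.items()
            if c != NODULE
        }


# ---------------------------------------------------------------------------
# offset-tracking document builder


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self._parts: list[str] = []
        self._pos = 0
        self._entities: list[tuple[str, int, int, str]] = []  # cat, start, end, surface
        self._relations: list[tuple[int, int]] = []  # head ent idx, tail ent idx
        self._negated: set[int] = set()

    def literal(self, text: str) -> None:
        self._parts.append(text)
        self._pos += len(text)

    def entity(self, category: str, surface: str) -> int:
        start = self._pos
        self.literal(surface)
        self._entities.append((category, start, start + len(surface), surface))
        return len(self._entities) - 1

    def relation(self, head_idx: int, tail_idx: int) -> None:
        self._relations.append((head_idx, tail_idx))

    def negate(self, ent_idx: int) -> None:
        self._negated.add(ent_idx)

    def end_sentence(self, sep: str = " ") -> None:
        self.literal(sep if sep == "\n" else sep)

    def build(self) -> Document:
        text = "".join(self._parts).rstrip()
        order = sorted(
            range(len(self._entities)),
            key=lambda i: (self._entities[i][1], self._entities[i][2]),
        )
        id_for = {idx: f"T{n}" for n, idx in enumerate(order, start=1)}
        entities = {}
        for idx in order:
            cat, start, end, surface = self._entities[idx]
            entities[idx] = Entity(id_for[idx], cat, start, end, surface)
        relations = []
        rel_sorted = sorted(
            self._relations,
            key=lambda ht: (entities[ht[0]].start, entities[ht[1]].start),
        )
        for n, (h, t) in enumerate(rel_sorted, start=1):
            tail = entities[t]
            relations.append(
                Relation(
                    f"R{n}",
                    RELATION_TYPE_FOR_CATEGORY[tail.category],
                    entities[h],
                    tail,
                )
            )
        negations = [
            NegationFlag(e, NEGATED if idx in self._negated else NON_NEGATED)
            for idx, e in entities.items()
            if e.category == NODULE
        ]
        return Document(
            doc_id=self.doc_id,
            text=text,
            entities=[entities[i] for i in order],
            relations=relations,
            negations=negations,
        )


# ---------------------------------------------------------------------------
# sentence templates


def _size_term(rng: random.Random) -> str:
    if rng.random() < 0.6:
        return f"{rng.randint(2, 9)} mm"
    return f"{rng.randint(1, 2)}.{rng.randint(0, 9)} cm"


def _char_surface(category: str, rng: random.Random) -> str:
    return {
        "Site": lambda: rng.choice(SITE_TERMS),
        "Laterality": lambda: rng.choice(LATERALITY_TERMS),
        "Size": lambda: _size_term(rng),
        "Course": lambda: rng.choice(COURSE_TERMS),
        "Texture": lambda: rng.choice(TEXTURE_TERMS),
        "Shape": lambda: rng.choice(SHAPE_TERMS),
    }[category]()


def _negated_sentence(b: _DocBuilder, rng: random.Random) -> None:
    word = rng.choice(["nodule", "mass", "opacity", "lesion"])
    template = rng.randrange(5)
    if template == 0:
        b.literal("No pulmonary ")
        idx = b.entity(NODULE, word)
        b.literal(".")
    elif template == 1:
        b.literal("No suspicious ")
        idx = b.entity(NODULE, word)
        b.literal(" is seen.")
    elif template == 2:
        b.literal("There is no evidence of a ")
        idx = b.entity(NODULE, word)
        b.literal(".")
    elif template == 3:
        b.literal("Without focal ")
        idx = b.entity(NODULE, word)
        b.literal(".")
    else:
        b.literal("Negative for ")
        idx = b.entity(NODULE, word)
        b.literal(".")
    b.negate(idx)


def _main_finding_sentence(
    b: _DocBuilder, rng: random.Random, inline: dict[str, str]
) -> tuple[int, dict[str, int]]:
    """Emit the sentence introducing a nodule with its inline (d = 0)
    characteristics; returns (nodule idx, characteristic idx per category)."""
    ents: dict[str, int] = {}
    word = rng.choice(NODULE_TERMS)
    style = rng.random()

    def premods() -> None:
        for cat in ("Size", "Course", "Texture", "Shape"):
            if cat in inline:
                ents[cat] = b.entity(cat, inline[cat])
                b.literal(" ")

    def location(prefix: str = " in the ") -> None:
        if "Laterality" in inline and "Site" in inline:
            b.literal(prefix)
            ents["Laterality"] = b.entity("Laterality", inline["Laterality"])
            b.literal(" ")
            ents["Site"] = b.entity("Site", inline["Site"])
        elif "Site" in inline:
            b.literal(prefix)
            ents["Site"] = b.entity("Site", inline["Site"])
        elif "Laterality" in inline:
            b.literal(" on the ")
            ents["Laterality"] = b.entity("Laterality", inline["Laterality"])
            b.literal(" side")

    if style < 0.35:
        b.literal("There is a ")
        premods()
        nod = b.entity(NODULE, word)
        location()
        b.literal(".")
    elif style < 0.70:
        b.literal("A ")
        premods()
        nod = b.entity(NODULE, word)
        b.literal(" is seen")
        location()
        b.literal(".")
    elif style < 0.85:
        # report-fragment style, mirrors "nodule located at the lower lobe"
        for cat in ("Size", "Texture"):
            if cat in inline:
                ents[cat] = b.entity(cat, inline[cat])
                b.literal(" ")
        nod = b.entity(NODULE, word)
        location(" located at the ")
        for cat in ("Course", "Shape"):
            if cat in inline:
                b.literal(", ")
                ents[cat] = b.entity(cat, inline[cat])
        b.literal(".")
    else:
        b.literal("Redemonstrated is a ")
        premods()
        nod = b.entity(NODULE, word)
        location()
        b.literal(".")
    return nod, ents


def _followup_sentence(
    b: _DocBuilder, rng: random.Random, chars: dict[str, str]
) -> dict[str, int]:
    """Emit exactly ONE pronoun follow-up sentence carrying the given
    characteristics (one sentence keeps the realized cross-distance equal to
    the sampled one)."""
    ents: dict[str, int] = {}
    pronoun = rng.choice(["It", "This"])
    b.literal(pronoun + " ")
    wrote_clause = False

    if "Size" in chars:
        b.literal("measures ")
        ents["Size"] = b.entity("Size", chars["Size"])
        wrote_clause = True
    descriptors = [c for c in ("Course", "Texture", "Shape") if c in chars]
    if descriptors:
        b.literal(" and is " if wrote_clause else rng.choice(["is ", "appears "]))
        for i, cat in enumerate(descriptors):
            if i:
                b.literal(" and ")
            ents[cat] = b.entity(cat, chars[cat])
        wrote_clause = True
    located = [c for c in ("Laterality", "Site") if c in chars]
    if located:
        b.literal(" and is located in the " if wrote_clause else "is located in the ")
        for i, cat in enumerate(located):
            if i:
                b.literal(" ")
            ents[cat] = b.entity(cat, chars[cat])
    b.literal(".")
    return ents


def _finding_block(b: _DocBuilder, rng: random.Random, config: GeneratorConfig) -> None:
    if rng.random() < config.negated_fraction:
        _negated_sentence(b, rng)
        b.end_sentence()
        return
    probs = config.characteristic_probabilities()
    chosen = [c for c, p in probs.items() if rng.random() < p]
    dist = config.cross_distance_distribution
    by_distance: dict[int, dict[str, str]] = {0: {}, 1: {}, 2: {}, 3: {}}
    for cat in chosen:
        d = rng.choices((0, 1, 2, 3), weights=dist)[0]
        by_distance[d][cat] = _char_surface(cat, rng)

    nod, ents = _main_finding_sentence(b, rng, by_distance[0])
    for cat, idx in ents.items():
        b.relation(nod, idx)
    b.end_sentence()
    max_d = max((d for d in (1, 2, 3) if by_distance[d]), default=0)
    for d in range(1, max_d + 1):
        if by_distance[d]:
            ents = _followup_sentence(b, rng, by_distance[d])
            for cat, idx in ents.items():
                b.relation(nod, idx)
        else:
            b.literal(rng.choice(FILLER_SENTENCES))
        b.end_sentence()


def generate_document(doc_id: str, rng: random.Random, config: GeneratorConfig) -> Document:
    b = _DocBuilder(doc_id)
    opener = rng.choice(OPENING_SENTENCES)
    b.literal(opener)
    b.end_sentence("\n" if opener.endswith(":") else " ")
    n_findings = rng.choices((1, 2, 3), weights=(0.5, 0.35, 0.15))[0]
    for _ in range(n_findings):
        _finding_block(b, rng, config)
        if rng.random() < 0.3:
            b.literal(rng.choice(FILLER_SENTENCES))
            b.end_sentence()
    if rng.random() < config.boilerplate_rate:
        b.literal(rng.choice(BOILERPLATE_SENTENCES))
        b.end_sentence()
    return b.build()


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[list[Document], dict[str, str]]:
    """Generate ``config.n_docs`` annotated reports plus a split assignment.

    Returns ``(documents, splits)`` where ``splits`` maps doc_id to one of
    ``train``/``val``/``test``.  Same config and seed reproduce the corpus
    byte-for-byte.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(config.seed)
    docs = [
        generate_document(f"synth_{i:04d}", rng, config) for i in range(config.n_docs)
    ]
    n = config.n_docs
    n_train = round(n * config.split_ratios[0])
    n_val = round(n * config.split_ratios[1])
    ids = [d.doc_id for d in docs]
    rng.shuffle(ids)
    splits = {}
    for i, doc_id in enumerate(ids):
        if i < n_train:
            splits[doc_id] = "train"
        elif i < n_train + n_val:
            splits[doc_id] = "val"
        else:
            splits[doc_id] = "test"
    return docs, splits


def split_documents(
    docs: list[Document], splits: dict[str, str]
) -> tuple[list[Document], list[Document], list[Document]]:
    train = [d for d in docs if splits[d.doc_id] == "train"]
    val = [d for d in docs if splits[d.doc_id] == "val"]
    test = [d for d in docs if splits[d.doc_id] == "test"]
    return train, val, test


# ---------------------------------------------------------------------------
# fixed worked fixtures


def make_worked_fixtures() -> list[Document]:
    """Small fixed corpus of hand-built documents with exact gold.

    Includes the canonical positive sentence ("nodule located at the lower
    lobe"), the canonical negation ("No pulmonary nodule."), and edge cases:
    adjacent same-category entities, a cross-sentence relation at distance
    two, an orphan characteristic at distance three (whose gold relation is
    unreachable for any candidate generator capped below three), and a
    two-nodule sentence.
    """
    docs: list[Document] = []

    # 1: canonical positive finding
    b = _DocBuilder("worked_site")
    nod = b.entity(NODULE, "nodule")
    b.literal(" located at the ")
    site = b.entity("Site", "lower lobe")
    b.relation(nod, site)
    docs.append(b.build())

    # 2: canonical negation
    b = _DocBuilder("worked_negation")
    b.literal("No pulmonary ")
    idx = b.entity(NODULE, "nodule")
    b.literal(".")
    b.negate(idx)
    docs.append(b.build())

    # 3: adjacent same-category entities
    b = _DocBuilder("worked_adjacent")
    b.literal("It is ")
    t1 = b.entity("Texture", "solid")
    b.literal(" ")
    t2 = b.entity("Texture", "calcified")
    b.literal(".")
    docs.append(b.build())

    # 4: cross-sentence relation at distance two
    b = _DocBuilder("worked_d2")
    b.literal("There is a ")
    nod = b.entity(NODULE, "nodule")
    b.literal(" in the ")
    site = b.entity("Site", "upper lobe")
    b.relation(nod, site)
    b.literal(". ")
    b.literal("Comparison was made with the prior examination. ")
    b.literal("It is ")
    course = b.entity("Course", "stable")
    b.literal(".")
    b.relation(nod, course)
    docs.append(b.build())

    # 5: orphan characteristic at distance three (gold relation unreachable
    # under the cross-distance < 3 candidate cap: the known false negative)
    b = _DocBuilder("worked_d3_orphan")
    b.literal("A ")
    nod = b.entity(NODULE, "mass")
    b.literal(" is seen. ")
    b.literal("Heart size is normal. ")
    b.literal("No pleural effusion. ")
    b.literal("It measures ")
    size = b.entity("Size", "9 mm")
    b.literal(".")
    b.relation(nod, size)
    docs.append(b.build())

    # 6: two nodules in one sentence, characteristics bound to the first
    b = _DocBuilder("worked_two_nodules")
    b.literal("A ")
    size = b.entity("Size", "4 mm")
    b.literal(" ")
    nod1 = b.entity(NODULE, "nodule")
    b.relation(nod1, size)
    b.literal(" is seen adjacent to a second ")
    nod2 = b.entity(NODULE, "nodule")
    b.literal(".")
    docs.append(b.build())

    # 7: finding plus guideline boilerplate carrying no annotations
    b = _DocBuilder("worked_boilerplate")
    b.literal("There is a ")
    tex = b.entity("Texture", "solid")
    b.literal(" ")
    nod = b.entity(NODULE, "nodule")
    b.relation(nod, tex)
    b.literal(". ")
    b.literal(BOILERPLATE_SENTENCES[0])
    docs.append(b.build())

    # 8: no findings at all
    docs.append(Document("worked_empty", "The lungs are clear."))

    # 9: laterality + site both linked across a sentence boundary (d = 1)
    b = _DocBuilder("worked_d1_location")
    b.literal("A ")
    nod = b.entity(NODULE, "nodule")
    b.literal(" is seen. ")
    b.literal("This is located in the ")
    lat = b.entity("Laterality", "right")
    b.literal(" ")
    site = b.entity("Site", "middle lobe")
    b.literal(".")
    b.relation(nod, lat)
    b.relation(nod, site)
    docs.append(b.build())

    # 10: negated and positive nodule in the same document
    b = _DocBuilder("worked_mixed")
    b.literal("No suspicious ")
    neg = b.entity(NODULE, "mass")
    b.literal(" is seen. ")
    b.negate(neg)
    b.literal("There is a ")
    size = b.entity("Size", "5 mm")
    b.literal(" ")
    nod = b.entity(NODULE, "nodule")
    b.literal(" in the ")
    lat = b.entity("Laterality", "left")
    b.literal(" ")
    site = b.entity("Site", "lingula")
    b.literal(".")
    b.relation(nod, size)
    b.relation(nod, lat)
    b.relation(nod, site)
    docs.append(b.build())

    return docs


__all__ = [
    "BOILERPLATE_SENTENCES",
    "DEFAULT_CATEGORY_WEIGHTS",
    "DEFAULT_CROSS_DISTANCE_DISTRIBUTION",
    "DEFAULT_NEGATED_FRACTION",
    "DEFAULT_SPLIT_RATIOS",
    "GeneratorConfig",
    "generate_corpus",
    "generate_document",
    "make_worked_fixtures",
    "split_documents",
]
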