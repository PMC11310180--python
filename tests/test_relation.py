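"""Candidate generation, pair features, classification, and rule typing."""

import pytest

from nodule_ie.preprocessing import normalize_and_segment
from nodule_ie.relation import (
    CandidatePair,
    HAS_RELATION,
    NO_RELATION,
    PairClassifier,
    assign_relation_type,
    cross_distance,
    featurize_corpus,
    featurize_pair,
    generate_candidates,
    train_pair_classifier,
)
from nodule_ie.schema import (
    CHARACTERISTIC_CATEGORIES,
    RELATION_TYPE_FOR_CATEGORY,
    Document,
    Entity,
)
from nodule_ie.synth import GeneratorConfig, generate_corpus, make_worked_fixtures


def _sentences(doc):
    _, s = normalize_and_segment(doc.text)
    return s


class TestCrossDistance:
    def test_same_sentence_is_zero(self):
        doc = make_worked_fixtures()[0]
        s = _sentences(doc)
        assert cross_distance(doc.entities[0], doc.entities[1], s) == 0

    def test_adjacent_sentences_is_one(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_d1_location")
        s = _sentences(doc)
        nod = doc.nodules()[0]
        site = next(e for e in doc.entities if e.category == "Site")
        assert cross_distance(nod, site, s) == 1

    def test_three_boundaries_apart(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_d3_orphan")
        s = _sentences(doc)
        nod = doc.nodules()[0]
        size = next(e for e in doc.entities if e.category == "Size")
        assert cross_distance(nod, size, s) == 3


class TestGenerateCandidates:
    def test_one_nodule_two_characteristics_in_sentence(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_mixed")
        pairs = generate_candidates(doc)
        # two nodules (one negated) x three characteristics, all within range
        assert len(pairs) == 6

    def test_two_nodules_one_characteristic_yields_one_pair_each(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_two_nodules")
        pairs = generate_candidates(doc)
        assert len(pairs) == 2
        assert all(p.tail.category == "Size" for p in pairs)

    def test_characteristic_three_sentences_away_is_excluded(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_d3_orphan")
        assert generate_candidates(doc) == []

    def test_document_without_nodules_yields_nothing(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_adjacent")
        assert generate_candidates(doc) == []

    def test_training_labels_match_gold(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_two_nodules")
        pairs = generate_candidates(doc, with_labels=True)
        labels = {(p.head.start, p.tail.start): p.label for p in pairs}
        gold = {(r.head.start, r.tail.start) for r in doc.relations}
        for key, label in labels.items():
            assert label == (HAS_RELATION if key in gold else NO_RELATION)

    def test_equals_brute_force_enumeration(self):
        """Candidate generation must equal the double loop over all entity
        pairs with the nodule-first + cross-distance filter applied."""
        docs, _ = generate_corpus(GeneratorConfig(n_docs=100, seed=99))
        for doc in docs:
            s = _sentences(doc)
            expected = set()
            for n in doc.entities:
                for c in doc.entities:
                    if (
                        n.category == "Nodule"
                        and c.category in CHARACTERISTIC_CATEGORIES
                        and cross_distance(n, c, s) < 3
                    ):
                        expected.add((n.span, c.span))
            got = {(p.head.span, p.tail.span) for p in generate_candidates(doc, s)}
            assert got == expected


class TestFeatures:
    def test_worked_pair_token_distance_and_entity_ngram(self):
        doc = make_worked_fixtures()[0]
        pair = generate_candidates(doc)[0]
        feats = featurize_pair(doc, pair)
        # "located at the" lie strictly between the entities -> distance 3
        assert feats.get("tokdist<=3") == 1.0
        assert feats.get("tail:ng=lower lobe") == 1.0

    def test_adjacent_entities_have_zero_token_distance(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_two_nodules")
        pair = generate_candidates(doc)[0]  # "4 mm" immediately before "nodule"
        feats = featurize_pair(doc, pair)
        assert feats.get("tokdist<=0") == 1.0

    def test_featurization_is_pure(self):
        doc = make_worked_fixtures()[0]
        pair = generate_candidates(doc)[0]
        assert featurize_pair(doc, pair) == featurize_pair(doc, pair)


class TestAssignRelationType:
    def test_site_pair_typed_nodule_site(self):
        doc = make_worked_fixtures()[0]
        pair = generate_candidates(doc)[0]
        rel = assign_relation_type(pair)
        assert rel.rtype == "nodule-site"

    def test_mapping_is_total_and_injective(self):
        types = {RELATION_TYPE_FOR_CATEGORY[c] for c in CHARACTERISTIC_CATEGORIES}
        assert len(types) == 6

    def test_nodule_tail_rejected(self):
        n1 = Entity("T1", "Nodule", 0, 6, "nodule")
        n2 = Entity("T2", "Nodule", 10, 16, "nodule")
        with pytest.raises(ValueError, match="tail"):
            assign_relation_type(CandidatePair(n1, n2, 0))


class TestPairClassifier:
    def test_single_class_training_data_raises_with_guidance(self):
        with pytest.raises(ValueError, match="single class"):
            PairClassifier().fit([{"a": 1.0}] * 10, [HAS_RELATION] * 10)

    def test_margin_backend_memorizes_training_pairs(self, small_corpus):
        train, _, _ = small_corpus
        clf = train_pair_classifier(train, backend="margin", seed=13)
        feats, labels = featurize_corpus(train)
        pred = clf.predict(feats)
        agreement = sum(p == l for p, l in zip(pred, labels)) / len(labels)
        assert agreement >= 0.99

    def test_margin_cv_f1_on_separable_pairs(self, small_corpus):
        train, _, _ = small_corpus
        clf = train_pair_classifier(train, backend="margin", seed=13)
        assert clf.cv_results_["best_score"] >= 0.95

    def test_same_seed_selects_same_hyperparameters(self, small_corpus):
        train, _, _ = small_corpus
        a = train_pair_classifier(train[:30], backend="margin", seed=13)
        b = train_pair_classifier(train[:30], backend="margin", seed=13)
        assert a.cv_results_ == b.cv_results_

    def test_neural_backend_handles_all_cross_distances_with_one_model(self, small_corpus):
        """The unified neural classifier judges single- and cross-sentence
        pairs without per-distance models."""
        train, _, test = small_corpus
        clf = train_pair_classifier(train[:40], backend="neural", seed=13)
        feats, labels = featurize_corpus(test)
        distances = set()
        for doc in test:
            distances |= {p.cross_distance for p in generate_candidates(doc)}
        assert distances >= {0, 1}
        pred = clf.predict(feats)
        agreement = sum(p == l for p, l in zip(pred, labels)) / len(labels)
        assert agreement >= 0.9
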