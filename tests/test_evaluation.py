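"""Strict micro-averaged scoring against arithmetic and brute-force oracles."""

import pytest

from conftest import perturb_predictions
from nodule_ie.evaluation import (
    bootstrap_sd,
    evaluate_end_to_end,
    evaluate_entities,
    evaluate_negation,
    evaluate_relations,
)
from nodule_ie.schema import Document, Entity, NEGATED, NON_NEGATED, NegationFlag, Relation
from nodule_ie.synth import GeneratorConfig, generate_corpus


def _doc(doc_id, text, entities=(), relations=(), negations=()):
    return Document(doc_id, text, list(entities), list(relations), list(negations))


class TestEntityScoring:
    def test_perfect_prediction_scores_one(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=20, seed=2))
        report = evaluate_entities(docs, docs)
        assert report.precision == report.recall == report.f1 == 1.0

    def test_strict_boundary_mismatch_counts_nothing(self):
        text = "nodules everywhere"
        gold = [_doc("d", text, [Entity("T1", "Nodule", 0, 6, "nodule")])]
        pred = [_doc("d", text, [Entity("T1", "Nodule", 0, 7, "nodules")])]
        report = evaluate_entities(gold, pred)
        assert (report.overall.tp, report.overall.fp, report.overall.fn) == (0, 1, 1)
        assert report.f1 == 0.0

    def test_arithmetic_fixture(self):
        text = "a nodule in the left lower lobe"
        g = [
            Entity("T1", "Nodule", 2, 8, "nodule"),
            Entity("T2", "Laterality", 16, 20, "left"),
            Entity("T3", "Site", 21, 31, "lower lobe"),
        ]
        p = [
            Entity("T1", "Nodule", 2, 8, "nodule"),  # exact match
            Entity("T2", "Site", 16, 31, "left lower lobe"),  # wrong span
        ]
        report = evaluate_entities([_doc("d", text, g)], [_doc("d", text, p)])
        assert report.precision == 0.5
        assert report.recall == pytest.approx(1 / 3)
        assert report.f1 == pytest.approx(0.4)

    def test_duplicate_predictions_deduplicated(self):
        text = "a nodule"
        e = Entity("T1", "Nodule", 2, 8, "nodule")
        e2 = Entity("T2", "Nodule", 2, 8, "nodule")
        report = evaluate_entities(
            [_doc("d", text, [e])], [_doc("d", text, [e, e2])]
        )
        assert (report.overall.tp, report.overall.fp) == (1, 0)

    def test_doc_id_mismatch_raises_listing_ids(self):
        with pytest.raises(ValueError, match="missing"):
            evaluate_entities([_doc("a", "x")], [_doc("b", "x")])


class TestRelationScoring:
    def test_arithmetic_fixture_four_gold_three_pred_two_correct(self):
        text = "n1 n2 n3 n4 s1 s2 s3 s4"
        nods = [Entity(f"T{i}", "Nodule", 3 * i, 3 * i + 2, text[3 * i : 3 * i + 2])
                for i in range(4)]
        sites = [Entity(f"T{i+4}", "Site", 12 + 3 * i, 12 + 3 * i + 2,
                        text[12 + 3 * i : 12 + 3 * i + 2]) for i in range(4)]
        gold_rel = [Relation(f"R{i}", "nodule-site", nods[i], sites[i]) for i in range(4)]
        pred_rel = [gold_rel[0], gold_rel[1],
                    Relation("R9", "nodule-site", nods[2], sites[3])]
        ents = nods + sites
        report = evaluate_relations(
            [_doc("d", text, ents, gold_rel)], [_doc("d", text, ents, pred_rel)]
        )
        assert report.precision == pytest.approx(2 / 3)
        assert report.recall == 0.5

    def test_endpoint_boundary_error_fails_relation(self):
        text = "nodule at apex"
        n_good = Entity("T1", "Nodule", 0, 6, "nodule")
        n_bad = Entity("T1", "Nodule", 0, 5, "nodul")
        s = Entity("T2", "Site", 10, 14, "apex")
        gold = [_doc("d", text, [n_good, s],
                     [Relation("R1", "nodule-site", n_good, s)])]
        pred = [_doc("d", text, [n_bad, s],
                     [Relation("R1", "nodule-site", n_bad, s)])]
        assert evaluate_relations(gold, pred).f1 == 0.0


class TestNegationScoring:
    def test_half_of_negated_found_without_false_alarms(self):
        text = "no a no b"
        ents = [Entity(f"T{i}", "Nodule", 2 * i, 2 * i + 1, text[2 * i]) for i in range(4)]
        gold = [_doc("d", text, ents, [], [NegationFlag(e, NEGATED) for e in ents])]
        pred_flags = [NegationFlag(ents[0], NEGATED), NegationFlag(ents[1], NEGATED),
                      NegationFlag(ents[2], NON_NEGATED), NegationFlag(ents[3], NON_NEGATED)]
        pred = [_doc("d", text, ents, [], pred_flags)]
        report = evaluate_negation(gold, pred)
        assert report.precision == 1.0
        assert report.recall == 0.5
        assert report.f1 == pytest.approx(2 / 3)

    def test_no_negations_anywhere_reports_zeros(self, caplog):
        text = "a nodule"
        e = Entity("T1", "Nodule", 2, 8, "nodule")
        gold = [_doc("d", text, [e], [], [NegationFlag(e, NON_NEGATED)])]
        report = evaluate_negation(gold, gold)
        assert report.precision == report.recall == report.f1 == 0.0


class TestEvaluatorProperties:
    def test_equals_brute_force_set_intersection_oracle(self):
        """The evaluator's counts must match an exhaustive tuple-matching
        oracle over noisy predictions."""
        docs, _ = generate_corpus(GeneratorConfig(n_docs=60, seed=17))
        pred = perturb_predictions(docs, seed=4)
        report = evaluate_entities(docs, pred)
        # independent oracle: greedy exact matching over item lists
        gold_items = [(d.doc_id, e.start, e.end, e.category) for d in docs for e in d.entities]
        pred_items = {(d.doc_id, e.start, e.end, e.category) for d in pred for e in d.entities}
        tp = sum(1 for it in set(gold_items) if it in pred_items)
        fn = len(set(gold_items)) - tp
        fp = len(pred_items) - tp
        assert (report.overall.tp, report.overall.fp, report.overall.fn) == (tp, fp, fn)

    def test_swapping_gold_and_pred_swaps_precision_and_recall(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=40, seed=23))
        pred = perturb_predictions(docs, seed=9)
        fwd = evaluate_entities(docs, pred)
        rev = evaluate_entities(pred, docs)
        assert fwd.precision == pytest.approx(rev.recall)
        assert fwd.recall == pytest.approx(rev.precision)

    def test_micro_counts_are_sums_of_categories(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=40, seed=31))
        pred = perturb_predictions(docs, seed=12)
        report = evaluate_entities(docs, pred)
        assert report.overall.tp == sum(c.tp for c in report.per_category.values())
        assert report.overall.fp == sum(c.fp for c in report.per_category.values())
        assert report.overall.fn == sum(c.fn for c in report.per_category.values())

    def test_end_to_end_pools_all_three_layers(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=30, seed=41))
        report = evaluate_end_to_end(docs, docs)
        assert set(report.per_category) <= {"entity", "relation", "negation"}
        assert report.f1 == 1.0


class TestBootstrap:
    def test_identical_predictions_have_zero_sd(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=25, seed=3))
        sd = bootstrap_sd(evaluate_entities, docs, docs, n_reps=20, seed=13)
        assert sd == {"precision": 0.0, "recall": 0.0, "f1": 0.0}

    def test_same_seed_reproduces_sd(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=25, seed=3))
        pred = perturb_predictions(docs, seed=7)
        a = bootstrap_sd(evaluate_entities, docs, pred, n_reps=20, seed=13)
        b = bootstrap_sd(evaluate_entities, docs, pred, n_reps=20, seed=13)
        assert a == b

    def test_twenty_replicates_consistent_with_many(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=40, seed=3))
        pred = perturb_predictions(docs, seed=7)
        few = bootstrap_sd(evaluate_entities, docs, pred, n_reps=20, seed=13)
        many = bootstrap_sd(evaluate_entities, docs, pred, n_reps=400, seed=13)
        for key in few:
            assert few[key] <= 3 * many[key] and many[key] <= 3 * few[key]

    def test_too_few_replicates_rejected(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=5, seed=3))
        with pytest.raises(ValueError):
            bootstrap_sd(evaluate_entities, docs, docs, n_reps=1)
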